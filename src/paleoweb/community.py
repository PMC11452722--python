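"""Guilds, guild sets and the species-occurrence table.

A *trophic guild* is the set of species sharing one exact trait
combination; guilds are the node unit of every web and simulation in this
package.  Guild identity is purely the trait combination, so the same
guild id refers to "the same node" across time intervals — which is what
makes presence/absence comparisons between intervals meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .traits import INTERVALS, TraitProfile

PRODUCER_ID = "producer"

TRAIT_COLUMNS = ("motility", "tiering", "feeding", "size_class", "calcification")


class SchemaError(ValueError):
    """Input table is missing required columns."""


class ConflictError(ValueError):
    """A (species, interval) pair appears with conflicting trait profiles."""


@dataclass
class Guild:
    guild_id: str
    traits: Optional[TraitProfile]
    members: list[str] = field(default_factory=list)
    is_producer: bool = False

    def __post_init__(self) -> None:
        if self.is_producer:
            if self.traits is not None:
                raise ValueError("producer guild carries no trait profile")
        elif self.traits is None:
            raise ValueError("non-producer guild requires a trait profile")


def producer_guild() -> Guild:
    return Guild(guild_id=PRODUCER_ID, traits=None, is_producer=True)


@dataclass
class GuildSet:
    """All guilds of one time-binned community."""

    interval: str
    guilds: list[Guild]

    def __post_init__(self) -> None:
        keys = [g.traits.key() for g in self.guilds if not g.is_producer]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate trait combinations among guilds")
        n_prod = sum(g.is_producer for g in self.guilds)
        if n_prod > 1:
            raise ValueError("at most one producer guild per community")

    def __len__(self) -> int:
        return sum(not g.is_producer for g in self.guilds)

    def __iter__(self):
        return iter(self.guilds)

    @property
    def consumer_guilds(self) -> list[Guild]:
        return [g for g in self.guilds if not g.is_producer]

    def guild_ids(self) -> list[str]:
        return [g.guild_id for g in self.consumer_guilds]

    def by_id(self, guild_id: str) -> Guild:
        for g in self.guilds:
            if g.guild_id == guild_id:
                return g
        raise KeyError(guild_id)

    def species(self) -> list[str]:
        out: list[str] = []
        for g in self.consumer_guilds:
            out.extend(g.members)
        return out


def _validate_column(df: pd.DataFrame, col: str, optional: bool) -> pd.Series:
    from .traits import VocabularyError, validate_trait

    out = []
    for idx, value in df[col].items():
        if optional and (pd.isna(value) or str(value).strip() == ""):
            out.append(None)
            continue
        try:
            out.append(validate_trait(col, value))
        except VocabularyError as exc:
            raise VocabularyError(f"row {idx}: {exc}") from None
    return pd.Series(out, index=df.index, dtype=object)


class OccurrenceTable:
    """Row-per-occurrence table: (species_id, interval, count, traits).

    Wraps a validated :class:`pandas.DataFrame` with columns
    ``species_id, interval, count`` plus the five trait columns.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"species_id", "interval", "count", *TRAIT_COLUMNS[:4]}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"missing columns: {sorted(missing)}")
        df = df.copy()
        if "calcification" not in df.columns:
            df["calcification"] = None
        if (df["species_id"].astype(str).str.len() == 0).any():
            raise ValueError("empty species_id")
        bad_interval = ~df["interval"].isin(INTERVALS)
        if bad_interval.any():
            row = int(df.index[bad_interval][0])
            raise ValueError(
                f"row {row}: unknown interval {df.loc[row, 'interval']!r}; "
                f"expected one of {INTERVALS}"
            )
        if (df["count"].astype(float) < 0).any():
            raise ValueError("negative occurrence count")
        # closed-vocabulary validation, reported with the offending row
        for col in TRAIT_COLUMNS[:4]:
            df[col] = _validate_column(df, col, optional=False)
        df["calcification"] = _validate_column(df, "calcification", optional=True)
        # one profile per (species, interval)
        prof_cols = list(TRAIT_COLUMNS)
        dedup = df.drop_duplicates(subset=["species_id", "interval", *prof_cols])
        dup = dedup.duplicated(subset=["species_id", "interval"], keep=False)
        if dup.any():
            pair = dedup.loc[dup, ["species_id", "interval"]].iloc[0]
            raise ConflictError(
                f"species {pair['species_id']!r} has conflicting trait profiles "
                f"in interval {pair['interval']!r}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def species(self) -> list[str]:
        return sorted(self.df["species_id"].unique())

    def intervals(self) -> list[str]:
        return [iv for iv in INTERVALS if iv in set(self.df["interval"])]

    def profile_for_row(self, row: pd.Series) -> TraitProfile:
        calc = row.get("calcification")
        if pd.isna(calc) or calc == "":
            calc = None
        return TraitProfile(
            motility=row["motility"],
            tiering=row["tiering"],
            feeding=row["feeding"],
            size_class=row["size_class"],
            calcification=calc,
        )


def aggregate_guilds(occ: OccurrenceTable, interval: str) -> GuildSet:
    """Collapse the species of one interval into trait-combination guilds.

    Each distinct trait profile among the interval's species becomes one
    guild whose members are exactly the species carrying that profile.
    The members therefore partition the interval's species, and the
    operation is idempotent on an already guild-level table.
    """
    if interval not in INTERVALS:
        raise ValueError(f"unknown interval {interval!r}")
    sub = occ.df[occ.df["interval"] == interval]
    if sub.empty:
        warnings.warn(f"interval {interval!r} has no occurrences", stacklevel=2)
        return GuildSet(interval=interval, guilds=[])
    groups: dict[tuple, Guild] = {}
    for _, row in sub.drop_duplicates(subset=["species_id"]).iterrows():
        profile = occ.profile_for_row(row)
        key = profile.key()
        if key not in groups:
            groups[key] = Guild(guild_id=profile.guild_id(), traits=profile)
        groups[key].members.append(str(row["species_id"]))
    guilds = sorted(groups.values(), key=lambda g: g.guild_id)
    for g in guilds:
        g.members.sort()
    return GuildSet(interval=interval, guilds=guilds)


def guildset_from_profiles(
    profiles: Iterable[TraitProfile], interval: str, members: Optional[dict] = None
) -> GuildSet:
    """Build a GuildSet directly from trait profiles (one guild each)."""
    guilds = []
    for p in profiles:
        gid = p.guild_id()
        mem = list(members.get(gid, [gid])) if members else [gid]
        guilds.append(Guild(guild_id=gid, traits=p, members=mem))
    guilds.sort(key=lambda g: g.guild_id)
    return GuildSet(interval=interval, guilds=guilds)
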