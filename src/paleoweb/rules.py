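"""Trait-pair feeding rules gating feasible trophic links.

A link from resource guild *r* to consumer guild *c* is feasible only if
**all four** per-trait rules pass: feeding (can this feeding mode take
animal food at all), tiering (can the consumer reach the resource's
position in the water/sediment column), motility (can it catch it) and
size (is the resource within the consumable size range).  The producer
node is gated by a single producer rule keyed on feeding mode.

The published rule matrix for this model family circulates as a figure,
not as machine-readable tables, so the default shipped here encodes the
described semantics ("reconstructed semantics") and is deliberately a
plain, serialisable data structure the user can edit and reload without
touching code.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

from .traits import (
    COARSE_TIERING_MAP,
    FEEDING,
    MOTILITY,
    MOTILITY_RANK,
    SIZE_CLASSES,
    TIERING,
    TraitProfile,
)


def _check_total(table: dict, rows, cols, name: str) -> None:
    for r in rows:
        if r not in table:
            raise ValueError(f"{name} rule table missing row {r!r}")
        for c in cols:
            if c not in table[r]:
                raise ValueError(f"{name} rule table missing cell ({r!r}, {c!r})")
            if not isinstance(table[r][c], bool):
                raise ValueError(f"{name} rule cell ({r!r}, {c!r}) is not boolean")


@dataclass
class RuleSet:
    """Total boolean tables over the closed trait vocabularies.

    ``feeding[consumer_feeding]['animal'|'producer']`` — what food classes a
    feeding mode may take; ``tiering[c][r]``, ``motility[c][r]``,
    ``size[c][r]`` — consumer-by-resource feasibility; all four must hold
    for an animal-animal link, and ``feeding[c]['producer']`` alone gates a
    producer link.
    """

    feeding: dict = field(default_factory=dict)
    tiering: dict = field(default_factory=dict)
    motility: dict = field(default_factory=dict)
    size: dict = field(default_factory=dict)
    allow_cannibalism: bool = False

    def __post_init__(self) -> None:
        _check_total(self.feeding, FEEDING, ("animal", "producer"), "feeding")
        _check_total(self.tiering, TIERING, TIERING, "tiering")
        _check_total(self.motility, MOTILITY, MOTILITY, "motility")
        _check_total(self.size, SIZE_CLASSES, SIZE_CLASSES, "size")

    # -- predicates -----------------------------------------------------
    def allows(self, consumer: TraitProfile, resource: TraitProfile) -> bool:
        """All-rules-must-pass conjunction for an animal-animal link."""
        return (
            self.feeding[consumer.feeding]["animal"]
            and self.tiering[consumer.tiering][resource.tiering]
            and self.motility[consumer.motility][resource.motility]
            and self.size[consumer.size_class][resource.size_class]
        )

    def allows_producer(self, consumer: TraitProfile) -> bool:
        return self.feeding[consumer.feeding]["producer"]

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        # deep copies: editing the returned tables must not mutate the rules
        return {
            "feeding": copy.deepcopy(self.feeding),
            "tiering": copy.deepcopy(self.tiering),
            "motility": copy.deepcopy(self.motility),
            "size": copy.deepcopy(self.size),
            "allow_cannibalism": self.allow_cannibalism,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleSet":
        return cls(
            feeding=copy.deepcopy(d["feeding"]),
            tiering=copy.deepcopy(d["tiering"]),
            motility=copy.deepcopy(d["motility"]),
            size=copy.deepcopy(d["size"]),
            allow_cannibalism=bool(d.get("allow_cannibalism", False)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_ruleset(allow_cannibalism: bool = False) -> RuleSet:
    """The shipped default rule semantics.

    * feeding: predators take animal food only; suspension feeders and
      grazers take the producer; deposit and mining feeders take the
      producer (standing in for detritus).
    * tiering: pelagic consumers reach pelagic/erect/surficial resources;
      epifaunal consumers reach everything except the deep infauna;
      infaunal consumers reach the infaunal tiers.
    * motility: fast consumers catch anything; slower classes only catch
      resources of equal or lower speed rank.
    * size: a consumer takes resources up to one size class larger than
      itself, and anything smaller.
    """
    feeding = {
        "predator": {"animal": True, "producer": False},
        "suspension-feeder": {"animal": False, "producer": True},
        "grazer": {"animal": False, "producer": True},
        "deposit-feeder": {"animal": False, "producer": True},
        "mining": {"animal": False, "producer": True},
    }
    reach = {
        "pelagic": {"pelagic", "erect", "surficial"},
        "epifaunal": set(TIERING) - {"deep-infaunal"},
        "infaunal": {"semi-infaunal", "shallow-infaunal", "deep-infaunal"},
    }
    tiering = {
        c: {r: (r in reach[COARSE_TIERING_MAP[c]]) for r in TIERING} for c in TIERING
    }
    motility = {
        c: {r: (MOTILITY_RANK[c] == 3 or MOTILITY_RANK[r] <= MOTILITY_RANK[c])
            for r in MOTILITY}
        for c in MOTILITY
    }
    size = {
        c: {r: SIZE_CLASSES.index(r) <= SIZE_CLASSES.index(c) + 1
            for r in SIZE_CLASSES}
        for c in SIZE_CLASSES
    }
    return RuleSet(
        feeding=feeding,
        tiering=tiering,
        motility=motility,
        size=size,
        allow_cannibalism=allow_cannibalism,
    )
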