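"""Regenerate data/synthetic_toarcian_occurrences.csv.

SYNTHETIC STAND-IN: this script builds a fully synthetic occurrence
table sized to the summary shape of an Early Toarcian basin-scale
compilation — 162 unique macroinvertebrate species across four time
intervals, with the post-extinction interval collapsing to exactly 21
trait-combination guilds — so the ingestion and aggregation path can be
exercised end to end without any real deposit.  None of the species,
counts or trait assignments are real.

Usage: python scripts/make_standin_dataset.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from paleoweb import SynthConfig, generate_interval_series
from paleoweb.traits import INTERVALS

TARGET_SPECIES = 162
SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "data" / (
    "synthetic_toarcian_occurrences.csv"
)


def build() -> pd.DataFrame:
    cfg = SynthConfig(seed=SEED)
    series = generate_interval_series(cfg)
    rng = np.random.default_rng(SEED)

    # species are carried across intervals by guild identity; new guilds get
    # new species.  Extra species are then sprinkled over (interval, guild)
    # slots until exactly TARGET_SPECIES unique ids exist.
    species_of_guild: dict[str, list[str]] = {}
    counter = 0

    def new_species() -> str:
        nonlocal counter
        counter += 1
        return f"sp{counter:03d}"

    membership: dict[tuple[str, str], list[str]] = {}
    for interval in INTERVALS:
        for g in series[interval].consumer_guilds:
            if g.guild_id not in species_of_guild:
                species_of_guild[g.guild_id] = [new_species()]
            membership[(interval, g.guild_id)] = list(
                species_of_guild[g.guild_id]
            )

    slots = sorted(membership)
    while counter < TARGET_SPECIES:
        interval, gid = slots[int(rng.integers(len(slots)))]
        sp = new_species()
        species_of_guild[gid].append(sp)
        membership[(interval, gid)].append(sp)

    rows = []
    for (interval, gid), species in sorted(membership.items()):
        traits = series[interval].by_id(gid).traits.as_dict()
        for sp in species:
            row = {
                "species_id": sp,
                "interval": interval,
                "count": int(rng.integers(1, 40)),
            }
            row.update(traits)
            rows.append(row)
    df = pd.DataFrame(rows).sort_values(["interval", "species_id"])
    return df.reset_index(drop=True)


if __name__ == "__main__":
    df = build()
    OUT.parent.mkdir(exist_ok=True)
    df.to_csv(OUT, index=False)
    print(
        f"wrote {OUT} ({len(df)} rows, "
        f"{df['species_id'].nunique()} unique species)"
    )
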