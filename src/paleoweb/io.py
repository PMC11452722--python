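"""CSV readers and writers for occurrence tables and food webs.

All files are UTF-8 CSV with a header row.  Web I/O uses a node table
(guild_id, traits, producer flag, members) plus an edge list
(prey_id, predator_id); round-trips are lossless for labels, traits and
edges.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .community import (
    PRODUCER_ID,
    Guild,
    GuildSet,
    OccurrenceTable,
    SchemaError,
    producer_guild,
)
from .traits import TraitProfile
from .webs import FoodWeb

#: default expected occurrence-file column names; a ``schema`` mapping of
#: {canonical name: file column name} overrides any of them
DEFAULT_SCHEMA = {
    "species_id": "species_id",
    "interval": "interval",
    "count": "count",
    "motility": "motility",
    "tiering": "tiering",
    "feeding": "feeding",
    "size_class": "size_class",
    "calcification": "calcification",
}


def read_occurrences(path, schema: Optional[dict] = None) -> OccurrenceTable:
    """Read and validate an occurrence CSV.

    ``schema`` maps canonical column names (``species_id``, ``interval``,
    ``count``, the five trait names) to the file's column names.  ``count``
    and ``calcification`` are optional in the file (count defaults to 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    raw = pd.read_csv(path)
    df = pd.DataFrame(index=raw.index)
    for canonical, col in mapping.items():
        if col in raw.columns:
            df[canonical] = raw[col]
        elif canonical == "count":
            df[canonical] = 1
        elif canonical == "calcification":
            df[canonical] = None
        else:
            raise SchemaError(
                f"{path.name}: missing required column {col!r} "
                f"(for {canonical!r})"
            )
    return OccurrenceTable(df)


def write_occurrences(occ: OccurrenceTable, path) -> None:
    occ.df.to_csv(path, index=False)


def write_web(web: FoodWeb, nodes_path, edges_path) -> None:
    """Write a web as a node table and an edge list (prey_id, predator_id)."""
    node_df = web.node_table()
    node_df.insert(1, "interval", web.interval)
    node_df.to_csv(nodes_path, index=False)
    web.edge_table().to_csv(edges_path, index=False)


def read_web(nodes_path, edges_path) -> FoodWeb:
    nodes = pd.read_csv(nodes_path, keep_default_na=False, na_values=[""])
    edges = pd.read_csv(edges_path, keep_default_na=False, na_values=[""])
    interval = ""
    guilds = []
    for _, row in nodes.iterrows():
        if "interval" in nodes.columns and not pd.isna(row["interval"]):
            interval = str(row["interval"])
        members = (
            str(row["members"]).split(";")
            if "members" in nodes.columns and not pd.isna(row["members"])
            else []
        )
        if bool(row["is_producer"]):
            g = producer_guild()
            g.members = members
            guilds.append(g)
            continue
        calc = row.get("calcification")
        if pd.isna(calc) or calc == "":
            calc = None
        traits = TraitProfile(
            motility=row["motility"],
            tiering=row["tiering"],
            feeding=row["feeding"],
            size_class=row["size_class"],
            calcification=calc,
        )
        guilds.append(
            Guild(guild_id=str(row["guild_id"]), traits=traits, members=members)
        )
    gs = GuildSet(interval=interval, guilds=guilds)
    edge_list = [
        (str(r["prey_id"]), str(r["predator_id"])) for _, r in edges.iterrows()
    ]
    consumers = GuildSet(
        interval=interval, guilds=[g for g in guilds if not g.is_producer]
    )
    web = FoodWeb.from_guilds(consumers, edge_list)
    # restore producer members if any were recorded
    prod_members = next((g.members for g in gs.guilds if g.is_producer), [])
    web.graph.nodes[PRODUCER_ID]["members"] = list(prod_members)
    return web
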