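"""The directed food-web container.

Edges run prey -> predator (direction of energy flow) throughout the
package.  Every web carries exactly one producer node, which anchors all
primary consumers and never has incoming edges.
"""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .community import PRODUCER_ID, Guild, GuildSet, producer_guild
from .traits import TraitProfile


class FoodWeb:
    """Directed trophic network over guild nodes, edge = prey -> predator."""

    def __init__(self, graph: nx.DiGraph, interval: str = ""):
        if PRODUCER_ID not in graph:
            raise ValueError("web must contain the producer node")
        if graph.in_degree(PRODUCER_ID) != 0:
            raise ValueError("producer node cannot have prey")
        for u, v in graph.edges():
            if u == v and not graph.graph.get("allow_cannibalism", False):
                raise ValueError(f"self-loop on {u!r} without cannibalism enabled")
        self.graph = graph
        self.interval = interval

    # -- construction ---------------------------------------------------
    @classmethod
    def from_guilds(
        cls,
        guilds: GuildSet,
        edges: Iterable[tuple[str, str]],
        allow_cannibalism: bool = False,
    ) -> "FoodWeb":
        g = nx.DiGraph(allow_cannibalism=allow_cannibalism)
        g.add_node(PRODUCER_ID, traits=None, members=[], is_producer=True)
        for guild in guilds.consumer_guilds:
            g.add_node(
                guild.guild_id,
                traits=guild.traits,
                members=list(guild.members),
                is_producer=False,
            )
        for prey, pred in edges:
            if prey not in g or pred not in g:
                raise ValueError(f"edge endpoint missing: {(prey, pred)}")
            g.add_edge(prey, pred)
        return cls(g, interval=guilds.interval)

    # -- accessors ------------------------------------------------------
    @property
    def producer(self) -> str:
        return PRODUCER_ID

    def nodes(self, include_producer: bool = True) -> list[str]:
        ns = list(self.graph.nodes)
        if not include_producer:
            ns = [n for n in ns if n != PRODUCER_ID]
        return ns

    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def traits(self, node: str) -> Optional[TraitProfile]:
        return self.graph.nodes[node].get("traits")

    def members(self, node: str) -> list[str]:
        return list(self.graph.nodes[node].get("members", []))

    def prey(self, node: str) -> set[str]:
        return set(self.graph.predecessors(node))

    def predators(self, node: str) -> set[str]:
        return set(self.graph.successors(node))

    def richness(self, include_producer: bool = False) -> int:
        return len(self.nodes(include_producer=include_producer))

    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def guild_set(self) -> GuildSet:
        guilds = [producer_guild()]
        for n in self.nodes(include_producer=False):
            guilds.append(
                Guild(
                    guild_id=n,
                    traits=self.traits(n),
                    members=self.members(n),
                )
            )
        return GuildSet(interval=self.interval, guilds=guilds)

    def subweb(self, keep: Iterable[str]) -> "FoodWeb":
        """Induced sub-web on ``keep`` plus the producer."""
        keep = set(keep) | {PRODUCER_ID}
        return FoodWeb(self.graph.subgraph(keep).copy(), interval=self.interval)

    def copy(self) -> "FoodWeb":
        return FoodWeb(self.graph.copy(), interval=self.interval)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FoodWeb):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        if set(self.graph.edges) != set(other.graph.edges):
            return False
        return all(
            self.traits(n) == other.traits(n)
            and sorted(self.members(n)) == sorted(other.members(n))
            for n in self.graph.nodes
        )

    def __repr__(self) -> str:
        return (
            f"FoodWeb(interval={self.interval!r}, "
            f"S={self.richness()}, L={self.n_links()})"
        )

    # -- tabular form ---------------------------------------------------
    def node_table(self) -> pd.DataFrame:
        rows = []
        for n in sorted(self.graph.nodes):
            t = self.traits(n)
            row = {"guild_id": n, "is_producer": n == PRODUCER_ID}
            row.update(
                t.as_dict()
                if t is not None
                else dict.fromkeys(
                    ("motility", "tiering", "feeding", "size_class", "calcification")
                )
            )
            row["members"] = ";".join(sorted(self.members(n)))
            rows.append(row)
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.graph.edges), columns=["prey_id", "predator_id"]
        )
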