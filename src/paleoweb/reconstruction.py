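"""Feasible-web construction from guild traits and feeding rules.

This is the inference step: every feeding link permitted by the rule
tables is included (no subsampling toward empirical link distributions),
so the output is the complete *feasible* web for the community.
"""

from __future__ import annotations

import itertools

from .community import GuildSet
from .rules import RuleSet
from .webs import FoodWeb


def infer_links(guilds: GuildSet, rules: RuleSet) -> FoodWeb:
    """Build the feasible web: edge (r -> c) iff all per-trait rules pass.

    A producer node is always added, with an edge to every guild whose
    feeding mode passes the producer rule, so that primary consumers are
    not mistaken for primary producers.  Consumers left with zero prey are
    permitted (see :func:`preyless_report`).
    """
    edges: list[tuple[str, str]] = []
    consumers = guilds.consumer_guilds
    for g in consumers:
        if rules.allows_producer(g.traits):
            edges.append(("producer", g.guild_id))
    for r, c in itertools.product(consumers, consumers):
        if r.guild_id == c.guild_id and not rules.allow_cannibalism:
            continue
        if rules.allows(c.traits, r.traits):
            edges.append((r.guild_id, c.guild_id))
    return FoodWeb.from_guilds(
        guilds, edges, allow_cannibalism=rules.allow_cannibalism
    )


def preyless_report(web: FoodWeb) -> list[str]:
    """Guild ids of non-producer nodes with no prey at all (in-degree 0)."""
    return sorted(
        n for n in web.nodes(include_producer=False) if web.graph.in_degree(n) == 0
    )
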