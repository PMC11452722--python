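import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paleoweb import (
    FoodWeb,
    Guild,
    GuildSet,
    SynthConfig,
    TraitProfile,
    default_ruleset,
    generate_community,
    infer_links,
)
from paleoweb.traits import FEEDING, MOTILITY, SIZE_CLASSES, TIERING

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

# distinct trait combinations used to label ad-hoc test nodes
_COMBOS = list(itertools.product(MOTILITY, TIERING, FEEDING, SIZE_CLASSES))


def make_profile(i: int) -> TraitProfile:
    m, t, f, s = _COMBOS[i]
    return TraitProfile(motility=m, tiering=t, feeding=f, size_class=s)


def make_web(names, edges, interval="pre") -> FoodWeb:
    """Web with named nodes carrying arbitrary-but-distinct trait profiles.

    ``edges`` are (prey, predator) pairs; the name "producer" refers to the
    producer node.
    """
    guilds = [
        Guild(guild_id=n, traits=make_profile(i)) for i, n in enumerate(names)
    ]
    gs = GuildSet(interval=interval, guilds=guilds)
    return FoodWeb.from_guilds(gs, edges)


@pytest.fixture
def rules():
    return default_ruleset()


@pytest.fixture
def chain_web():
    """producer -> A -> B -> C"""
    return make_web(
        ["A", "B", "C"], [("producer", "A"), ("A", "B"), ("B", "C")]
    )


def star_web(n: int) -> FoodWeb:
    """producer feeding n independent consumers (no secondary extinctions)."""
    names = [f"c{i}" for i in range(n)]
    return make_web(names, [("producer", c) for c in names])


@pytest.fixture
def random_feasible_web(rules):
    """Factory: seeded random community -> feasible web under default rules."""

    def build(seed: int, richness: int = 12) -> FoodWeb:
        cfg = SynthConfig(seed=seed)
        cfg.richness["pre"] = richness
        gs = generate_community(cfg, "pre", rules=rules)
        return infer_links(gs, rules)

    return build


def random_digraph(rng: np.random.Generator, n: int, p: float):
    """Erdos-Renyi-style digraph as a FoodWeb-free networkx graph."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(i, j)
    return g
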