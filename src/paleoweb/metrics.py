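"""Structural metrics, trophic levels and the three-node motif census.

Motifs use the standard S-naming of the food-web literature (edges read
prey -> predator):

* S1 — linear chain, A -> B -> C
* S2 — omnivory, A -> B -> C with the shortcut A -> C
* S4 — apparent competition, two resources sharing one consumer
* S5 — direct (exploitative) competition, one resource with two consumers

The census classifies **every** connected unordered triple into one of the
13 connected triad classes (patterns containing bidirectional edges form
their own classes), so the four reported motifs sit inside an exhaustive,
conservation-checkable partition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .community import PRODUCER_ID
from .webs import FoodWeb

# ---------------------------------------------------------------------------
# triad pattern machinery
#
# A triple (a, b, c) is encoded as 6 bits, one per ordered pair in the order
# (a,b), (b,a), (a,c), (c,a), (b,c), (c,b).  Canonical form = minimum code
# over the 6 relabellings of the triple.
# ---------------------------------------------------------------------------

_PAIRS = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))


def _permute_code(code: int, perm: tuple[int, int, int]) -> int:
    out = 0
    for bit, (i, j) in enumerate(_PAIRS):
        if code >> bit & 1:
            pi, pj = perm[i], perm[j]
            out |= 1 << _PAIRS.index((pi, pj))
    return out


def _build_tables() -> tuple[list[int], list[bool]]:
    canon, connected = [], []
    perms = list(itertools.permutations(range(3)))
    for code in range(64):
        canon.append(min(_permute_code(code, p) for p in perms))
        dyads = sum(
            1
            for k in range(3)
            if code >> (2 * k) & 1 or code >> (2 * k + 1) & 1
        )
        connected.append(dyads >= 2)
    return canon, connected


_CANON, _CONNECTED = _build_tables()


def _code_of(edges: set[tuple[int, int]]) -> int:
    return sum(1 << b for b, pair in enumerate(_PAIRS) if pair in edges)


#: canonical codes of the four reported motif classes
S1_CODE = _CANON[_code_of({(0, 1), (1, 2)})]          # chain
S2_CODE = _CANON[_code_of({(0, 1), (1, 2), (0, 2)})]  # omnivory
S4_CODE = _CANON[_code_of({(0, 2), (1, 2)})]          # apparent competition
S5_CODE = _CANON[_code_of({(0, 1), (0, 2)})]          # direct competition

_MOTIF_NAMES = {S1_CODE: "S1", S2_CODE: "S2", S4_CODE: "S4", S5_CODE: "S5"}


@dataclass
class MotifCounts:
    s1: int
    s2: int
    s4: int
    s5: int
    n_connected_triads: int
    census: dict = field(default_factory=dict)  # class label -> count

    @property
    def frequencies(self) -> dict:
        n = self.n_connected_triads
        if n == 0:
            return {"S1": 0.0, "S2": 0.0, "S4": 0.0, "S5": 0.0}
        return {
            "S1": self.s1 / n,
            "S2": self.s2 / n,
            "S4": self.s4 / n,
            "S5": self.s5 / n,
        }

    def as_dict(self) -> dict:
        return {"S1": self.s1, "S2": self.s2, "S4": self.s4, "S5": self.s5}


def triad_census(web, include_producer: bool = True) -> dict:
    """Counts of all 13 connected triad classes over unordered triples.

    Accepts a :class:`FoodWeb` or a bare ``networkx.DiGraph``.  Labels are
    S1/S2/S4/S5 for the reported motifs and ``T<code>`` (canonical pattern
    code) for the other nine classes.
    """
    graph = web.graph if isinstance(web, FoodWeb) else web
    nodes = [
        n
        for n in graph.nodes
        if include_producer or n != PRODUCER_ID
    ]
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in graph.edges:
        if u in index and v in index and u != v:
            adj[index[u], index[v]] = True
    counts: dict[int, int] = {}
    for i, j, k in itertools.combinations(range(n), 3):
        code = (
            (1 if adj[i, j] else 0)
            | (2 if adj[j, i] else 0)
            | (4 if adj[i, k] else 0)
            | (8 if adj[k, i] else 0)
            | (16 if adj[j, k] else 0)
            | (32 if adj[k, j] else 0)
        )
        if not _CONNECTED[code]:
            continue
        c = _CANON[code]
        counts[c] = counts.get(c, 0) + 1
    return {
        _MOTIF_NAMES.get(code, f"T{code}"): cnt for code, cnt in counts.items()
    }


def count_motifs(web, include_producer: bool = True) -> MotifCounts:
    """Exhaustive S1/S2/S4/S5 census (producer participates by default)."""
    census = triad_census(web, include_producer=include_producer)
    return MotifCounts(
        s1=census.get("S1", 0),
        s2=census.get("S2", 0),
        s4=census.get("S4", 0),
        s5=census.get("S5", 0),
        n_connected_triads=sum(census.values()),
        census=census,
    )


# ---------------------------------------------------------------------------
# trophic levels
# ---------------------------------------------------------------------------


def trophic_levels(web: FoodWeb) -> dict:
    """Prey-averaged trophic level per node (producer = 1).

    Each consumer's level is 1 + the mean level of its prey, solved as a
    linear system (so loops are handled, as in the cheddar toolchain).
    Preyless consumers, and consumers whose prey chains never reach the
    producer, have no defined level: they are returned as NaN with a
    warning and are excluded from web-level summaries.
    """
    import networkx as nx

    g = web.graph
    kept = set(g.nodes)
    # iteratively drop preyless non-producer nodes (their level is undefined,
    # and so is the level of anything fed only by them)
    changed = True
    while changed:
        changed = False
        for node in list(kept):
            if node == PRODUCER_ID:
                continue
            if not any(p in kept for p in g.predecessors(node)):
                kept.discard(node)
                changed = True
    # drop nodes with no prey path down to the producer (cycles with no
    # basal support make the linear system singular)
    reachable = set(nx.descendants(g.subgraph(kept), PRODUCER_ID)) | {PRODUCER_ID}
    dropped = set(g.nodes) - (kept & reachable)
    kept = kept & reachable
    if dropped:
        warnings.warn(
            f"trophic level undefined for {sorted(dropped)} "
            "(preyless or without basal support)",
            stacklevel=2,
        )
    order = sorted(kept)
    idx = {n: i for i, n in enumerate(order)}
    m = len(order)
    a = np.eye(m)
    b = np.ones(m)
    for node in order:
        i = idx[node]
        if node == PRODUCER_ID:
            continue
        prey = [p for p in g.predecessors(node) if p in kept]
        w = 1.0 / len(prey)
        for p in prey:
            a[i, idx[p]] -= w
    levels = np.linalg.solve(a, b)
    out = {n: float("nan") for n in g.nodes}
    out.update({n: float(levels[idx[n]]) for n in order})
    return out


def chain_trophic_levels(web: FoodWeb) -> dict:
    """Longest-chain trophic level (1 + max over prey), producer = 1.

    Computed on the condensation of the graph so that cycles (mutual
    predation between same-sized predators) receive a single shared value.
    """
    import networkx as nx

    g = web.graph
    cond = nx.condensation(g)
    mapping = cond.graph["mapping"]  # node -> scc index
    level: dict[int, float] = {}
    for scc in nx.topological_sort(cond):
        members = cond.nodes[scc]["members"]
        if PRODUCER_ID in members:
            level[scc] = 1.0
            continue
        prey_lvls = [level[p] for p in cond.predecessors(scc) if p in level]
        level[scc] = (1.0 + max(prey_lvls)) if prey_lvls else float("nan")
    return {n: level[mapping[n]] for n in g.nodes}


# ---------------------------------------------------------------------------
# structural metric vector
# ---------------------------------------------------------------------------

#: the nine headline structural metrics, in reporting order
METRIC_FIELDS = (
    "richness",
    "links",
    "connectance",
    "generality",
    "sd_generality",
    "vulnerability",
    "sd_vulnerability",
    "mean_tl",
    "max_tl",
)


@dataclass
class MetricVector:
    richness: int                 # node count excluding the producer
    richness_incl_producer: int
    links: int
    connectance: float            # L / S^2 with S including the producer
    generality: float             # mean prey per consumer (in-degree > 0)
    sd_generality: float
    vulnerability: float          # mean predators per resource (out-degree > 0)
    sd_vulnerability: float
    mean_tl: float                # prey-averaged, over nodes with defined level
    max_tl: float
    max_chain_tl: float           # longest-chain variant of max trophic level

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in METRIC_FIELDS}


def structural_metrics(
    web: FoodWeb,
    connectance_denominator: str = "S2",
    include_producer_in_s: bool = True,
) -> MetricVector:
    """Compute the full structural metric vector of a web.

    ``connectance_denominator`` is ``"S2"`` (directed, L/S^2, the default)
    or ``"S(S-1)"``; ``include_producer_in_s`` controls whether S counts
    the producer node.
    """
    g = web.graph
    if web.richness(include_producer=True) == 0:
        raise ValueError("empty web")
    s_excl = web.richness(include_producer=False)
    s_incl = web.richness(include_producer=True)
    s = s_incl if include_producer_in_s else s_excl
    links = g.number_of_edges()
    if connectance_denominator == "S2":
        denom = s * s
    elif connectance_denominator == "S(S-1)":
        denom = s * (s - 1)
    else:
        raise ValueError(f"unknown denominator {connectance_denominator!r}")
    connectance = links / denom if denom else float("nan")

    in_deg = [d for _, d in g.in_degree() if d > 0]
    out_deg = [d for _, d in g.out_degree() if d > 0]
    generality = float(np.mean(in_deg)) if in_deg else 0.0
    sd_generality = float(np.std(in_deg)) if in_deg else 0.0
    vulnerability = float(np.mean(out_deg)) if out_deg else 0.0
    sd_vulnerability = float(np.std(out_deg)) if out_deg else 0.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tl = trophic_levels(web)
        ctl = chain_trophic_levels(web)
    defined = [v for v in tl.values() if np.isfinite(v)]
    cdefined = [v for v in ctl.values() if np.isfinite(v)]
    return MetricVector(
        richness=s_excl,
        richness_incl_producer=s_incl,
        links=links,
        connectance=connectance,
        generality=generality,
        sd_generality=sd_generality,
        vulnerability=vulnerability,
        sd_vulnerability=sd_vulnerability,
        mean_tl=float(np.mean(defined)) if defined else float("nan"),
        max_tl=float(np.max(defined)) if defined else float("nan"),
        max_chain_tl=float(np.max(cdefined)) if cdefined else float("nan"),
    )
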