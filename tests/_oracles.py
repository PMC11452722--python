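"""Independent brute-force oracles used only by the test suite.

Everything here is written from the definitions, without reusing the
package's implementations, so agreement is a genuine two-route check.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Optional, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# motifs: explicit pattern matching over labelled triples
# ---------------------------------------------------------------------------


def brute_force_motifs(edges: Iterable[tuple], nodes: Sequence) -> dict:
    """Count S1/S2/S4/S5 and connected triples by explicit enumeration.

    For every unordered triple, try all 6 labelings (a, b, c) and test the
    exact edge set of each motif definition:
    S1 a->b->c; S2 a->b->c plus a->c; S4 a->c, b->c; S5 a->b, a->c.
    """
    eset = {(u, v) for u, v in edges if u != v}
    counts = {"S1": 0, "S2": 0, "S4": 0, "S5": 0, "connected": 0}
    for triple in itertools.combinations(nodes, 3):
        sub = {
            (u, v)
            for u, v in itertools.permutations(triple, 2)
            if (u, v) in eset
        }
        if not sub:
            continue
        touched = {u for e in sub for u in e}
        if len(touched) < 3:
            continue
        counts["connected"] += 1
        for a, b, c in itertools.permutations(triple):
            if sub == {(a, b), (b, c)}:
                counts["S1"] += 1
                break
            if sub == {(a, b), (b, c), (a, c)}:
                counts["S2"] += 1
                break
            if sub == {(a, c), (b, c)}:
                counts["S4"] += 1
                break
            if sub == {(a, b), (a, c)}:
                counts["S5"] += 1
                break
    return counts


# ---------------------------------------------------------------------------
# cascades: step-by-step re-simulation from the raw edge list
# ---------------------------------------------------------------------------


def cascade_oracle(
    edges: Iterable[tuple],
    nodes: Sequence[str],
    producer: str,
    sequence: Sequence[str],
    stop_richness: int,
    rng: Optional[np.random.Generator] = None,
) -> set[str]:
    """Survivor set after trait-ordered removals with secondary cascades.

    Recomputes every consumer's remaining prey from the raw edge list at
    every propagation step; when ``rng`` is given, doomed consumers are
    removed one at a time in random order (fixpoint-uniqueness probe).
    """
    eset = list(edges)
    prey0 = {n: {u for u, v in eset if v == n} for n in nodes}
    consumers = {n for n in nodes if prey0[n]}
    alive = {n for n in nodes if n != producer}
    for target in sequence:
        if len(alive) <= stop_richness:
            break
        if target not in alive:
            continue
        alive.discard(target)
        while True:
            doomed = sorted(
                n
                for n in alive
                if n in consumers
                and not {p for p in prey0[n] if p == producer or p in alive}
            )
            if not doomed:
                break
            if rng is not None:
                alive.discard(doomed[int(rng.integers(len(doomed)))])
            else:
                alive.difference_update(doomed)
    return alive


# ---------------------------------------------------------------------------
# metrics: naive recomputation from the edge list
# ---------------------------------------------------------------------------


def naive_metrics(edges: Iterable[tuple], nodes: Sequence[str], producer: str) -> dict:
    eset = list(edges)
    in_deg = {n: sum(1 for _, v in eset if v == n) for n in nodes}
    out_deg = {n: sum(1 for u, _ in eset if u == n) for n in nodes}
    s = len(nodes)
    links = len(eset)
    gen = [in_deg[n] for n in nodes if in_deg[n] > 0]
    vul = [out_deg[n] for n in nodes if out_deg[n] > 0]
    return {
        "richness": s - 1,
        "links": links,
        "connectance": links / s**2,
        "generality": float(np.mean(gen)) if gen else 0.0,
        "sd_generality": float(np.std(gen)) if gen else 0.0,
        "vulnerability": float(np.mean(vul)) if vul else 0.0,
        "sd_vulnerability": float(np.std(vul)) if vul else 0.0,
    }


def fixed_point_trophic_levels(
    edges: Iterable[tuple], nodes: Sequence[str], producer: str, tol: float = 1e-12
) -> dict:
    """Iterative prey-averaged levels (acyclic webs: converges to the fix
    point of TL_i = 1 + mean prey TL)."""
    prey = {n: [u for u, v in edges if v == n] for n in nodes}
    tl = dict.fromkeys(nodes, 1.0)
    for _ in range(10000):
        new = {}
        for n in nodes:
            if n == producer or not prey[n]:
                new[n] = 1.0
            else:
                new[n] = 1.0 + float(np.mean([tl[p] for p in prey[n]]))
        delta = max(abs(new[n] - tl[n]) for n in nodes)
        tl = new
        if delta < tol:
            break
    return tl


# ---------------------------------------------------------------------------
# feasible-web reconstruction: independent double loop over the rules
# ---------------------------------------------------------------------------


def brute_force_feasible_edges(guilds, rules) -> set[tuple]:
    """Re-derive the feasible edge set with an explicit double loop.

    Re-states the four per-trait predicates from the default rule
    semantics directly (rather than calling RuleSet.allows), so it only
    applies to the default rule set.
    """
    from paleoweb.traits import COARSE_TIERING_MAP, MOTILITY_RANK, SIZE_CLASSES

    producer_ok = {"suspension-feeder", "grazer", "deposit-feeder", "mining"}
    reach = {
        "pelagic": {"pelagic", "erect", "surficial"},
        "epifaunal": {"pelagic", "erect", "surficial", "semi-infaunal",
                      "shallow-infaunal"},
        "infaunal": {"semi-infaunal", "shallow-infaunal", "deep-infaunal"},
    }
    edges = set()
    gl = guilds.consumer_guilds
    for c in gl:
        if c.traits.feeding in producer_ok:
            edges.add(("producer", c.guild_id))
    for c in gl:
        for r in gl:
            if c.guild_id == r.guild_id:
                continue
            ct, rt = c.traits, r.traits
            if ct.feeding != "predator":
                continue
            if rt.tiering not in reach[COARSE_TIERING_MAP[ct.tiering]]:
                continue
            if MOTILITY_RANK[ct.motility] != 3 and (
                MOTILITY_RANK[rt.motility] > MOTILITY_RANK[ct.motility]
            ):
                continue
            if SIZE_CLASSES.index(rt.size_class) > SIZE_CLASSES.index(ct.size_class) + 1:
                continue
            edges.add((r.guild_id, c.guild_id))
    return edges
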