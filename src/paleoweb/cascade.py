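"""Trait-ordered primary extinctions with secondary-extinction cascades.

A scenario fixes an ordering of the web's guilds into trait levels (e.g.
infaunal -> epifaunal -> pelagic for tiering); each replicate shuffles the
guilds *within* each level, removes them one at a time, and after every
primary removal propagates secondary extinctions — a consumer goes extinct
the moment it has lost all of its prey — to a fixpoint before checking the
stopping rule.  The producer node anchors the web: it is never removed,
primarily or secondarily, so guilds feeding on the producer can only be
lost to primary removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .community import PRODUCER_ID
from .traits import CALCIFICATION, COARSE_TIERING, MOTILITY, SIZE_CLASSES
from .webs import FoodWeb

#: the 13 canonical scenarios: trait plus direction of the primary sequence
SCENARIO_NAMES = (
    "random",
    "size_LS",
    "size_SL",
    "tiering_IP",
    "tiering_PI",
    "motility_FN",
    "motility_NF",
    "calcification_HL",
    "calcification_LH",
    "generality_LH",
    "generality_HL",
    "vulnerability_LH",
    "vulnerability_HL",
)


@dataclass(frozen=True)
class Scenario:
    name: str
    n_replicates: int = 50
    recompute_degrees: bool = False  # degree orderings on the eroding web

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(
                f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}"
            )


def _levels_for(web: FoodWeb, name: str) -> list[list[str]]:
    """Ordered trait levels (first level goes extinct first)."""
    nodes = web.nodes(include_producer=False)
    if name == "random":
        return [list(nodes)]

    def group(keyfn, order) -> list[list[str]]:
        buckets: dict = {k: [] for k in order}
        for n in nodes:
            buckets[keyfn(n)].append(n)
        return [buckets[k] for k in order if buckets[k]]

    t = web.traits
    if name in ("size_LS", "size_SL"):
        order = list(reversed(SIZE_CLASSES)) if name == "size_LS" else list(SIZE_CLASSES)
        return group(lambda n: t(n).size_class, order)
    if name in ("tiering_IP", "tiering_PI"):
        order = ["infaunal", "epifaunal", "pelagic"]
        if name == "tiering_PI":
            order = list(reversed(order))
        assert set(order) == set(COARSE_TIERING)
        return group(lambda n: t(n).coarse_tiering, order)
    if name in ("motility_FN", "motility_NF"):
        # fast -> slow -> facultative -> non-motile, by decreasing speed rank
        order = list(MOTILITY) if name == "motility_FN" else list(reversed(MOTILITY))
        return group(lambda n: t(n).motility, order)
    if name in ("calcification_HL", "calcification_LH"):
        order = (
            list(reversed(CALCIFICATION))
            if name == "calcification_HL"
            else list(CALCIFICATION)
        )
        # guilds without a calcification value form a final tier
        order = order + [None]
        vals = {t(n).calcification for n in nodes}
        if vals == {None}:
            raise ValueError(
                "calcification scenario on a web with no calcification values"
            )
        return group(lambda n: t(n).calcification, order)
    if name.startswith(("generality", "vulnerability")):
        deg = (
            dict(web.graph.in_degree())
            if name.startswith("generality")
            else dict(web.graph.out_degree())
        )
        ascending = name.endswith("_LH")
        distinct = sorted({deg[n] for n in nodes}, reverse=not ascending)
        return group(lambda n: deg[n], distinct)
    raise AssertionError(name)


def order_primary_sequence(
    web: FoodWeb, scenario: Scenario, rng: np.random.Generator
) -> list[str]:
    """One primary-extinction sequence: trait levels in scenario order,
    uniformly shuffled within each level.  Never contains the producer.

    Degree-based scenarios use the intact web's in-/out-degrees (the
    sequence is fixed up front); set ``Scenario.recompute_degrees`` to
    re-rank survivors after every removal instead.
    """
    seq: list[str] = []
    for level in _levels_for(web, scenario.name):
        level = sorted(level)
        rng.shuffle(level)
        seq.extend(level)
    return seq


@dataclass
class CascadeResult:
    """Ordered extinction log plus the surviving community."""

    events: list[tuple[int, str, str]]  # (step, guild_id, "primary"|"secondary")
    survivors: frozenset[str]           # non-producer guilds still alive
    stop_reason: str                    # "stop_richness" | "sequence_exhausted"
    web: Optional[FoodWeb] = field(default=None, repr=False)
    replicate_seed: Optional[int] = None

    @property
    def surviving_web(self) -> FoodWeb:
        if self.web is None:
            raise ValueError("source web not attached")
        return self.web.subweb(self.survivors)

    @property
    def final_richness(self) -> int:
        return len(self.survivors)

    def n_secondary(self) -> int:
        return sum(1 for _, _, cause in self.events if cause == "secondary")


class _Engine:
    """Adjacency-list cascade engine, built once per web and reused."""

    def __init__(self, web: FoodWeb):
        self.web = web
        self.nodes = web.nodes(include_producer=False)
        self.prey = {n: frozenset(web.graph.predecessors(n)) for n in self.nodes}
        self.preds = {n: frozenset(web.graph.successors(n)) for n in self.nodes}
        self.preds[PRODUCER_ID] = frozenset(web.graph.successors(PRODUCER_ID))
        # only guilds that started with prey can lose "all of their resources"
        self.consumers = {n for n in self.nodes if self.prey[n]}

    def run(
        self,
        sequence: Sequence[str],
        stop_richness: int,
        replicate_seed: Optional[int] = None,
    ) -> CascadeResult:
        alive = set(self.nodes)
        n_prey = {n: len(self.prey[n]) for n in self.nodes}
        events: list[tuple[int, str, str]] = []
        stop_reason = "sequence_exhausted"
        step = 0
        for target in sequence:
            if len(alive) <= stop_richness:
                stop_reason = "stop_richness"
                break
            step += 1
            if target not in alive:
                continue  # already lost secondarily; the removal is a no-op
            alive.discard(target)
            events.append((step, target, "primary"))
            stack = [target]
            while stack:
                gone = stack.pop()
                for pred in self.preds[gone]:
                    if pred not in alive:
                        continue
                    n_prey[pred] -= 1
                    if n_prey[pred] == 0 and pred in self.consumers:
                        alive.discard(pred)
                        events.append((step, pred, "secondary"))
                        stack.append(pred)
        else:
            if len(alive) <= stop_richness:
                stop_reason = "stop_richness"
        return CascadeResult(
            events=events,
            survivors=frozenset(alive),
            stop_reason=stop_reason,
            web=self.web,
            replicate_seed=replicate_seed,
        )


def run_cascade(
    web: FoodWeb, sequence: Sequence[str], stop_richness: int
) -> CascadeResult:
    """Remove guilds in ``sequence`` order, cascading after each removal.

    Stops at the first state with richness (non-producer guilds)
    <= ``stop_richness``; a cascade may overshoot below it, because each
    primary removal plus its secondary fallout is atomic.  If the sequence
    runs out first the result is flagged ``sequence_exhausted``.
    """
    bad = [g for g in sequence if g == PRODUCER_ID]
    if bad:
        raise ValueError("producer cannot appear in a primary sequence")
    return _Engine(web).run(sequence, stop_richness)


def run_scenario_ensemble(
    web: FoodWeb,
    scenario: Scenario,
    stop_richness: int,
    n_replicates: Optional[int] = None,
    seed: int = 0,
) -> list[CascadeResult]:
    """Independent replicates with per-replicate derived RNG streams.

    Replicate ``r`` uses ``np.random.default_rng([seed, scenario_index, r])``,
    so results do not depend on execution order and ensembles are
    reproducible from the master seed alone.
    """
    n = n_replicates if n_replicates is not None else scenario.n_replicates
    engine = _Engine(web)
    scen_idx = SCENARIO_NAMES.index(scenario.name)
    out = []
    for r in range(n):
        rng = np.random.default_rng([seed, scen_idx, r])
        if scenario.recompute_degrees and scenario.name.startswith(
            ("generality", "vulnerability")
        ):
            result = _run_dynamic_degree(web, engine, scenario, stop_richness, rng, r)
        else:
            seq = order_primary_sequence(web, scenario, rng)
            result = engine.run(seq, stop_richness, replicate_seed=r)
        out.append(result)
    return out


def _run_dynamic_degree(web, engine, scenario, stop_richness, rng, replicate):
    """Degree ordering re-evaluated on the eroding web after each removal."""
    current = web
    alive = set(engine.nodes)
    events: list[tuple[int, str, str]] = []
    step = 0
    stop_reason = "sequence_exhausted"
    while alive:
        if len(alive) <= stop_richness:
            stop_reason = "stop_richness"
            break
        seq = order_primary_sequence(current, scenario, rng)
        if not seq:
            break
        step += 1
        partial = _Engine(current).run(seq[:1], stop_richness=0)
        for _, guild, cause in partial.events:
            events.append((step, guild, cause))
        alive = set(partial.survivors)
        current = web.subweb(alive)
    if len(alive) <= stop_richness:
        stop_reason = "stop_richness"
    return CascadeResult(
        events=events,
        survivors=frozenset(alive),
        stop_reason=stop_reason,
        web=web,
        replicate_seed=replicate,
    )
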