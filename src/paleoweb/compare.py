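"""Scoring simulated post-extinction webs against an empirical web.

Two complementary scores:

* the True Skill Statistic (TSS) on a guild presence/absence confusion
  matrix over a fixed guild universe (by default the pre-extinction
  community, on which primary and secondary extinction operate), and
* a mean normalised distance across a list of structural metrics and
  motif counts (13 by default: the nine structural metrics plus the four
  motif counts).

TSS = (TP*TN - FP*FN) / ((TP+FN)(FP+TN)), equivalently sensitivity +
specificity - 1; it is 1 for a perfect match, -1 for a perfect mismatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cascade import CascadeResult
from .metrics import METRIC_FIELDS, count_motifs, structural_metrics
from .webs import FoodWeb

#: default 13-metric list: 9 structural + 4 motif raw counts
DEFAULT_METRICS = tuple(METRIC_FIELDS) + ("S1", "S2", "S4", "S5")


@dataclass(frozen=True)
class TSSResult:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def tss(self) -> float:
        denom = (self.tp + self.fn) * (self.fp + self.tn)
        if denom == 0:
            return float("nan")  # degenerate margin; undefined by convention
        return (self.tp * self.tn - self.fp * self.fn) / denom

    @property
    def defined(self) -> bool:
        return not math.isnan(self.tss)

    def universe_size(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _survivor_ids(obj) -> set[str]:
    if isinstance(obj, FoodWeb):
        return set(obj.nodes(include_producer=False))
    if isinstance(obj, CascadeResult):
        return set(obj.survivors)
    return set(obj)


def tss(sim, emp, universe: Iterable[str]) -> TSSResult:
    """Confusion matrix of joint survival over ``universe``.

    TP: survives in both; TN: extinct in both; FP: survives only in the
    simulation; FN: survives only in the empirical web.  Guilds outside
    the universe (e.g. post-extinction immigrants) are ignored; the caller
    is responsible for choosing a universe containing both webs' shared
    ancestry (default elsewhere: the pre-extinction guild set).
    """
    uni = set(universe)
    sim_s = _survivor_ids(sim) & uni
    emp_s = _survivor_ids(emp) & uni
    tp = len(sim_s & emp_s)
    fp = len(sim_s - emp_s)
    fn = len(emp_s - sim_s)
    tn = len(uni) - tp - fp - fn
    return TSSResult(tp=tp, tn=tn, fp=fp, fn=fn)


def metric_values(web: FoodWeb, metrics: Sequence[str] = DEFAULT_METRICS) -> dict:
    """Structural + motif values of a web for the requested metric names."""
    vec = structural_metrics(web).as_dict()
    vec.update(count_motifs(web).as_dict())
    unknown = [m for m in metrics if m not in vec]
    if unknown:
        raise KeyError(f"unknown metrics {unknown}")
    return {m: float(vec[m]) for m in metrics}


def metric_distance(
    sim: dict,
    emp: dict,
    metrics: Sequence[str] = DEFAULT_METRICS,
    zero_scale: float = 1.0,
) -> float:
    """Mean per-metric relative absolute difference |sim-emp| / |emp|.

    Metrics whose empirical value is 0 fall back to an absolute difference
    on the ``zero_scale`` (i.e. |sim - emp| / zero_scale) so the mean stays
    finite.  Lower is better; 0 iff equal on the metric list.
    """
    if not metrics:
        raise ValueError("empty metric list")
    terms = []
    for m in metrics:
        s, e = float(sim[m]), float(emp[m])
        if e == 0.0:
            terms.append(abs(s - e) / zero_scale)
        else:
            terms.append(abs(s - e) / abs(e))
    return float(np.mean(terms))


def compare_ensemble(
    results: Sequence[CascadeResult],
    emp_web: FoodWeb,
    universe: Iterable[str],
    scenario_name: str = "",
    include_metric_distance: bool = True,
    metrics: Sequence[str] = DEFAULT_METRICS,
) -> pd.DataFrame:
    """One row per replicate: TSS and (optionally) the 13-metric distance."""
    emp_vals = metric_values(emp_web, metrics) if include_metric_distance else None
    rows = []
    for i, res in enumerate(results):
        row: dict = {"scenario": scenario_name, "replicate": i}
        row["tss"] = tss(res, emp_web, universe).tss
        if include_metric_distance:
            sim_vals = metric_values(res.surviving_web, metrics)
            for m in metrics:
                row[f"d_{m}"] = sim_vals[m] - emp_vals[m]
            row["metric_distance"] = metric_distance(sim_vals, emp_vals, metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def rank_scenarios(
    ensembles: dict,
    emp_web: FoodWeb,
    universe: Iterable[str],
    include_metric_distance: bool = True,
    metrics: Sequence[str] = DEFAULT_METRICS,
) -> pd.DataFrame:
    """Per-scenario mean/sd of TSS (and metric distance), with ranks.

    ``ensembles`` maps scenario name -> list of :class:`CascadeResult`.
    Ranking 1 = best: highest mean TSS, respectively lowest mean distance.
    """
    universe = set(universe)
    frames = [
        compare_ensemble(
            res,
            emp_web,
            universe,
            scenario_name=name,
            include_metric_distance=include_metric_distance,
            metrics=metrics,
        )
        for name, res in ensembles.items()
    ]
    per_rep = pd.concat(frames, ignore_index=True)
    agg = {"tss": ["mean", "std"]}
    if include_metric_distance:
        agg["metric_distance"] = ["mean", "std"]
    table = per_rep.groupby("scenario").agg(agg)
    table.columns = ["_".join(c) for c in table.columns]
    table = table.reset_index()
    table["rank_tss"] = table["tss_mean"].rank(ascending=False, method="min")
    if include_metric_distance:
        table["rank_distance"] = table["metric_distance_mean"].rank(
            ascending=True, method="min"
        )
    return table.sort_values("rank_tss", kind="stable").reset_index(drop=True)
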