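"""Gradient robustness: community fraction surviving vs fraction removed.

For each replicate one uniform random permutation of the non-producer
guilds is drawn and removed cumulatively with cascade propagation; for
each grid value x (1..99% of the community) the fraction of the original
community still alive after the first ceil(x*S/100) primary removals is
recorded.  R_x is then read off the mean curve by inverse interpolation:
the smallest primary-removal fraction whose mean *total* loss (primary +
secondary) reaches x%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cascade import _Engine
from .webs import FoodWeb


@dataclass
class RobustnessCurve:
    x: np.ndarray            # percent of community primarily removed (1..99)
    mean: np.ndarray         # mean fraction of original community remaining
    sd: np.ndarray
    replicates: np.ndarray   # (n_replicates, len(x)) remaining fractions
    n_replicates: int
    seed: Optional[int]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "mean_remaining": self.mean,
                "sd_remaining": self.sd,
                "n": self.n_replicates,
            }
        )


@dataclass
class RxEstimate:
    x: float                  # target total loss, percent
    r_x: float                # proportion primarily deleted (NaN if unattained)
    attained: bool


def robustness_curve(
    web: FoodWeb,
    n_replicates: int = 500,
    seed: Optional[int] = None,
    x_grid: Optional[np.ndarray] = None,
) -> RobustnessCurve:
    """Monte-Carlo robustness curve over random deletion sequences.

    One permutation per replicate is reused across the whole x grid
    (nested removals), so each replicate's curve is non-increasing by
    construction.  The producer is excluded both from removal and from
    the remaining-fraction denominator.
    """
    engine = _Engine(web)
    s = len(engine.nodes)
    if s < 2:
        raise ValueError("need at least 2 non-producer guilds")
    if x_grid is None:
        x_grid = np.arange(1, 100)
    if seed is None:
        seed = int(np.random.default_rng().integers(2**31))
    x_grid = np.asarray(x_grid)
    ks = np.ceil(x_grid * s / 100.0).astype(int)
    rows = np.empty((n_replicates, len(x_grid)))
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        perm = sorted(engine.nodes)
        rng.shuffle(perm)
        alive_after = _alive_trajectory(engine, perm)
        rows[r] = [alive_after[k] / s for k in ks]
    return RobustnessCurve(
        x=x_grid,
        mean=rows.mean(axis=0),
        sd=rows.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros(len(x_grid)),
        replicates=rows,
        n_replicates=n_replicates,
        seed=seed,
    )


def _alive_trajectory(engine: _Engine, perm: list[str]) -> list[int]:
    """alive_after[k] = survivors after the first k primary removals."""
    alive = set(engine.nodes)
    n_prey = {n: len(engine.prey[n]) for n in engine.nodes}
    out = [len(alive)]
    for target in perm:
        if target in alive:
            alive.discard(target)
            stack = [target]
            while stack:
                gone = stack.pop()
                for pred in engine.preds[gone]:
                    if pred not in alive:
                        continue
                    n_prey[pred] -= 1
                    if n_prey[pred] == 0 and pred in engine.consumers:
                        alive.discard(pred)
                        stack.append(pred)
        out.append(len(alive))
    return out


def exact_robustness_curve(
    web: FoodWeb, x_grid: Optional[np.ndarray] = None
) -> RobustnessCurve:
    """Exact expectation over *all* permutations (small webs only).

    Full enumeration of deletion sequences; factorial cost, intended for
    webs with at most ~8 non-producer guilds as an oracle/reference.
    """
    import itertools

    engine = _Engine(web)
    s = len(engine.nodes)
    if x_grid is None:
        x_grid = np.arange(1, 100)
    x_grid = np.asarray(x_grid)
    ks = np.ceil(x_grid * s / 100.0).astype(int)
    perms = list(itertools.permutations(sorted(engine.nodes)))
    rows = np.empty((len(perms), len(x_grid)))
    for i, perm in enumerate(perms):
        alive_after = _alive_trajectory(engine, list(perm))
        rows[i] = [alive_after[k] / s for k in ks]
    return RobustnessCurve(
        x=x_grid,
        mean=rows.mean(axis=0),
        sd=rows.std(axis=0, ddof=1),
        replicates=rows,
        n_replicates=len(perms),
        seed=None,
    )


def r_x(curve: RobustnessCurve, x_loss: float) -> RxEstimate:
    """Smallest primary-removal fraction whose mean total loss >= x_loss %.

    Linear inverse interpolation on the mean curve; flagged unattained if
    the loss level is never reached on the grid (e.g. a producer-anchored
    remnant persists).
    """
    target = x_loss / 100.0
    loss = 1.0 - curve.mean
    frac = curve.x / 100.0
    idx = np.nonzero(loss >= target)[0]
    if idx.size == 0:
        return RxEstimate(x=x_loss, r_x=float("nan"), attained=False)
    i = int(idx[0])
    if i == 0 or math.isclose(loss[i], target):
        return RxEstimate(x=x_loss, r_x=float(frac[i]), attained=True)
    # interpolate between the bracketing grid points
    x0, x1 = frac[i - 1], frac[i]
    y0, y1 = loss[i - 1], loss[i]
    r = x0 + (target - y0) * (x1 - x0) / (y1 - y0) if y1 > y0 else x1
    return RxEstimate(x=x_loss, r_x=float(r), attained=True)


def plot_robustness(curves: dict, ax=None):
    """Plot mean remaining fraction vs proportion removed for named curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        ax.plot(curve.x / 100.0, curve.mean, label=label)
    ax.set_xlabel("proportion of the community removed")
    ax.set_ylabel("proportion of the original community remaining")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
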