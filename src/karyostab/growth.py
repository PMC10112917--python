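"""Doubling-time estimation from cell-count growth curves.

Exponential growth ``N(t) = N0 * 2**(lambda * t)`` is fitted in log2 space by
ordinary least squares, which is the maximum-likelihood fit under
multiplicative log-normal noise and gives a closed-form confidence interval
for the doubling frequency ``lambda`` (doublings/h).  The doubling time is
``1/lambda``; a non-growing culture (``lambda <= 0``) has an undefined
doubling time, flagged with NaN rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GrowthCurve",
    "DoublingEstimate",
    "fit_doubling_time",
    "pool_replicates",
    "percent_improvement",
]


@dataclass
class GrowthCurve:
    """One replicate's viable-count time course (hours, cells)."""

    times: np.ndarray
    counts: np.ndarray
    replicate: str = "r1"
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape or self.times.ndim != 1:
            raise ValueError("times and counts must be 1-D of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts <= 0):
            raise ValueError(
                "counts must be positive (zero counts have no log; "
                "remove or re-assay those points)"
            )


@dataclass
class DoublingEstimate:
    """Fitted doubling frequency and its back-transformed doubling time."""

    lambda_hat: float
    doubling_time_h: float
    ci95_low: float
    ci95_high: float
    r_squared: float
    n_points: int

    @property
    def is_growing(self) -> bool:
        return math.isfinite(self.doubling_time_h)


def _estimate(slope: float, se: float, dof: int, r2: float, n: int) -> DoublingEstimate:
    if slope <= 0:
        return DoublingEstimate(slope, math.nan, math.nan, math.nan, r2, n)
    if se > 0 and dof > 0:
        tcrit = stats.t.ppf(0.975, dof)
        lo_lambda = slope - tcrit * se
        hi_lambda = slope + tcrit * se
    else:  # exact data: zero residual variance
        lo_lambda = hi_lambda = slope
    ci_low = 1.0 / hi_lambda
    ci_high = 1.0 / lo_lambda if lo_lambda > 0 else math.inf
    return DoublingEstimate(slope, 1.0 / slope, ci_low, ci_high, r2, n)


def fit_doubling_time(curve: GrowthCurve) -> DoublingEstimate:
    """OLS fit of ``log2(counts) = log2(N0) + lambda * t`` for one curve."""
    if curve.times.size < 3:
        raise ValueError("need >= 3 timepoints to fit a doubling time")
    res = stats.linregress(curve.times, np.log2(curve.counts))
    se = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return _estimate(
        float(res.slope), se, curve.times.size - 2,
        float(res.rvalue) ** 2, int(curve.times.size),
    )


def pool_replicates(curves: list[GrowthCurve]) -> DoublingEstimate:
    """Common-slope fit across replicates, each with its own intercept.

    Stacks all (t, log2 count) points and fits one doubling frequency shared
    by every replicate while letting each replicate have its own starting
    cell number.  All curves must share a condition label.
    """
    if not curves:
        raise ValueError("need at least one curve")
    conditions = {c.condition for c in curves}
    if len(conditions) > 1:
        raise ValueError(f"mixed condition labels {sorted(conditions)}: refusing to pool")
    t = np.concatenate([c.times for c in curves])
    y = np.concatenate([np.log2(c.counts) for c in curves])
    rep_labels = np.concatenate(
        [np.repeat(f"{i}:{c.replicate}", c.times.size) for i, c in enumerate(curves)]
    )
    dummies = (rep_labels[:, None] == np.unique(rep_labels)[None, :]).astype(float)
    X = np.column_stack([dummies, t])
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[-1])
    se = float(fit.bse[-1])
    if not math.isfinite(se):
        se = 0.0
    return _estimate(slope, se, int(fit.df_resid), float(fit.rsquared), t.size)


def percent_improvement(doubling_time_fast: float, doubling_time_slow: float) -> float:
    """Percentage reduction in doubling time: ``100 * (1 - fast/slow)``."""
    if doubling_time_fast <= 0 or doubling_time_slow <= 0:
        raise ValueError("doubling times must be positive")
    return 100.0 * (1.0 - doubling_time_fast / doubling_time_slow)
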