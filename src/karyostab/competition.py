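"""Clonal competition between XX and XO cells in mESC culture.

Female mouse embryonic stem cell cultures are progressively taken over by
cells that have lost one X chromosome (XO).  If both classes grow as simple
exponentials ``N(t) = N0 * 2**(lambda * t)`` with doubling frequencies
``lambda_xx`` and ``lambda_xo`` (units: doublings per hour, the reciprocal of
the doubling time), the XO proportion follows a logistic curve in time whose
slope on the log2-odds scale is the selection parameter
``delta_lambda = lambda_xo - lambda_xx``.

This module provides the deterministic closed form, an exact stochastic
(Gillespie) counterpart with optional XX→XO conversion and serial-passage
bottlenecks, and inference of ``delta_lambda`` from observed proportion time
courses by ordinary least squares on the log2-odds scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from ._gillespie import run_birth_conversion

__all__ = [
    "LN2",
    "CompetitionParams",
    "ProportionTrajectory",
    "CompetitionFit",
    "delta_lambda",
    "proportion_xo",
    "predict_crossing_time",
    "simulate_competition",
    "fit_competition",
    "relative_xx_yield",
    "UnsupportedConfigurationError",
    "PopulationGuardError",
    "InsufficientDataError",
    "NoCrossingError",
]

LN2 = math.log(2.0)


class UnsupportedConfigurationError(ValueError):
    """Closed-form requested for a configuration that only the simulator supports."""


class PopulationGuardError(RuntimeError):
    """Exact simulation aborted because the population exceeded the guard."""


class InsufficientDataError(ValueError):
    """Too few usable data points for a fit."""


class NoCrossingError(ValueError):
    """The proportion curve is flat (delta_lambda = 0): no crossing time exists."""


def delta_lambda(doubling_time_fast: float, doubling_time_slow: float) -> float:
    """Difference in doubling frequencies from two doubling times.

    Returns ``1/doubling_time_fast - 1/doubling_time_slow`` in h^-1.  The
    arguments are not reordered: swapping them flips the sign.

    Examples
    --------
    >>> round(delta_lambda(24.5, 43.3), 4)
    0.0177
    """
    if doubling_time_fast <= 0 or doubling_time_slow <= 0:
        raise ValueError("doubling times must be positive")
    return 1.0 / doubling_time_fast - 1.0 / doubling_time_slow


@dataclass(frozen=True)
class CompetitionParams:
    """Parameter vector of the two-clone competition model.

    Attributes
    ----------
    n_xx0, n_xo0:
        Initial XX and XO cell numbers (``n_xx0 + n_xo0 > 0``).
    lambda_xx, lambda_xo:
        Doubling frequencies in doublings/h; growth is ``N0 * 2**(lambda*t)``,
        so the per-cell stochastic division rate is ``lambda * ln 2``.
    conversion_rate:
        Rate (events per XX cell per hour) at which an XX cell becomes XO
        (X-chromosome loss converts a cell, it does not kill it).
    passage_interval_h, passage_survival:
        Optional serial-passage bottleneck: every ``passage_interval_h`` hours
        each cell survives independently with probability ``passage_survival``.
    """

    n_xx0: float
    n_xo0: float
    lambda_xx: float
    lambda_xo: float
    conversion_rate: float = 0.0
    passage_interval_h: float | None = None
    passage_survival: float | None = None

    def __post_init__(self) -> None:
        if self.n_xx0 < 0 or self.n_xo0 < 0 or self.n_xx0 + self.n_xo0 <= 0:
            raise ValueError("need n_xx0 >= 0, n_xo0 >= 0 and n_xx0 + n_xo0 > 0")
        if self.lambda_xx < 0 or self.lambda_xo < 0:
            raise ValueError("doubling frequencies must be >= 0")
        if self.conversion_rate < 0:
            raise ValueError("conversion_rate must be >= 0")
        if (self.passage_interval_h is None) != (self.passage_survival is None):
            raise ValueError("passage_interval_h and passage_survival go together")
        if self.passage_interval_h is not None:
            if self.passage_interval_h <= 0:
                raise ValueError("passage_interval_h must be > 0")
            if not 0 < self.passage_survival <= 1:
                raise ValueError("passage_survival must be in (0, 1]")

    def delta_lambda(self) -> float:
        return self.lambda_xo - self.lambda_xx

    @property
    def has_passaging(self) -> bool:
        return self.passage_interval_h is not None

    @property
    def is_closed_form(self) -> bool:
        """True when the two-exponential closed form applies."""
        return self.conversion_rate == 0 and not self.has_passaging


@dataclass
class ProportionTrajectory:
    """Time series of the XO proportion, optionally with observed class counts."""

    times: np.ndarray
    p_xo: np.ndarray
    counts_xx: np.ndarray | None = None
    counts_xo: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p_xo = np.asarray(self.p_xo, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.p_xo.shape:
            raise ValueError("times and p_xo must be 1-D and the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.p_xo < 0) | (self.p_xo > 1)):
            raise ValueError("p_xo must lie in [0, 1]")
        if (self.counts_xx is None) != (self.counts_xo is None):
            raise ValueError("counts_xx and counts_xo go together")
        if self.counts_xx is not None:
            self.counts_xx = np.asarray(self.counts_xx, dtype=float)
            self.counts_xo = np.asarray(self.counts_xo, dtype=float)
            tot = self.counts_xx + self.counts_xo
            ok = tot > 0
            if not np.allclose(
                self.p_xo[ok], self.counts_xo[ok] / tot[ok], atol=1e-6
            ):
                raise ValueError("p_xo inconsistent with counts")

    @property
    def has_counts(self) -> bool:
        return self.counts_xx is not None

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.times, "p_xo": self.p_xo}
        if self.has_counts:
            data["n_xx"] = self.counts_xx
            data["n_xo"] = self.counts_xo
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "") -> "ProportionTrajectory":
        counts_xx = frame["n_xx"].to_numpy() if "n_xx" in frame else None
        counts_xo = frame["n_xo"].to_numpy() if "n_xo" in frame else None
        return cls(
            times=frame["time_h"].to_numpy(),
            p_xo=frame["p_xo"].to_numpy(),
            counts_xx=counts_xx,
            counts_xo=counts_xo,
            label=label,
        )


@dataclass
class CompetitionFit:
    """OLS fit of log2-odds(p_xo) against time: slope is delta_lambda."""

    delta_lambda_hat: float
    log2_odds0_hat: float
    stderr_delta_lambda: float
    r_squared: float
    n_points_used: int
    n_points_dropped: int = 0


def _log2_odds0(params: CompetitionParams) -> float:
    if params.n_xo0 == 0:
        return -math.inf
    if params.n_xx0 == 0:
        return math.inf
    return math.log2(params.n_xo0 / params.n_xx0)


def proportion_xo(t, params: CompetitionParams):
    """Closed-form XO proportion at time ``t`` (hours) under pure competition.

    ``p(t) = N_xo0 2**(lambda_xo t) / (N_xx0 2**(lambda_xx t) + N_xo0 2**(lambda_xo t))``,
    evaluated on the log-odds scale so it never overflows for large ``t``.
    Only valid with ``conversion_rate == 0`` and no passaging; other
    configurations must use :func:`simulate_competition`.
    """
    if not params.is_closed_form:
        raise UnsupportedConfigurationError(
            "closed form requires conversion_rate=0 and no passaging; "
            "use simulate_competition for the extended model"
        )
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    l0 = _log2_odds0(params)
    if not math.isfinite(l0):
        out = np.broadcast_to(np.float64(0.0 if l0 < 0 else 1.0), t.shape).copy()
        return out if out.ndim else float(out)
    log2_odds = l0 + params.delta_lambda() * t
    p = special.expit(LN2 * log2_odds)
    return p if p.ndim else float(p)


def predict_crossing_time(params: CompetitionParams, p_target: float) -> float:
    """Time at which the closed-form XO proportion reaches ``p_target``.

    Inverts the logistic closed form:
    ``t = (log2(odds_target) - log2(n_xo0/n_xx0)) / delta_lambda``.
    The result is negative when the crossing lies in the past.
    """
    if not params.is_closed_form:
        raise UnsupportedConfigurationError(
            "crossing time is defined for the closed form only"
        )
    if not 0 < p_target < 1:
        raise ValueError("p_target must be in (0, 1)")
    dl = params.delta_lambda()
    if dl == 0:
        raise NoCrossingError("delta_lambda = 0: proportion is constant")
    l0 = _log2_odds0(params)
    if not math.isfinite(l0):
        raise ValueError("crossing time undefined when one class starts empty")
    return (math.log2(p_target / (1.0 - p_target)) - l0) / dl


def simulate_competition(
    params: CompetitionParams,
    t_end: float,
    record_times: Sequence[float],
    seed: int,
    max_population: float = 1e7,
) -> ProportionTrajectory:
    """Exact Gillespie simulation of the XX/XO birth process.

    Each XX cell divides at rate ``lambda_xx * ln 2`` and converts to XO at
    rate ``conversion_rate``; each XO cell divides at rate ``lambda_xo * ln 2``
    (so expected counts follow ``N0 * 2**(lambda t)``).  If passaging is
    configured, every cell survives each passage independently with
    probability ``passage_survival``; a record time coinciding with a passage
    reports the pre-passage state.  Fully reproducible given ``seed``.
    """
    record = np.asarray(record_times, dtype=float)
    if record.ndim != 1 or record.size == 0:
        raise ValueError("record_times must be a non-empty 1-D sequence")
    if np.any(np.diff(record) <= 0):
        raise ValueError("record_times must be strictly increasing")
    if record[0] < 0 or record[-1] > t_end:
        raise ValueError("record_times must lie in [0, t_end]")
    n_xx0 = int(round(params.n_xx0))
    n_xo0 = int(round(params.n_xo0))
    if n_xx0 + n_xo0 > max_population:
        raise PopulationGuardError(
            f"initial population {n_xx0 + n_xo0} exceeds guard {max_population:g}; "
            "rescale n0"
        )
    interval = params.passage_interval_h if params.has_passaging else 0.0
    survival = params.passage_survival if params.has_passaging else 1.0
    out_xx, out_xo, status = run_birth_conversion(
        n_xx0,
        n_xo0,
        params.lambda_xx * LN2,
        params.lambda_xo * LN2,
        params.conversion_rate,
        record,
        float(interval),
        float(survival),
        int(max_population),
        int(seed) & 0x7FFFFFFF,
    )
    if status != 0:
        raise PopulationGuardError(
            f"population exceeded guard {max_population:g} during simulation; "
            "rescale n0 or lower t_end"
        )
    tot = out_xx + out_xo
    p = np.divide(out_xo, tot, out=np.zeros(len(tot)), where=tot > 0)
    return ProportionTrajectory(
        times=record,
        p_xo=p,
        counts_xx=out_xx.astype(float),
        counts_xo=out_xo.astype(float),
        label="gillespie",
    )


def fit_competition(traj: ProportionTrajectory) -> CompetitionFit:
    """Estimate delta_lambda by OLS of log2-odds(p_xo) on time.

    Boundary observations (p_xo exactly 0 or 1) are handled by the
    Haldane–Anscombe correction (+0.5 to both class counts) when raw counts
    are available; without counts such points are dropped and reported via
    ``n_points_dropped``.
    """
    t = traj.times
    if traj.has_counts:
        xo = traj.counts_xo.astype(float)
        xx = traj.counts_xx.astype(float)
        boundary = (xo == 0) | (xx == 0)
        xo = np.where(boundary, xo + 0.5, xo)
        xx = np.where(boundary, xx + 0.5, xx)
        y = np.log2(xo / xx)
        dropped = 0
    else:
        keep = (traj.p_xo > 0) & (traj.p_xo < 1)
        dropped = int(np.sum(~keep))
        t = t[keep]
        y = np.log2(traj.p_xo[keep] / (1.0 - traj.p_xo[keep]))
    if t.size < 2:
        raise InsufficientDataError(
            f"need >= 2 usable timepoints, have {t.size} after exclusions"
        )
    res = stats.linregress(t, y)
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return CompetitionFit(
        delta_lambda_hat=float(res.slope),
        log2_odds0_hat=float(res.intercept),
        stderr_delta_lambda=stderr,
        r_squared=float(res.rvalue) ** 2,
        n_points_used=int(t.size),
        n_points_dropped=dropped,
    )


def relative_xx_yield(
    traj: ProportionTrajectory, doubling_time_h: float
) -> pd.DataFrame:
    """XX daughter-cell yield: XX fraction scaled by cumulative doublings.

    ``yield(t) = (1 - p_xo(t)) * 2**((t - t0) / doubling_time_h)``, so a pure
    XX culture doubles its yield every ``doubling_time_h`` hours and
    ``yield(t0) = 1 - p_xo(t0)``.
    """
    if doubling_time_h <= 0:
        raise ValueError("doubling_time_h must be > 0")
    t0 = traj.times[0]
    y = (1.0 - traj.p_xo) * np.exp2((traj.times - t0) / doubling_time_h)
    return pd.DataFrame({"time_h": traj.times, "xx_yield": y})
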