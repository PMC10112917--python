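"""Karyotype calling from two-channel X-linked reporter flow cytometry.

Cells carry GFP and mCherry reporters on opposite X chromosomes; naive mESCs
express both X's, so a double-positive event is XX while single-positive
events mark cells that lost the other X (XO-GFP or XO-mCherry).  Events below
both gates are reporter-uninformative (dead cells, doublets, silenced
reporters) and are excluded from the XO proportion.

Gating is rectangular with strict inequalities: an event exactly on a
threshold counts as negative for that channel.  Thresholds are either fixed
or derived per channel by Otsu's method on log10 intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .competition import ProportionTrajectory

__all__ = [
    "FlowEventTable",
    "GateThresholds",
    "KaryotypeFractions",
    "auto_threshold",
    "classify_events",
    "xx_fraction_timecourse",
]


@dataclass
class FlowEventTable:
    """Per-event two-channel intensities for one sample.

    Non-positive intensities (possible after compensation) are clipped to the
    smallest positive value observed in that channel, with a warning, so that
    log transforms are always defined.
    """

    gfp: np.ndarray
    mcherry: np.ndarray
    sample_id: str
    time_h: float | None = None
    passage: float | None = None

    def __post_init__(self) -> None:
        self.gfp = self._guard(np.asarray(self.gfp, dtype=float), "gfp")
        self.mcherry = self._guard(np.asarray(self.mcherry, dtype=float), "mcherry")
        if self.gfp.shape != self.mcherry.shape or self.gfp.ndim != 1:
            raise ValueError("gfp and mcherry must be 1-D of equal length")
        if self.gfp.size == 0:
            raise ValueError("need at least one event")

    def _guard(self, x: np.ndarray, name: str) -> np.ndarray:
        bad = x <= 0
        if np.any(bad):
            positive = x[~bad]
            if positive.size == 0:
                raise ValueError(f"all {name} intensities non-positive")
            floor = positive.min()
            warnings.warn(
                f"{self.sample_id}: clipped {int(bad.sum())} non-positive {name} "
                f"intensities to {floor:g}",
                stacklevel=3,
            )
            x = np.where(bad, floor, x)
        return x

    @property
    def n_events(self) -> int:
        return int(self.gfp.size)


@dataclass(frozen=True)
class GateThresholds:
    gfp_threshold: float
    mcherry_threshold: float
    method: str = "fixed"

    def __post_init__(self) -> None:
        if self.gfp_threshold <= 0 or self.mcherry_threshold <= 0:
            raise ValueError("thresholds must be strictly positive")


@dataclass
class KaryotypeFractions:
    """Counts of the four gate quadrants for one sample."""

    n_xx: int
    n_xo_gfp: int
    n_xo_mcherry: int
    n_double_neg: int

    @property
    def total(self) -> int:
        return self.n_xx + self.n_xo_gfp + self.n_xo_mcherry + self.n_double_neg

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {
            "xx": self.n_xx / t,
            "xo_gfp": self.n_xo_gfp / t,
            "xo_mcherry": self.n_xo_mcherry / t,
            "double_neg": self.n_double_neg / t,
        }

    @property
    def p_xo(self) -> float:
        """XO proportion among reporter-informative events."""
        informative = self.n_xx + self.n_xo_gfp + self.n_xo_mcherry
        if informative == 0:
            raise ValueError("no reporter-informative events")
        return (self.n_xo_gfp + self.n_xo_mcherry) / informative


def auto_threshold(intensities, n_bins: int = 256) -> float:
    """Otsu threshold on log10 intensities, returned on the original scale.

    Maximises the between-class variance of the ``n_bins``-bin histogram of
    log10 intensities; ties break toward the lowest threshold.  Being a
    log-scale method, the result is equivariant under rescaling of the
    intensities.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 50:
        raise ValueError("need >= 50 events for auto-thresholding")
    if np.any(x <= 0):
        raise ValueError("intensities must be positive (apply the floor guard first)")
    lx = np.log10(x)
    if lx.max() == lx.min():
        raise ValueError("degenerate input: all intensities equal")
    hist, edges = np.histogram(lx, bins=n_bins)
    w = hist.astype(float) / hist.sum()
    mids = 0.5 * (edges[:-1] + edges[1:])
    omega = np.cumsum(w)                    # mass of the lower class
    mu = np.cumsum(w * mids)                # unnormalised lower-class mean
    mu_total = mu[-1]
    denom = omega * (1.0 - omega)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = np.where(denom > 0, (mu_total * omega - mu) ** 2 / denom, -np.inf)
    sigma_b[-1] = -np.inf                   # no empty upper class
    k = int(np.argmax(sigma_b))             # first max == lowest threshold
    return float(10.0 ** edges[k + 1])


def classify_events(events: FlowEventTable, gates: GateThresholds) -> KaryotypeFractions:
    """Partition events into XX / XO-GFP / XO-mCherry / double-negative."""
    g = events.gfp > gates.gfp_threshold
    m = events.mcherry > gates.mcherry_threshold
    return KaryotypeFractions(
        n_xx=int(np.sum(g & m)),
        n_xo_gfp=int(np.sum(g & ~m)),
        n_xo_mcherry=int(np.sum(~g & m)),
        n_double_neg=int(np.sum(~g & ~m)),
    )


def xx_fraction_timecourse(
    samples: list[FlowEventTable],
    gates: GateThresholds,
    time_unit: str = "hours",
    passage_interval_h: float = 24.0,
) -> ProportionTrajectory:
    """XO-proportion trajectory from a series of flow samples.

    Double-negative events are excluded as reporter-uninformative; the
    returned trajectory carries informative class counts so that downstream
    fitting can use exact-count corrections.  With ``time_unit="passage"``
    the time axis is ``passage * passage_interval_h`` hours.
    """
    if not samples:
        raise ValueError("need at least one sample")
    if time_unit not in ("hours", "passage"):
        raise ValueError("time_unit must be 'hours' or 'passage'")
    rows = []
    for s in samples:
        if time_unit == "hours":
            if s.time_h is None:
                raise ValueError(f"{s.sample_id}: missing time_h label")
            t = float(s.time_h)
        else:
            if s.passage is None:
                raise ValueError(f"{s.sample_id}: missing passage label")
            t = float(s.passage) * passage_interval_h
        frac = classify_events(s, gates)
        rows.append((t, frac))
    rows.sort(key=lambda r: r[0])
    times = [r[0] for r in rows]
    if len(set(times)) != len(times):
        raise ValueError(
            "duplicate time labels within the series; split replicates into "
            "separate series"
        )
    n_xx = np.array([r[1].n_xx for r in rows], dtype=float)
    n_xo = np.array(
        [r[1].n_xo_gfp + r[1].n_xo_mcherry for r in rows], dtype=float
    )
    return ProportionTrajectory(
        times=np.array(times),
        p_xo=n_xo / (n_xx + n_xo),
        counts_xx=n_xx,
        counts_xo=n_xo,
        label="flow",
    )
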