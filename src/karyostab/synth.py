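"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator emulates the statistical structure the downstream analysis
assumes: exponential growth with multiplicative log-normal noise for count
curves, the exact two-class birth process plus per-class bivariate log-normal
reporter intensities for flow samples, and multinomial binned read counts
with a gamma positional-bias field and planted copy-number segments for
sequencing coverage.  Every generator takes an explicit integer seed
(replicate ``r`` of a design uses ``seed + r``) and returns its ground truth
alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .competition import CompetitionParams, ProportionTrajectory, simulate_competition
from .cnv import BinnedCoverage, GenomeBins
from .flow import FlowEventTable
from .growth import GrowthCurve

__all__ = [
    "FlowIntensityModel",
    "SimulationScenario",
    "CnvTruth",
    "gen_growth_counts",
    "gen_competition_culture",
    "gen_binned_reads",
    "gen_cnv_experiment",
]


def gen_growth_counts(
    lam: float,
    n0: float,
    times,
    cv: float,
    replicates: int,
    seed: int,
    condition: str = "synthetic",
) -> list[GrowthCurve]:
    """Exponential count curves with multiplicative log-normal noise.

    ``counts = n0 * 2**(lam*t) * exp(eps)`` with ``eps ~ N(0, sigma)`` and
    ``sigma = sqrt(ln(1 + cv**2))``, so ``cv`` is the coefficient of
    variation of the multiplicative noise.  Replicate ``r`` uses ``seed + r``.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    times = np.asarray(times, dtype=float)
    sigma = math.sqrt(math.log1p(cv * cv))
    curves = []
    for r in range(replicates):
        rng = np.random.default_rng(seed + r)
        eps = rng.normal(0.0, sigma, size=times.size) if sigma > 0 else 0.0
        counts = n0 * np.exp2(lam * times) * np.exp(eps)
        curves.append(
            GrowthCurve(times=times, counts=counts, replicate=f"r{r + 1}", condition=condition)
        )
    return curves


@dataclass(frozen=True)
class FlowIntensityModel:
    """Bivariate log-normal reporter intensities per karyotype class.

    Channel intensities are 10**N(mean, sd) with the class determining which
    channels sit at the high or the low mean (log10 scale): XX is high/high,
    XO-GFP high GFP / low mCherry, XO-mCherry the reverse.
    """

    log10_high: float = 3.0
    log10_low: float = 1.0
    log10_sd: float = 0.3

    def class_means(self, label: str) -> tuple[float, float]:
        return {
            "xx": (self.log10_high, self.log10_high),
            "xo_gfp": (self.log10_high, self.log10_low),
            "xo_mcherry": (self.log10_low, self.log10_high),
        }[label]


@dataclass(frozen=True)
class SimulationScenario:
    """Everything needed to simulate one reporter culture end to end."""

    competition: CompetitionParams
    events_per_sample: int = 5000
    xo_gfp_fraction: float = 0.5  # which X was lost, among XO cells
    intensity: FlowIntensityModel = field(default_factory=FlowIntensityModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.events_per_sample <= 0:
            raise ValueError("events_per_sample must be positive")
        if not 0 <= self.xo_gfp_fraction <= 1:
            raise ValueError("xo_gfp_fraction must be in [0, 1]")


_CLASSES = ("xx", "xo_gfp", "xo_mcherry")


def gen_competition_culture(
    scenario: SimulationScenario, record_times
) -> tuple[ProportionTrajectory, list[FlowEventTable], list[np.ndarray]]:
    """Simulate a culture and draw flow events at each recorded time.

    Runs the exact birth-process simulator, then at each timepoint samples
    ``events_per_sample`` events with class labels drawn from the realised
    class fractions and intensities from the per-class log-normal model.
    Returns the true trajectory, the event tables and the true labels.
    """
    record_times = np.asarray(record_times, dtype=float)
    traj = simulate_competition(
        scenario.competition, float(record_times[-1]), record_times, seed=scenario.seed
    )
    rng = np.random.default_rng(scenario.seed + 1_000_003)
    tables: list[FlowEventTable] = []
    labels: list[np.ndarray] = []
    for i, t in enumerate(traj.times):
        p_xo = traj.p_xo[i]
        probs = np.array(
            [
                1.0 - p_xo,
                p_xo * scenario.xo_gfp_fraction,
                p_xo * (1.0 - scenario.xo_gfp_fraction),
            ]
        )
        cls = rng.choice(3, size=scenario.events_per_sample, p=probs)
        gfp = np.empty(scenario.events_per_sample)
        mch = np.empty(scenario.events_per_sample)
        for c, name in enumerate(_CLASSES):
            sel = cls == c
            mg, mm = scenario.intensity.class_means(name)
            sd = scenario.intensity.log10_sd
            gfp[sel] = 10.0 ** rng.normal(mg, sd, size=int(sel.sum()))
            mch[sel] = 10.0 ** rng.normal(mm, sd, size=int(sel.sum()))
        tables.append(
            FlowEventTable(gfp=gfp, mcherry=mch, sample_id=f"t{t:g}", time_h=float(t))
        )
        labels.append(np.array(_CLASSES)[cls])
    return traj, tables, labels


@dataclass
class CnvTruth:
    """Planted copy-number segments (copy ratio relative to baseline 1.0)."""

    segments: list[tuple[str, int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, ratio in self.segments:
            if end <= start:
                raise ValueError(f"segment {chrom}:{start}-{end} has end <= start")
            if ratio <= 0:
                raise ValueError("copy ratio must be > 0")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.segments:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping truth segments on {chrom}")

    def copy_ratio_per_bin(self, bins: GenomeBins) -> np.ndarray:
        """Per-bin copy ratio (a bin takes a segment's ratio iff it overlaps)."""
        ratio = np.ones(bins.n_bins)
        bt = bins.table
        for chrom, start, end, r in self.segments:
            sel = (
                (bt["chrom"] == chrom)
                & (bt["start"].to_numpy() < end)
                & (bt["end"].to_numpy() > start)
            ).to_numpy()
            ratio[sel] = r
        return ratio

    def affected_bins(self, bins: GenomeBins) -> np.ndarray:
        return self.copy_ratio_per_bin(bins) != 1.0


def gen_binned_reads(
    bins: GenomeBins,
    truth: CnvTruth,
    depth: int,
    bias_dispersion: float,
    seed: int,
    sample_id: str = "s1",
    bias: np.ndarray | None = None,
) -> tuple[BinnedCoverage, np.ndarray]:
    """Multinomial binned read counts with positional bias and planted CNVs.

    Per-bin weight = gamma bias (shape ``bias_dispersion``, mean 1) x copy
    ratio x bin width; counts are Multinomial(depth, normalised weights).
    Passing the returned ``bias`` back in generates a matched library (e.g. a
    passage-0 reference) sharing the same positional bias field, which then
    cancels in log2 fold changes as it does between matched real libraries.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if bias_dispersion <= 0:
        raise ValueError("bias_dispersion must be positive")
    rng = np.random.default_rng(seed)
    if bias is None:
        bias = rng.gamma(shape=bias_dispersion, scale=1.0 / bias_dispersion, size=bins.n_bins)
    w = bias * truth.copy_ratio_per_bin(bins) * bins.widths
    counts = rng.multinomial(depth, w / w.sum())
    cov = BinnedCoverage(
        bins=bins,
        counts=pd.DataFrame({sample_id: counts}, index=bins.ids),
    )
    return cov, bias


def gen_cnv_experiment(
    bins: GenomeBins,
    truth: CnvTruth,
    depth: int,
    bias_dispersion: float,
    n_replicates: int,
    seed: int,
) -> tuple[BinnedCoverage, list[tuple[str, str]]]:
    """Replicated matched design: per replicate a p0 reference and a sample.

    Each replicate line gets its own gamma bias field, shared between its
    passage-0 reference (all copy ratios 1) and its evolved sample (planted
    ``truth``).  Returns the combined coverage matrix and the
    (sample, reference) pairs for :func:`call_aberrant_bins`.
    """
    columns: dict[str, np.ndarray] = {}
    pairs: list[tuple[str, str]] = []
    baseline = CnvTruth(segments=[])
    for r in range(n_replicates):
        ref_cov, bias = gen_binned_reads(
            bins, baseline, depth, bias_dispersion, seed + 2 * r, sample_id="ref"
        )
        smp_cov, _ = gen_binned_reads(
            bins, truth, depth, bias_dispersion, seed + 2 * r + 1,
            sample_id="smp", bias=bias,
        )
        ref_name = f"p0_rep{r + 1}"
        smp_name = f"evolved_rep{r + 1}"
        columns[ref_name] = ref_cov.counts["ref"].to_numpy()
        columns[smp_name] = smp_cov.counts["smp"].to_numpy()
        pairs.append((smp_name, ref_name))
    cov = BinnedCoverage(bins=bins, counts=pd.DataFrame(columns, index=bins.ids))
    return cov, pairs
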