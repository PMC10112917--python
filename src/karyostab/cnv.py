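"""Karyotype stability from binned sequencing coverage.

Reads are counted in fixed-width genome bins (1 Mb by default, BED-style
0-based half-open coordinates, assignment by read start).  Bins overlapping a
blacklist are flagged and excluded from every statistic.  Coverage is
depth-normalised as log2 counts per million with a small prior count, per-bin
log2 fold changes are taken against a matched passage-0 reference, and
aberrant bins are called by an exact conditional binomial test with
Benjamini–Hochberg control plus a minimum fold-change floor, with
replicate-consistency filtering across matched pairs.  Sample relationships
are summarised by classical (Torgerson) multidimensional scaling of the
log-fold-change profiles.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenomeBins",
    "BinnedCoverage",
    "BinCallResult",
    "make_bins",
    "count_reads_in_bins",
    "log_cpm",
    "bin_log2fc",
    "chromosome_coverage_fraction",
    "conditional_binomial_pvalues",
    "call_aberrant_bins",
    "mds_profiles",
]

# autosomes plus sex chromosomes, with or without the "chr" prefix
_CANONICAL = re.compile(r"^(chr)?([0-9]{1,2}|X|Y)$")


def is_canonical(chrom: str) -> bool:
    return bool(_CANONICAL.match(str(chrom)))


def _is_sex_chrom(chrom: str) -> bool:
    return str(chrom).removeprefix("chr") in ("X", "Y")


@dataclass
class GenomeBins:
    """Fixed-width tiling of canonical chromosomes with blacklist flags."""

    table: pd.DataFrame  # columns: chrom, start, end, blacklisted
    bin_size: int

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "blacklisted"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"bins table needs columns {sorted(required)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_bins(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> pd.Index:
        t = self.table
        return pd.Index(
            t["chrom"].astype(str) + ":" + t["start"].astype(str) + "-" + t["end"].astype(str)
        )

    @property
    def blacklisted(self) -> np.ndarray:
        return self.table["blacklisted"].to_numpy(dtype=bool)

    @property
    def widths(self) -> np.ndarray:
        return (self.table["end"] - self.table["start"]).to_numpy()


def make_bins(
    chrom_sizes: dict[str, int] | pd.DataFrame,
    bin_size: int = 1_000_000,
    blacklist: pd.DataFrame | None = None,
) -> GenomeBins:
    """Tile canonical chromosomes into ``bin_size`` bins and flag blacklist hits.

    ``chrom_sizes`` maps chromosome name to length (or a two-column frame
    ``chrom, length``).  Non-canonical contigs are dropped with a warning.
    The final bin of each chromosome is truncated at the chromosome end.  A
    bin is blacklisted iff it overlaps any blacklist interval by >= 1 bp.
    """
    if isinstance(chrom_sizes, pd.DataFrame):
        chrom_sizes = dict(zip(chrom_sizes.iloc[:, 0].astype(str), chrom_sizes.iloc[:, 1]))
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    dropped = [c for c in chrom_sizes if not is_canonical(c)]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} non-canonical contigs: {dropped[:5]}...")
    rows: list[tuple[str, int, int]] = []
    for chrom, size in chrom_sizes.items():
        if not is_canonical(chrom):
            continue
        size = int(size)
        if size <= 0:
            raise ValueError(f"{chrom}: chromosome size must be positive")
        starts = np.arange(0, size, bin_size)
        for s in starts:
            rows.append((str(chrom), int(s), int(min(s + bin_size, size))))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    flagged = np.zeros(len(table), dtype=bool)
    if blacklist is not None and len(blacklist):
        bl = blacklist.iloc[:, :3].copy()
        bl.columns = ["chrom", "start", "end"]
        if (bl["end"] <= bl["start"]).any():
            bad = bl[bl["end"] <= bl["start"]].iloc[0]
            raise ValueError(f"malformed blacklist interval {bad.tolist()} (end <= start)")
        for chrom, grp in bl.groupby("chrom"):
            sel = table["chrom"] == str(chrom)
            if not sel.any():
                continue
            bs = table.loc[sel, "start"].to_numpy()
            be = table.loc[sel, "end"].to_numpy()
            hit = np.zeros(len(bs), dtype=bool)
            for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
                hit |= (bs < e) & (be > s)  # half-open overlap >= 1 bp
            flagged[sel.to_numpy()] |= hit
    table["blacklisted"] = flagged
    return GenomeBins(table=table, bin_size=bin_size)


@dataclass
class BinnedCoverage:
    """Bins x samples count matrix plus sample metadata and discard tallies.

    Blacklisted bins carry counts but are excluded from library sizes and
    every downstream statistic.
    """

    bins: GenomeBins
    counts: pd.DataFrame  # index: bin ids, columns: samples
    samples: pd.DataFrame | None = None
    discarded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.counts) != self.bins.n_bins:
            raise ValueError("counts rows must match bins")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.library_sizes() <= 0).any():
            raise ValueError("every sample needs a positive library size")

    def library_sizes(self) -> pd.Series:
        """Per-sample total counts over non-blacklisted bins."""
        return self.counts.loc[~self.bins.blacklisted].sum(axis=0)


def count_reads_in_bins(
    read_positions: pd.DataFrame, bins: GenomeBins
) -> BinnedCoverage:
    """Count reads into bins by start position (half-open convention).

    ``read_positions`` needs columns ``chrom`` and ``pos`` and optionally
    ``sample``; without a sample column all reads form one sample "s1".
    Reads on unknown/dropped contigs or beyond the chromosome end go to a
    per-sample discard tally (with a warning), so column sums plus discards
    always equal the input read count.
    """
    df = read_positions.copy()
    if "sample" not in df.columns:
        df["sample"] = "s1"
    bt = bins.table
    chrom_offsets: dict[str, tuple[int, int]] = {}  # chrom -> (row offset, chrom length)
    for chrom, grp in bt.groupby("chrom", sort=False):
        chrom_offsets[str(chrom)] = (int(grp.index[0]), int(grp["end"].max()))
    n = bins.n_bins
    sample_names = list(dict.fromkeys(df["sample"].astype(str)))
    mat = np.zeros((n, len(sample_names)), dtype=np.int64)
    discarded: dict[str, int] = {s: 0 for s in sample_names}
    for j, s in enumerate(sample_names):
        sub = df[df["sample"].astype(str) == s]
        for chrom, grp in sub.groupby("chrom", sort=False):
            chrom = str(chrom)
            pos = grp["pos"].to_numpy(dtype=np.int64)
            if chrom not in chrom_offsets:
                discarded[s] += len(pos)
                continue
            offset, length = chrom_offsets[chrom]
            ok = (pos >= 0) & (pos < length)
            if not ok.all():
                discarded[s] += int((~ok).sum())
                pos = pos[ok]
            idx = offset + pos // bins.bin_size
            np.add.at(mat[:, j], idx, 1)
    total_disc = sum(discarded.values())
    if total_disc:
        warnings.warn(f"discarded {total_disc} reads on unknown contigs / out of bounds")
    counts = pd.DataFrame(mat, index=bins.ids, columns=sample_names)
    return BinnedCoverage(bins=bins, counts=counts, discarded=discarded)


def log_cpm(cov: BinnedCoverage, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million per bin: ``log2((c + p) / (L + 2p) * 1e6)``.

    ``L`` is the non-blacklisted library size; blacklisted bins are masked
    with NaN.
    """
    lib = cov.library_sizes().to_numpy(dtype=float)
    c = cov.counts.to_numpy(dtype=float)
    out = np.log2((c + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    out[cov.bins.blacklisted, :] = np.nan
    return pd.DataFrame(out, index=cov.counts.index, columns=cov.counts.columns)


def bin_log2fc(
    cov: BinnedCoverage, sample: str, reference: str, prior_count: float = 0.5
) -> pd.Series:
    """Per-bin log-CPM difference (sample minus reference), blacklist-masked."""
    lc = log_cpm(cov, prior_count=prior_count)
    for name in (sample, reference):
        if name not in lc.columns:
            raise KeyError(f"sample {name!r} not in coverage matrix")
    return lc[sample] - lc[reference]


def chromosome_coverage_fraction(cov: BinnedCoverage) -> pd.DataFrame:
    """Percentage of (non-blacklisted, non-discarded) reads per chromosome.

    Returns a chromosomes x samples table; each column sums to 100.
    """
    keep = ~cov.bins.blacklisted
    counts = cov.counts.loc[keep]
    chroms = cov.bins.table.loc[keep, "chrom"].to_numpy()
    per_chrom = counts.groupby(chroms, sort=False).sum()
    return per_chrom / per_chrom.sum(axis=0) * 100.0


def conditional_binomial_pvalues(
    x: np.ndarray, n: np.ndarray, prob: float
) -> np.ndarray:
    """Exact two-sided binomial p-values for observed successes ``x`` of ``n``.

    Two-sidedness by summing the probabilities of all outcomes whose pmf does
    not exceed the observed one (up to a 1 + 1e-7 relative tolerance, the
    usual guard against floating-point ties).
    """
    x = np.asarray(x, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    p = np.ones(x.shape, dtype=float)
    for i in range(x.size):
        ni = int(n.flat[i])
        if ni == 0:
            continue
        pmf = stats.binom.pmf(np.arange(ni + 1), ni, prob)
        obs = pmf[int(x.flat[i])]
        p.flat[i] = min(1.0, float(pmf[pmf <= obs * (1.0 + 1e-7)].sum()))
    return p


@dataclass
class BinCallResult:
    """Per-pair and consensus aberrant-bin calls.

    ``per_pair`` maps ``(sample, reference)`` to a per-bin table with the
    exact-test p-value, its BH adjustment (within the pair, across
    non-blacklisted bins) and a significance flag requiring both
    ``adj_p < alpha`` and ``|log2fc| >= lfc_min``.  ``consensus`` calls a bin
    for the condition when every pair has ``adj_p < alpha`` with a common
    fold-change sign and the across-pair mean ``|log2fc| >= lfc_min``.
    """

    per_pair: dict[tuple[str, str], pd.DataFrame]
    consensus: pd.DataFrame
    alpha: float
    lfc_min: float

    @property
    def n_called(self) -> int:
        return int(self.consensus["significant"].sum())

    def fraction_genome_called(self, include_sex: bool = True) -> float:
        """Width-weighted fraction (%) of assessable bins called aberrant."""
        c = self.consensus
        keep = np.ones(len(c), dtype=bool)
        if not include_sex:
            keep = ~c["chrom"].map(_is_sex_chrom).to_numpy()
        widths = (c["end"] - c["start"]).to_numpy(dtype=float)[keep]
        called = c["significant"].to_numpy()[keep]
        if widths.sum() == 0:
            return 0.0
        return float(widths[called].sum() / widths.sum() * 100.0)


def call_aberrant_bins(
    cov: BinnedCoverage,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    lfc_min: float = 1.1,
    prior_count: float = 0.5,
) -> BinCallResult:
    """Exact conditional binomial test of each bin against its reference.

    For a bin with ``x`` sample reads and ``y`` reference reads, under the
    null of equal relative coverage ``x | x+y ~ Binomial(x+y, Ns/(Ns+Nr))``
    with ``Ns``, ``Nr`` the library sizes; two-sided p-values are adjusted by
    Benjamini–Hochberg within each pair across non-blacklisted bins.
    Replicate consistency across pairs is summarised in the consensus table.
    """
    if not pairs:
        raise ValueError("need at least one (sample, reference) pair")
    lib = cov.library_sizes()
    keep = ~cov.bins.blacklisted
    bt = cov.bins.table
    per_pair: dict[tuple[str, str], pd.DataFrame] = {}
    for sample, reference in pairs:
        ns = float(lib[sample])
        nr = float(lib[reference])
        if ns <= 0 or nr <= 0:
            raise ValueError("zero library size")
        x = cov.counts.loc[keep, sample].to_numpy(dtype=np.int64)
        y = cov.counts.loc[keep, reference].to_numpy(dtype=np.int64)
        pvals = conditional_binomial_pvalues(x, x + y, ns / (ns + nr))
        adj = multipletests(pvals, method="fdr_bh")[1]
        lfc = bin_log2fc(cov, sample, reference, prior_count=prior_count).to_numpy()[keep]
        tab = bt.loc[keep, ["chrom", "start", "end"]].reset_index(drop=True)
        tab["log2fc"] = lfc
        tab["p_value"] = pvals
        tab["adj_p"] = adj
        tab["significant"] = (adj < alpha) & (np.abs(lfc) >= lfc_min)
        per_pair[(sample, reference)] = tab
    tables = list(per_pair.values())
    all_sig = np.all([t["adj_p"].to_numpy() < alpha for t in tables], axis=0)
    signs = np.array([np.sign(t["log2fc"].to_numpy()) for t in tables])
    common_sign = np.all(signs == signs[0], axis=0) & (signs[0] != 0)
    mean_lfc = np.mean([t["log2fc"].to_numpy() for t in tables], axis=0)
    consensus = tables[0][["chrom", "start", "end"]].copy()
    consensus["log2fc"] = mean_lfc
    consensus["max_adj_p"] = np.max([t["adj_p"].to_numpy() for t in tables], axis=0)
    consensus["significant"] = all_sig & common_sign & (np.abs(mean_lfc) >= lfc_min)
    return BinCallResult(per_pair=per_pair, consensus=consensus, alpha=alpha, lfc_min=lfc_min)


def mds_profiles(logfc_matrix: pd.DataFrame) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples from bins x samples logFC profiles.

    Rows with any NaN (masked bins) are removed listwise; Euclidean distances
    between sample columns are double-centred and the top two eigenpairs give
    coordinates scaled by the square root of the eigenvalues.  Each axis's
    sign is fixed by making its largest-magnitude loading positive, so the
    embedding is fully deterministic.
    """
    m = logfc_matrix.dropna(axis=0, how="any")
    samples = list(m.columns)
    k = len(samples)
    if k < 3:
        raise ValueError("need >= 3 samples for MDS")
    X = m.to_numpy(dtype=float).T  # samples x bins
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.clip(d2, 0.0, None, out=d2)
    J = np.eye(k) - np.ones((k, k)) / k
    B = -0.5 * J @ d2 @ J
    B = 0.5 * (B + B.T)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:2]
    coords = np.zeros((k, 2))
    for a, idx in enumerate(order):
        lam = max(evals[idx], 0.0)
        v = evecs[:, idx] * np.sqrt(lam)
        pivot = int(np.argmax(np.abs(v)))
        if v[pivot] < 0:
            v = -v
        coords[:, a] = v
    return pd.DataFrame(coords, index=samples, columns=["dim1", "dim2"])
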