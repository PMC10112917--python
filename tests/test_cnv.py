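"""Binned-coverage karyotyping: binning, normalisation, calling, MDS."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from karyostab.cnv import (
    BinnedCoverage,
    call_aberrant_bins,
    chromosome_coverage_fraction,
    conditional_binomial_pvalues,
    count_reads_in_bins,
    bin_log2fc,
    log_cpm,
    make_bins,
    mds_profiles,
)
from karyostab.synth import CnvTruth, gen_binned_reads, gen_cnv_experiment


def _cov(bins, arrays: dict) -> BinnedCoverage:
    return BinnedCoverage(bins=bins, counts=pd.DataFrame(arrays, index=bins.ids))


class TestMakeBins:
    def test_truncated_last_bin(self):
        bins = make_bins({"chr1": 2_500_000})
        assert bins.table[["start", "end"]].to_numpy().tolist() == [
            [0, 1_000_000],
            [1_000_000, 2_000_000],
            [2_000_000, 2_500_000],
        ]

    def test_blacklist_boundary_overlap_flags_both_bins(self):
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [999_999], "end": [1_000_001]})
        bins = make_bins({"chr1": 3_000_000}, blacklist=bl)
        assert bins.blacklisted.tolist() == [True, True, False]

    def test_empty_blacklist_and_no_blacklist(self):
        bins = make_bins({"chr1": 3_000_000}, blacklist=pd.DataFrame(columns=["chrom", "start", "end"]))
        assert not bins.blacklisted.any()

    def test_malformed_blacklist_interval(self):
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [100]})
        with pytest.raises(ValueError, match="end <= start"):
            make_bins({"chr1": 3_000_000}, blacklist=bl)

    def test_non_canonical_contigs_dropped(self):
        with pytest.warns(UserWarning, match="non-canonical"):
            bins = make_bins({"chr1": 2_000_000, "chrM": 16_000, "chr1_random": 5_000_000})
        assert set(bins.table["chrom"]) == {"chr1"}


class TestCounting:
    def test_half_open_boundary_assignment(self, small_bins):
        reads = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [0, 1_000_000]})
        cov = count_reads_in_bins(reads, small_bins)
        assert cov.counts.iloc[0, 0] == 1
        assert cov.counts.iloc[1, 0] == 1

    def test_conservation_with_discards(self, small_bins):
        reads = pd.DataFrame(
            {"chrom": ["chr1", "chr2", "chrUn", "chr1"], "pos": [5, 10, 10, 9_999_999]}
        )
        with pytest.warns(UserWarning, match="discarded"):
            cov = count_reads_in_bins(reads, small_bins)
        assert cov.counts.sum().sum() + sum(cov.discarded.values()) == 4
        assert cov.discarded["s1"] == 2  # unknown contig + out-of-bounds

    def test_multinomial_proportions_recovered(self, small_bins, rng):
        n = 50_000
        w = np.arange(1, small_bins.n_bins + 1, dtype=float)
        w /= w.sum()
        chroms = small_bins.table["chrom"].to_numpy()
        starts = small_bins.table["start"].to_numpy()
        idx = rng.choice(small_bins.n_bins, size=n, p=w)
        reads = pd.DataFrame({"chrom": chroms[idx], "pos": starts[idx] + 17})
        cov = count_reads_in_bins(reads, small_bins)
        obs = cov.counts["s1"].to_numpy() / n
        se = np.sqrt(w * (1 - w) / n)
        assert np.all(np.abs(obs - w) < 3 * se + 1e-9)


class TestLogCpm:
    def test_zero_count_floor_value(self, small_bins):
        counts = np.full(small_bins.n_bins, 0)
        counts[0] = 0
        # make library size exactly 1e6
        counts[1:] = 0
        counts[1] = 1_000_000
        cov = _cov(small_bins, {"s": counts})
        val = log_cpm(cov).iloc[0, 0]
        assert val == pytest.approx(math.log2(0.5 / (1e6 + 1) * 1e6), abs=1e-12)
        assert val == pytest.approx(-1.0, abs=1e-5)

    def test_doubling_library_shifts_by_one(self, small_bins, rng):
        base = rng.integers(10_000, 20_000, small_bins.n_bins)
        doubled = base.copy()
        doubled[0] = base[0]  # fixed count, library doubled via other bins
        doubled[1:] = base[1:] * 2 + np.round(base[0] / (small_bins.n_bins - 1)).astype(int)
        cov = _cov(small_bins, {"a": base, "b": doubled})
        lc = log_cpm(cov, prior_count=0.5)
        lib_ratio = cov.library_sizes()["b"] / cov.library_sizes()["a"]
        assert lc.iloc[0, 1] - lc.iloc[0, 0] == pytest.approx(-math.log2(lib_ratio), abs=1e-3)

    def test_uniform_counts_give_uniform_cpm(self, small_bins):
        cov = _cov(small_bins, {"s": np.full(small_bins.n_bins, 100_000)})
        lc = log_cpm(cov)
        expected = math.log2(1e6 / small_bins.n_bins)
        assert np.allclose(lc["s"], expected, atol=1e-3)

    def test_blacklisted_bins_masked(self):
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        bins = make_bins({"chr1": 3_000_000}, blacklist=bl)
        cov = _cov(bins, {"s": [50, 100, 100]})
        lc = log_cpm(cov)
        assert math.isnan(lc.iloc[0, 0])
        assert cov.library_sizes()["s"] == 200  # blacklisted counts excluded


class TestLog2FC:
    def test_self_comparison_is_zero(self, small_bins, rng):
        c = rng.integers(100, 1000, small_bins.n_bins)
        cov = _cov(small_bins, {"a": c})
        assert np.allclose(bin_log2fc(cov, "a", "a"), 0.0)

    def test_planted_whole_chromosome_loss(self):
        bins = make_bins({f"chr{i}": 20_000_000 for i in range(1, 11)})
        truth = CnvTruth(segments=[("chr3", 0, 20_000_000, 0.5)])
        ref, bias = gen_binned_reads(bins, CnvTruth(), 2_000_000, 30.0, seed=1, sample_id="p0")
        smp, _ = gen_binned_reads(bins, truth, 2_000_000, 30.0, seed=2, sample_id="s", bias=bias)
        cov = _cov(bins, {"p0": ref.counts["p0"], "s": smp.counts["s"]})
        lfc = bin_log2fc(cov, "s", "p0")
        on = bins.table["chrom"] == "chr3"
        # -1 plus the library renormalisation from losing 5% of the genome mass
        expected = -1.0 + math.log2(200 / 190)
        assert lfc[on.to_numpy()].mean() == pytest.approx(expected, abs=0.05)

    def test_library_scaling_invariance(self, small_bins, rng):
        c = rng.integers(5_000, 10_000, small_bins.n_bins)
        r = rng.integers(5_000, 10_000, small_bins.n_bins)
        cov = _cov(small_bins, {"s": c, "r": r})
        scaled = _cov(small_bins, {"s": c * 7, "r": r})
        delta = bin_log2fc(scaled, "s", "r") - bin_log2fc(cov, "s", "r")
        assert np.allclose(delta, 0.0, atol=1e-3)  # large-count limit


class TestChromosomeFractions:
    def test_all_reads_on_one_chromosome(self, small_bins):
        counts = np.zeros(small_bins.n_bins, dtype=int)
        counts[:3] = [10, 20, 30]  # chr1 bins only
        frac = chromosome_coverage_fraction(_cov(small_bins, {"s": counts}))
        assert frac.loc["chr1", "s"] == pytest.approx(100.0)
        assert frac["s"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_uniform_two_chromosomes(self, rng):
        bins = make_bins({"chr1": 5_000_000, "chr2": 5_000_000})
        n = 100_000
        counts = rng.multinomial(n, np.full(10, 0.1))
        frac = chromosome_coverage_fraction(_cov(bins, {"s": counts}))
        se = 100 * math.sqrt(0.25 / n)
        assert abs(frac.loc["chr1", "s"] - 50.0) < 3 * se


class TestExactConditionalTest:
    def test_matches_brute_force_small(self):
        prob = 0.5
        for n in (3, 17, 150):
            x = np.arange(n + 1)
            impl = conditional_binomial_pvalues(x, np.full(n + 1, n), prob)
            pmf = np.array(
                [math.comb(n, k) * prob**k * (1 - prob) ** (n - k) for k in range(n + 1)]
            )
            oracle = np.minimum(
                [pmf[pmf <= pmf[k] * (1 + 1e-7)].sum() for k in range(n + 1)], 1.0
            )
            assert np.abs(impl - oracle).max() < 1e-12

    def test_matches_scipy_binomtest(self):
        for prob in (0.5, 0.35):
            for n, x in [(150, 50), (150, 75), (433, 200), (40, 0)]:
                ours = conditional_binomial_pvalues(np.array([x]), np.array([n]), prob)[0]
                ref = stats.binomtest(x, n, prob).pvalue
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_modal_outcome_has_p_one(self):
        # x = y with equal libraries: the observed split is modal, p = 1
        p = conditional_binomial_pvalues(np.array([100]), np.array([200]), 0.5)[0]
        assert p == pytest.approx(1.0, abs=1e-9)


def test_bh_adjustment_matches_sort_oracle(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(size=500) ** 2
    adj = multipletests(p, method="fdr_bh")[1]
    # direct sort-based oracle: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1
    order = np.argsort(p)
    m = len(p)
    stepped = p[order] * m / np.arange(1, m + 1)
    oracle_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
    oracle = np.empty(m)
    oracle[order] = np.minimum(oracle_sorted, 1.0)
    assert np.allclose(adj, oracle, atol=1e-12)
    assert np.all(adj >= p - 1e-12)  # BH never decreases a p-value


class TestCalling:
    def test_self_comparison_yields_no_calls(self, rng):
        bins = make_bins({"chr1": 50_000_000})
        counts = rng.multinomial(500_000, np.full(50, 0.02))
        cov = _cov(bins, {"a": counts})
        res = call_aberrant_bins(cov, [("a", "a")], alpha=0.5, lfc_min=0.0)
        assert res.n_called == 0
        assert np.all(res.per_pair[("a", "a")]["p_value"] >= 1.0 - 1e-9)

    def test_zero_library_rejected(self, small_bins):
        cov = _cov(small_bins, {"a": np.ones(small_bins.n_bins, dtype=int)})
        with pytest.raises(ValueError):
            BinnedCoverage(bins=small_bins, counts=pd.DataFrame({"z": np.zeros(small_bins.n_bins)}, index=small_bins.ids))
        with pytest.raises(ValueError, match="pair"):
            call_aberrant_bins(cov, [])

    def test_detection_power_monotone_in_effect_size(self):
        # statistical power (lfc floor off) grows with |log2 copy ratio|
        bins = make_bins({"chr1": 60_000_000, "chr2": 40_000_000})
        rates = []
        for i, ratio in enumerate([0.9, 0.7, 0.5]):
            truth = CnvTruth(segments=[("chr2", 0, 40_000_000, ratio)])
            cov, pairs = gen_cnv_experiment(bins, truth, 1_000_000, 30.0, 2, seed=50 + i)
            res = call_aberrant_bins(cov, pairs, alpha=0.05, lfc_min=0.0)
            planted = truth.affected_bins(bins)
            rates.append(res.consensus["significant"].to_numpy()[planted].mean())
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9

    def test_consensus_requires_common_sign_and_every_pair(self):
        bins = make_bins({"chr1": 5_000_000})
        base = np.full(5, 10_000)
        up = base.copy(); up[0] = 40_000
        down = base.copy(); down[0] = 2_500
        cov = _cov(bins, {"r1": base, "s1": up, "r2": base, "s2": down})
        res = call_aberrant_bins(cov, [("s1", "r1"), ("s2", "r2")], lfc_min=0.5)
        # both pairs highly significant at bin 0 but with opposite signs
        assert res.per_pair[("s1", "r1")]["significant"].iloc[0]
        assert res.per_pair[("s2", "r2")]["significant"].iloc[0]
        assert not res.consensus["significant"].iloc[0]

    def test_fraction_genome_called_with_and_without_sex(self):
        bins = make_bins({"chr1": 10_000_000, "chrX": 10_000_000})
        base = np.full(20, 50_000)
        smp = base.copy()
        smp[10:] = 5_000  # whole chrX depleted
        cov = _cov(bins, {"p0": base, "s": smp})
        res = call_aberrant_bins(cov, [("s", "p0")])
        assert res.fraction_genome_called(include_sex=True) == pytest.approx(50.0, abs=1e-9)
        assert res.fraction_genome_called(include_sex=False) == pytest.approx(0.0)


class TestMds:
    def test_isometry_on_colinear_profiles(self):
        # samples on a line in logFC space: axis 1 reproduces distances exactly
        base = np.zeros(40)
        direction = np.ones(40) / math.sqrt(40)
        offsets = [0.0, 1.0, 2.5, 7.0]
        m = pd.DataFrame({f"s{i}": base + o * direction for i, o in enumerate(offsets)})
        coords = mds_profiles(m)
        d1 = coords["dim1"].to_numpy()
        for i in range(4):
            for j in range(4):
                assert abs(d1[i] - d1[j]) == pytest.approx(
                    abs(offsets[i] - offsets[j]), abs=1e-9
                )
        # axis 2 is numerical zero (its eigenvalue is rounding noise)
        assert np.allclose(coords["dim2"], 0.0, atol=1e-6)

    def test_duplicated_sample_is_coincident(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        m["c"] = m["a"]
        coords = mds_profiles(m)
        assert np.allclose(coords.loc["a"], coords.loc["c"], atol=1e-6)

    def test_group_separation_ordering(self, rng):
        # p0-like, mildly and grossly aberrant profiles separate in order on axis 1
        n = 100
        noise = lambda: rng.normal(0, 0.01, n)
        shift = np.zeros(n); shift[:20] = 1.0
        m = pd.DataFrame(
            {
                "p0_a": noise(), "p0_b": noise(),
                "mild_a": 0.4 * shift + noise(), "mild_b": 0.4 * shift + noise(),
                "gross_a": 2.0 * shift + noise(), "gross_b": 2.0 * shift + noise(),
            }
        )
        coords = mds_profiles(m)
        c = coords["dim1"]
        centers = [c[["p0_a", "p0_b"]].mean(), c[["mild_a", "mild_b"]].mean(),
                   c[["gross_a", "gross_b"]].mean()]
        gaps = [abs(centers[1] - centers[0]), abs(centers[2] - centers[0])]
        assert gaps[1] > gaps[0] > 0

    def test_needs_three_samples(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match=">= 3"):
            mds_profiles(m)

    def test_deterministic_sign_convention(self, rng):
        m = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        c1 = mds_profiles(m)
        c2 = mds_profiles(m)
        pd.testing.assert_frame_equal(c1, c2)
        for axis in ("dim1", "dim2"):
            v = c1[axis].to_numpy()
            assert v[np.argmax(np.abs(v))] >= 0
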