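"""Copy-number karyotype stability from the simulated binned coverage.

Reads results/data/cnv_counts.tsv (two replicate lines, each with a p0
reference and an evolved sample carrying a planted chr13 loss at copy ratio
0.45), calls aberrant bins at FDR 0.05 with a minimum |log2FC| of 1.1,
summarises the fraction of the genome affected, tabulates per-chromosome read
percentages and embeds the samples by classical MDS of their log2FC profiles.
Writes results/cnv_calls.tsv, results/cnv_chrom_fractions.tsv and
results/cnv_mds.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import karyostab as ks
from karyostab.io import read_chrom_sizes, read_counts_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"

sizes = read_chrom_sizes(DATA / "cnv_chrom_sizes.tsv")
bins = ks.make_bins(sizes)
cov = ks.BinnedCoverage(bins=bins, counts=read_counts_matrix(DATA / "cnv_counts.tsv"))
pairs = [("evolved_rep1", "p0_rep1"), ("evolved_rep2", "p0_rep2")]

res = ks.call_aberrant_bins(cov, pairs, alpha=0.05, lfc_min=1.1)
res.consensus.to_csv(ROOT / "cnv_calls.tsv", sep="\t", index=False)

truth = pd.read_csv(DATA / "cnv_truth.tsv", sep="\t")
planted = ks.CnvTruth(segments=[tuple(r) for r in truth.itertuples(index=False)]
                      ).affected_bins(bins)
sig = res.consensus["significant"].to_numpy()
print(f"{res.n_called} bins called aberrant "
      f"({res.fraction_genome_called():.2f}% of assessable genome; "
      f"{res.fraction_genome_called(include_sex=False):.2f}% autosomes only)")
print(f"sensitivity on the {planted.sum()} planted bins: {100 * sig[planted].mean():.1f}%")
print(f"false calls on {np.sum(~planted)} diploid bins: {int(sig[~planted].sum())}")
print(f"mean log2FC on the planted chromosome: "
      f"{res.consensus['log2fc'].to_numpy()[planted].mean():.3f} "
      f"(construction predicts log2(0.45) + renormalisation ~ -1.14)")

frac = ks.chromosome_coverage_fraction(cov)
frac.round(3).to_csv(ROOT / "cnv_chrom_fractions.tsv", sep="\t")
print(f"\nchr13 read share, p0 vs evolved: {frac.loc['chr13', 'p0_rep1']:.2f}% "
      f"-> {frac.loc['chr13', 'evolved_rep1']:.2f}%")

# MDS of all evolved samples' logFC profiles against their references,
# plus a self-comparison profile as the p0-like anchor
logfc = pd.DataFrame({
    "p0_self": ks.bin_log2fc(cov, "p0_rep2", "p0_rep1"),
    "evolved_rep1": ks.bin_log2fc(cov, "evolved_rep1", "p0_rep1"),
    "evolved_rep2": ks.bin_log2fc(cov, "evolved_rep2", "p0_rep2"),
})
coords = ks.mds_profiles(logfc)
coords.round(4).to_csv(ROOT / "cnv_mds.tsv", sep="\t", index_label="sample")
print("\nMDS coordinates (dim1 separates aberrant from p0-like profiles):")
print(coords.round(3).to_string())
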