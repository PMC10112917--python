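"""Generate every synthetic input the downstream analyses consume.

Writes, under results/data/:
  growth_curves.tsv      six replicates per protocol, 10% CV multiplicative noise
  flow_events.tsv        reporter flow events from a simulated XX/XO culture
  trajectory_truth.tsv   the simulated culture's true XO-proportion trajectory
  cnv_counts.tsv         binned read counts: two replicate lines, p0 + evolved
  cnv_chrom_sizes.tsv    the synthetic genome
  cnv_truth.tsv          the planted copy-number segment (truth sidecar)

Conditions mirror the two culture protocols: doubling times 26.5 h (XX) /
21.8 h (XY proxy for XO) under the improved protocol and 43.3 h / 24.5 h
under the reference protocol; competition cultures start at 20% XO.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import karyostab as ks
from karyostab.io import write_counts_matrix, write_growth_curves, write_trajectory

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# -- growth curves -----------------------------------------------------------
curves = []
for i, (condition, dt) in enumerate(
    (("improved_xx", 26.5), ("reference_xx", 43.3),
     ("improved_xy", 21.8), ("reference_xy", 24.5))
):
    curves += ks.gen_growth_counts(
        lam=1 / dt, n0=1e4, times=np.arange(0, 121, 24), cv=0.10,
        replicates=6, seed=SEED + 100 * i, condition=condition,
    )
write_growth_curves(curves, OUT / "growth_curves.tsv")
print(f"growth_curves.tsv: {len(curves)} replicates x 6 timepoints")

# -- reporter culture under the reference protocol ---------------------------
scenario = ks.SimulationScenario(
    competition=ks.CompetitionParams(8_000, 2_000, 1 / 43.3, 1 / 24.5),
    events_per_sample=5_000,
    seed=SEED,
)
record = np.array([0.0, 48.0, 96.0, 144.0, 192.0, 240.0])
traj, tables, labels = ks.gen_competition_culture(scenario, record)
write_trajectory(traj, OUT / "trajectory_truth.tsv")
rows = []
for tab, lab in zip(tables, labels):
    for g, m, l in zip(tab.gfp, tab.mcherry, lab):
        rows.append({"sample_id": tab.sample_id, "time_h": tab.time_h,
                     "gfp": g, "mcherry": m, "true_class": l})
pd.DataFrame(rows).to_csv(OUT / "flow_events.tsv", sep="\t", index=False)
print(f"flow_events.tsv: {len(rows)} events over {len(tables)} timepoints "
      f"(true p_xo {traj.p_xo[0]:.2f} -> {traj.p_xo[-1]:.2f})")

# -- binned sequencing coverage with a planted chromosome loss ---------------
sizes = {f"chr{i}": 200_000_000 for i in range(1, 13)}
sizes["chr13"] = 40_000_000
sizes["chrX"] = 160_000_000
pd.DataFrame(sizes.items()).to_csv(OUT / "cnv_chrom_sizes.tsv", sep="\t",
                                   header=False, index=False)
bins = ks.make_bins(sizes)
truth = ks.CnvTruth(segments=[("chr13", 0, 40_000_000, 0.45)])
cov, pairs = ks.gen_cnv_experiment(
    bins, truth, depth=5_000_000, bias_dispersion=30.0, n_replicates=2, seed=SEED
)
write_counts_matrix(cov.counts, OUT / "cnv_counts.tsv")
pd.DataFrame(truth.segments, columns=["chrom", "start", "end", "copy_ratio"]).to_csv(
    OUT / "cnv_truth.tsv", sep="\t", index=False
)
print(f"cnv_counts.tsv: {bins.n_bins} bins x {cov.counts.shape[1]} samples, "
      f"pairs {pairs}; planted {truth.segments[0]}")
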