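# karyostab

Karyotype stability analysis for female mouse embryonic stem cell (mESC)
cultures. Female (XX) mESC lines are progressively overtaken by cells that
have lost one X chromosome (XO), because XO cells divide faster. `karyostab`
implements the quantitative side of that problem as a reusable pipeline:

- **Clonal-competition growth model** — XX and XO cells grow as simple
  exponentials `N(t) = N0 · 2^(λt)` with doubling frequencies λ_XX and λ_XO
  (doublings·h⁻¹, the reciprocal of the doubling time). The XO proportion

      p_XO(t) = N_XO0·2^(λ_XO·t) / (N_XX0·2^(λ_XX·t) + N_XO0·2^(λ_XO·t))

  is logistic in time with slope Δλ = λ_XO − λ_XX on the log2-odds scale;
  Δλ is the selection parameter that sets how fast XO cells take over.
  Alongside the closed form there is an exact Gillespie simulator (per-cell
  division rate λ·ln2, optional XX→XO conversion and serial-passage
  bottlenecks) and OLS inference of Δλ from observed proportion series.
- **Doubling-time estimation** — log-linear fits of count curves, with
  replicate pooling (common slope, per-replicate intercepts) and
  t-distribution CIs.
- **Reporter flow-cytometry quantification** — cells carry GFP and mCherry
  on opposite X chromosomes, so double-positive events are XX and
  single-positive events are XO; rectangular gating with fixed or Otsu
  auto-thresholds yields karyotype fractions and XO-proportion time courses.
- **Binned-coverage karyotyping** — reads counted in 1 Mb genome bins
  (blacklist-aware), log2 counts-per-million, per-bin log2 fold changes
  against a passage-0 reference, exact conditional binomial tests with
  Benjamini–Hochberg control (FDR 0.05, |log2FC| ≥ 1.1) and
  replicate-consistency filtering, chromosome read shares, and classical
  (Torgerson) MDS of sample log2FC profiles.
- **Synthetic-data generators** — seeded generators with ground truth for
  every input above, so the whole pipeline runs and is validated without any
  external dataset.

## Worked example

The numbered scripts under `analysis/` form a small narrative study. Run
them in order from the repository root (`01` writes the synthetic inputs the
others read, under `results/`):

```sh
python analysis/01_simulate_inputs.py
python analysis/02_doubling_times.py
python analysis/03_competition_dynamics.py
python analysis/04_cnv_karyotype.py
```

`02_doubling_times.py` pools six noisy replicates per condition (generating
doubling times 26.5/43.3 h for XX and 21.8/24.5 h for XY under the improved
vs reference protocol) and prints:

```
improved_xx: 26.5 h (95% CI 25.6-27.5)
improved_xy: 21.3 h (95% CI 20.7-21.9)
reference_xx: 41.1 h (95% CI 39.3-43.2)
reference_xy: 24.6 h (95% CI 23.8-25.5)

XX doubling-time reduction (improved vs reference): 36%
```

i.e. the improved protocol shortens the XX doubling time by ~36%, far more
than for XY cells, so the XX/XO growth gap narrows.
`03_competition_dynamics.py` turns the measured doubling times into
selection parameters and take-over dynamics:

```
delta_lambda: reference 0.0177 /h, improved 0.00814 /h
time for XO to reach 50% from 20%: reference 113 h, improved 246 h (2.18x longer)
delta_lambda refit from gated flow series: 0.01769 /h (s.e. 0.00050; generating value 0.01772)
```

Δλ = (24.5 h)⁻¹ − (43.3 h)⁻¹ = 0.0177 h⁻¹ under the reference protocol
versus 0.00814 h⁻¹ under the improved one: every crossing time stretches by
the ratio of the two (≈ 2.18×), which is why XX cultures stay usable for
weeks longer. The last line closes the loop: Otsu-gating simulated reporter
flow data and refitting the log2-odds slope recovers the generating Δλ to
three decimals. `04_cnv_karyotype.py` calls the planted chr13 loss (copy
ratio 0.45, mean log2FC ≈ −1.13) with zero false calls on diploid bins.

The same functionality is exposed as a CLI (`karyostab simulate`,
`fit-growth`, `fit-competition`, `flow-call`, `cnv-call`, `report`); see
`karyostab --help`.

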