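# Methods

## The competition model

XX and XO subpopulations are modelled as independent exponentials,
`N_c(t) = N_c(0) · 2^(λ_c t)` with doubling frequency λ_c in doublings·h⁻¹
(the reciprocal of the doubling time). The XO proportion then satisfies

    log2 odds(p_XO(t)) = log2(N_XO0 / N_XX0) + Δλ · t,     Δλ = λ_XO − λ_XX,

so the whole deterministic model is a straight line on the log2-odds scale.
`proportion_xo` evaluates it through a logistic (expit) transform of the
log-odds, never through the raw exponentials, so it is exact at t = 0,
monotone in t with the sign of Δλ, and free of overflow out to at least
10⁵ h. `predict_crossing_time` is its algebraic inverse and is allowed to
return negative times (a crossing in the past).

Assumptions worth keeping in mind: no density dependence, no cell death, no
lag phase — growth is treated as exponential over the assayed window, which
matches how the doubling times feeding the model were measured.

### Stochastic counterpart

`simulate_competition` is an exact continuous-time Gillespie simulation of
the same process: each XX cell divides at rate λ_XX·ln2, each XO cell at
λ_XO·ln2 (so expected counts follow `N0·2^(λt)`), and two extensions beyond
the closed form are available:

- **conversion** — an XX cell becomes an XO cell at rate `conversion_rate`
  per cell per hour (X loss converts a cell, it does not kill it; the total
  population is preserved at the event). With equal division rates the
  expected proportion follows the one-way ODE solution
  `E[p(t)] = 1 − (1−p0)·e^(−ct)`, which the tests use as an oracle.
- **passaging** — every `passage_interval_h` hours each cell survives
  independently with probability `passage_survival` (binomial thinning,
  identical for both classes; class-biased survival is deliberately not
  modelled). A record time that coincides with a passage reports the
  pre-passage state.

The closed form refuses these configurations explicitly rather than
silently approximating them. The event loop is JIT-compiled (numba) so that
desk-scale populations (guard: 10⁷ cells, configurable) stay affordable —
200 runs at n0 = 10⁵ over 120 h is ~10⁸ events and takes seconds. One
integer seed determines a trajectory completely; designs that need
replicates use seed + r for replicate r.

### Fitting

`fit_competition` regresses log2-odds(p_XO) on time by OLS; the slope is
Δλ̂ directly and the intercept the initial log2 odds. Boundary observations
(p ∈ {0, 1}) have infinite logits; when class counts are available they get
the Haldane–Anscombe +0.5 on both counts, otherwise the point is dropped
and reported in `n_points_dropped`. No weighting is applied: per-point
binomial logit variance `1/(n·p·q)` varies across a time course, but at the
event counts this pipeline deals in (10³–10⁴ per sample) the bias from
ignoring it is far below the Monte-Carlo error the tests budget for.

`relative_xx_yield` converts a proportion series into cumulative XX
daughter-cell output, `yield(t) = (1 − p_XO(t)) · 2^((t−t0)/DT_XX)`,
normalised to `1 − p_XO(t0)` at the first timepoint — the quantity that
shows slower takeover and faster doubling compounding multiplicatively.

## Doubling-time estimation

`fit_doubling_time` fits `log2(count) = log2(N0) + λt` by OLS — the ML fit
under multiplicative log-normal noise, which is what serial dilutions and
haemocytometer/Coulter counts produce — and back-transforms λ̂ and its
t-based 95% CI to hours (`DT = 1/λ̂`, CI endpoints inverted). R² is
reported in log space. λ̂ ≤ 0 yields `doubling_time_h = NaN` (flagged
`is_growing = False`) instead of an exception, because a flat well is a
result, not an error; zero counts, by contrast, are rejected as invalid
input. `pool_replicates` stacks replicates with per-replicate intercepts
and one common slope, so replicates may start at different seeding
densities without biasing λ̂.

## Flow-reporter karyotyping

Gating is rectangular with strict inequalities (an event exactly on a
threshold is negative — a deterministic, testable convention). Per-channel
auto-thresholds use Otsu's between-class variance maximisation on a 256-bin
histogram of log10 intensities, ties broken toward the lowest threshold;
working in log space makes the threshold equivariant under instrument gain
changes. Non-positive intensities (possible after compensation) are clipped
to the smallest positive observed value with an explicit warning.

The XO proportion is computed over reporter-informative events only:
double-negatives (dead cells, doublets, reporter-silenced cells) are
excluded. Scatter-based pre-gating, compensation and FCS parsing are out of
scope — inputs are pre-gated tables or synthetic events.

## Binned-coverage karyotyping

Coordinates are 0-based half-open (BED convention) throughout; reads are
assigned to bins by start position; only autosomes and sex chromosomes are
kept, and a bin is blacklisted iff it overlaps a blacklist interval by
≥ 1 bp. Blacklisted bins carry counts but enter no statistic — including
library sizes, which are sums over non-blacklisted bins only.

Coverage is `log2((c + 0.5) / (L + 1) · 10⁶)` (prior count 0.5, a standard
small-count stabiliser, stated because nothing in the data fixes it), and
per-bin log2 fold changes are log-CPM differences against the matched
passage-0 sample of the same line, which cancels line-specific positional
bias.

Differential bins are called by an exact conditional binomial test: given
bin counts x (sample) and y (reference), under the null
`x | x+y ~ Binomial(x+y, Ns/(Ns+Nr))` with Ns, Nr the library sizes;
two-sided p-values sum the probabilities of all outcomes whose pmf does not
exceed the observed one (relative tolerance 1 + 1e−7 against
floating-point ties), followed by Benjamini–Hochberg within each
sample/reference pair across non-blacklisted bins. A bin is called for a
condition when every replicate pair is BH-significant with a common
fold-change sign and the across-pair mean |log2FC| clears the floor
(defaults: FDR 0.05, |log2FC| ≥ 1.1). The consensus table stores that mean
log2FC, so its significance flag always implies both conditions on its own
columns; per-pair tables flag `adj_p < α ∧ |log2FC| ≥ floor` per pair. The
fraction-of-genome-aberrant summary is width-weighted and reported both
with and without chrX/chrY, since sex-chromosome loss can predate an
experiment. No segmentation, GC or mappability correction is applied — the
analysis is bin-wise by design.

Sample relationships use classical (Torgerson) MDS: Euclidean distances of
log2FC profiles (masked bins removed listwise), double-centred squared
distances, top-two eigenpairs scaled by √eigenvalue. Each axis's sign is
fixed by making its largest-magnitude loading positive, so the embedding is
deterministic. For exactly colinear profiles axis 1 reproduces pairwise
distances to machine precision; axis 2's eigenvalue is then pure rounding
noise, so its coordinates are numerical zeros at the ~1e−8 level (the
square root of a ~1e−15-relative eigenvalue), not exact zeros.

## Synthetic data: what it emulates, and what it does not

- **Growth curves**: `counts = n0·2^(λt)·e^ε`, ε ~ N(0, σ) with
  σ = √ln(1+cv²). Default study design mirrors the real assays: 6
  timepoints at 24 h spacing, 6 replicates, cv = 10%.
- **Reporter cultures**: the exact birth-process simulator provides true
  class counts; flow events are drawn per timepoint with class labels
  categorical in the realised fractions (XO split between GFP-only and
  mCherry-only, default 50/50) and intensities bivariate log-normal per
  class (log10 means 3.0 high / 1.0 low, sd 0.3 — a clean two-decade
  separation typical of bright reporters). Competition cultures start at
  20% XO with 10⁴ cells after derivation and are sampled at 5,000 events
  per timepoint over 240 h.
- **Binned reads**: per-bin weight = gamma bias (shape 30, mean 1, ~18% CV,
  a realistic library-prep positional bias) × copy ratio × bin width;
  counts are multinomial at fixed depth. The bias field is shared between a
  sample and its matched p0 reference, mirroring the fact that positional
  bias largely cancels between matched real libraries; replicate lines get
  independent bias fields. The standard test genome has 2,600 1 Mb bins
  with a 40-bin chromosome planted at copy ratio 0.45 and depth 5×10⁶.

What the generators do *not* emulate: instrument drift and spectral
spillover in flow data, GC/mappability structure (the gamma bias is
exchangeable across bins), overdispersion beyond multinomial sampling
within a library, mosaicism (planted CNVs are clonal), and cell death.
Passing tests therefore demonstrate correctness of the inference machinery
under the stated noise models, not robustness to every artefact of real
instruments and libraries.

## Problem sizes and numerical choices

Test and acceptance runs use the design sizes above (200 simulation runs at
n0 = 10⁵ for the model/simulation comparison; 20 cultures for Δλ recovery;
one 2,600-bin experiment for CNV recovery), chosen so the full suite
completes in about a minute while leaving Monte-Carlo error well inside the
asserted tolerances. Exact-test correctness is verified against brute-force
pmf summation for all instances with x+y ≤ 500 and against an independent
implementation. Ties in Otsu thresholding break toward the lowest
threshold; gate comparisons are strict; record-vs-passage ties in the
simulator record first. Seeds are explicit everywhere; hypothesis-based
property tests run derandomised.

## Known limitations

- Δλ inference assumes the two-exponential model; conversion is
  simulation-only (not estimable from data in this version).
- The CNV caller's replicate-consistency rule is conservative: a bin whose
  mean |log2FC| sits near the floor is called only sporadically, so
  sensitivity degrades sharply for effects within ~2 standard errors of the
  fold-change floor (e.g. copy ratio 0.45 at 5×10⁶ depth yields a true
  |log2FC| of ≈1.14 against the 1.1 floor, and per-bin detection of only
  ~80%). Raising depth, pooling replicates before testing, or segmenting
  would all help; none is in scope for a bin-wise caller.
- The flow model assumes pre-gated, compensation-free events.
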