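# Methods

## The data model

An Affymetrix-style boutique chip interrogates each transcript with a
probe set of 11 perfect-match (PM) / single-mismatch (MM) probe pairs.
Probe-level intensities are stored linear-scale, strictly positive, in
probe-set-major row order with an explicit probe index; every log2
transform happens inside an operation, never in storage. Missing values
are not permitted — none of the implemented procedures define
missing-data behaviour, so absence is rejected at the door rather than
silently imputed.

## Background correction

Observed PM intensity is modelled as O = S + N with signal
S ~ Exp(α) (truncated to S > 0) and background N ~ Normal(μ, σ²). The
correction replaces O by the posterior mean

    E[S | O = o] = a + σ · φ(a/σ) / Φ(a/σ),   a = o − μ − σ²α,

computed via the scaled complementary error function so the inverse
Mills ratio stays finite for strongly negative a. The output is strictly
positive and strictly increasing in o; for large o it converges to
o − μ − σ²α.

Parameter estimation starts from the classical lower-mode heuristic
(kernel-density mode of the log2 intensities for μ, left-tail spread
about the mode for σ, reciprocal mean excess for α) and then refines by
maximum likelihood on the exponentially modified Gaussian
(`scipy.stats.exponnorm`), seeded with those values. The refinement
matters: the mode of the EMG sits roughly 1.7σ above μ at typical chip
parameters (α = 0.01, μ = 100, σ = 10), so the raw mode heuristic
overestimates the background level whenever signal and background
overlap. Estimation requires ≥ 50 intensities and errors out on
zero-spread input; fits are capped at 20,000 values (even striding) for
speed, and fall back to the mode-based seed if the likelihood
optimization fails. Everything is deterministic for fixed input.

A known, accepted consequence of posterior-mean correction is
attenuation of fold changes for genes near the background level: the
corrected value of a barely-expressed gene is biased upward, so a true
2-log2 induction of a low-baseline gene is reported as ~1.5 log2. This
is standard RMA behaviour, visible in the examples, and is not removed.

## Quantile normalization and summarization

Quantile normalization maps every column onto the across-array mean of
sorted columns. Ties receive the mean of the reference values at their
tied ranks, which makes the operation symmetric, deterministic and
idempotent. A single-column input is returned unchanged with a logged
warning.

Each probe set's block of log2 PM values is summarized by Tukey median
polish (row = probe, column = array), iterating row/column median sweeps
until the change in the sum of absolute residuals falls below 1e-8 or 20
iterations, and reporting overall + array effect. The sweep is
vectorized across all probe-set blocks simultaneously; a block that has
already converged is unaffected by further sweeps of zero medians. MM
probes never enter summarization (standard RMA contract); they exist for
detection calls only.

## Detection calls

Per probe set and array, discrimination scores
R_i = (PM_i − MM_i)/(PM_i + MM_i) are tested one-sided against the
threshold τ: H0 median(R − τ) = 0 versus > 0. With at most 11 informative
pairs the Wilcoxon signed-rank null is enumerated exactly (2^n sign
assignments, conditional on the observed midrank pattern; zero
differences dropped, the standard signed-rank convention), so p-values
are exact and the suite's calls are deterministic. Calls: Present if
p < α₁, Marginal if α₁ ≤ p < α₂, Absent otherwise, with defaults
α₁ = 0.05 (the recommended level for 11 probe pairs), α₂ = 0.065,
τ = 0.015 (vendor defaults). If every score equals τ the probe set is
Absent with p = 1 and a logged warning. Calls are computed from raw
PM/MM (the MAS5 convention); callers may background-correct first if
they wish, but that is not the default.

## Boutique normalization

**SBQ (stable-gene based quantile).** Input is summarized log2
expression that has *not* been quantile-normalized across arrays (the
`raw_summary` tag). The reference distribution is the across-array mean
of sorted stable-gene values. Per array, stable genes are rank-mapped
onto the reference (tied anchor values collapse to the mean reference of
their ranks); every other gene is mapped by monotone piecewise-linear
interpolation between the (observed → reference) anchor pairs; values
outside the stable range are shifted by the boundary anchor's offset, so
the map is monotone non-decreasing everywhere. With the stable set equal
to all genes, SBQ is exactly full quantile normalization. At least 10
stable genes are required.

**RMAPS / RIMS.** RMA is run separately within each replicate group
(inside a group all arrays share a condition, so the distributional
assumptions hold), then each group's log2 matrix is shifted by a single
additive constant — equivalently a multiplicative factor on the linear
scale, the minimal transformation a median anchor can identify — so that
its anchor median equals the grand median of that statistic across
groups (a symmetric, order-independent target). RMAPS anchors on the
probe sets called Absent in *every* array of the experiment and raises a
specific error when that set is empty; RIMS anchors on a designated
invariant-gene list (≥ 10). A single replicate group passes through
unscaled. After scaling, anchor medians agree across groups to 1e-9.

**Invariant selection.** CV = sample SD / mean, computed on the linear
scale (2^log2) across all arrays, strict `< threshold` (default 0.10; a
gene at exactly 10% is excluded). A config switch computes CV on the
log2 scale instead.

**Heat-map scaling.** Row-median centering of log2 values (every row has
median 0), rendered with a green–white–magenta diverging palette (low /
average / high relative abundance).

## Downstream analysis

- *Catalog*: a gene is "expressed" in a tissue when called Present in at
  least `expressed_rule_min_present` of that tissue's replicates
  (default 2 of 3 — majority rule, robust to one failed hybridization;
  the combination rule is a package choice). Classes: constitutive
  (expressed in all ≥ 2 tissues), unique-to-one-tissue, multi-tissue,
  not expressed. Venn counts are exclusive region counts over up to 4
  named tissue groups and always sum to the union size.
- *Differential expression*: pooled-variance Student t for two groups
  (Welch available by keyword; with n = 3 per group the pooled variance
  estimate is what keeps power usable, and groups are normalized to
  comparable variance upstream), one-way ANOVA for more. BH step-up
  q-values; significance means q < 0.05. Zero-variance, zero-difference
  probe sets get p = 1 rather than NaN.
- *Co-expression*: Pearson r against a seed probe set across all arrays;
  reported when r > 0 and r² ≥ 0.7. The positive-r restriction encodes
  "co-regulated" as same-direction regulation — r² alone would admit
  perfectly anti-correlated genes.
- *Clustering*: UPGMA on d = 1 − r. Minimum-distance ties are broken
  lexicographically on the sorted member identifiers of the candidate
  pair, making the merge sequence fully deterministic (library
  implementations leave tie order unspecified). Zero-variance rows get
  r = 0 (d = 1) with a logged warning.
- *Reference-gene stability*: on linear-scale values (the original
  geNorm convention; log2 input must be exponentiated first), pairwise
  per-sample log2 ratios A_jk, V_jk = SD(A_jk), M_j = mean over k ≠ j.
  Lower M is more stable; optional iterative worst-gene exclusion is off
  by default.

## The simulator

`simulate_experiment` generates the data-generating structure that a
boutique family chip presents:

- True expression: θ_gc = baseline_g + effect(g, c), with baselines
  N(7, 1.5²) log2. Each non-designated condition induces its own random
  subset of expressed family genes (`tissue_frac_shifted`, default 0.20,
  at `effect_log2` = 2.0) — family chips show exactly this
  tissue-specific patterning — while the designated condition induces
  `frac_shifted` (default 0.70) of them: the boutique pathology.
  Replicates add N(0, 0.25²) biological noise.
- Invariant probe sets (default 171) get baselines uniform over log2
  4–10 — invariant sets are chosen to cover the intensity range, which
  is what lets them anchor a quantile map at every level — and small
  biological noise (SD 0.05 log2), keeping their linear CV below 10% in
  expectation.
- A fraction of family genes (default 0.10) is never expressed in any
  sampled condition (near-zero signal): these produce the Absent calls
  that detection catalogs and RMAPS's anchor require.
- Probe effects: per-probe log2 affinities N(0, 0.5²), drawn once and
  shared across arrays (affinity is a probe property — the additive
  structure median polish assumes).
- Array technical effects: per-array gain offset N(0, 0.5²) log2 and
  intensity-response slope N(1, 0.10²); observed log2 signal is
  gain_j + slope_j · (θ + affinity). Without array-level variation every
  normalization is a no-op and the methods cannot be distinguished;
  these magnitudes are typical of heterogeneous chip collections.
- Intensities: PM = signal + N(100, 10²); MM = 10% cross-hybridized
  signal + background, both truncated at a floor of 1.0 to keep
  intensities positive (truncation slightly raises the background mean
  of signal-free probes).

Everything is reproducible bit-for-bit from the config's seed, and the
returned truth object carries per-condition and per-array true log2
expression, per-condition effect assignments, affinities and array
effects for parameter-recovery tests.

`make_boutique_subset` models the boutique chip as a biased draw from a
whole-genome simulation: all requested invariants, truly induced genes
oversampled to the requested fraction of non-invariant content, and the
remaining slots stratified so silent family members appear at their
whole-array proportion. Selection is first-k in annotation order within
each stratum — deterministic given the simulation.

What the simulator does **not** model: spatial chip artifacts, scanner
saturation, sequence-dependent affinity, probe-level outliers beyond
Gaussian background, and correlated gene modules beyond the designed
condition effects. Passing tests therefore demonstrate correctness of
the algorithms under the stated generative assumptions, not performance
on any particular real hybridization series.

## The evaluation harness

`compare_to_reference` pools all shared probe-set × array log2 pairs and
reports pooled Pearson r, per-category r (family / invariant / marker),
per-array r and RMS difference — all three conventions, so any of them
can be checked. `boutique_method_comparison` is the one-call experiment:
normalize a boutique subset by SBQ / RMAPS / RIMS and score each against
whole-array RMA of the superset. Because single-simulation correlations
of the leading methods differ by less than the simulation-to-simulation
spread, the acceptance script averages each method's r over 8
independent replicate simulations (seeds derived from `--seed`) and
compares the means — the expected ordering, not one draw.

Raw-intensity density profiles use a Gaussian KDE of log2(PM) per array
(Silverman bandwidth) on a shared 512-point grid padded by five
bandwidths so every curve integrates to 1 within 1e-3.

## Problem sizes

The acceptance computation uses 5,000-gene whole-array simulations
(3 conditions × 3 replicates), 300-probe-set boutique subsets with 150
invariants and 60% truly-shifted content, 1,000-probe-set calibration
panels, and 8 comparison replicates — sizes at which every reported
quantity is stable to well under its decision margin while the full run
stays in the low minutes on one CPU.

## Known limitations

- SBQ extrapolates outside the stable-gene range by a constant offset;
  if invariants do not span the intensity range, low/high-end genes are
  corrected only up to an additive shift.
- RMAPS is undefined when no probe set is Absent everywhere; the error
  message points the caller to RIMS/SBQ.
- The exact signed-rank enumeration is O(2^n) and intended for n ≤ ~16;
  the chip's fixed n = 11 is the design point.
- Fold changes of genes near background are attenuated by posterior-mean
  background correction (see above).
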