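# Methods

## Data model and conventions

All expression values are log2 signal intensities; one qPCR cycle equals one
log2 unit of template abundance (inverse relation). Chromosome arms are
{X, 2L, 2R, 3L, 3R, 4}. The aggregate autosome class ("A") is always
2L+2R+3L+3R; the dot fourth chromosome is reported on its own because its
heterochromatic regulation (e.g. its strong meiotic down-regulation) would
otherwise distort the autosomal reference. This exclusion is asserted
structurally: the pooled A row is computed only from the four major arms.

Replicate spots of the same probe are averaged on the **linear** scale and
re-logged, since raw array signal is linear intensity; background-subtracted
intensities can reach zero or below, so linear values are clamped at a small
positive floor (1e-6) before re-logging. Replicate arrays are collapsed by
arithmetic mean of log2 values per condition before any median statistic.

Percentages in count tables use round-half-up at one decimal (via exact
decimal arithmetic, not binary-float rounding), and sheath-effect
percentages are displayed rounded half-away-from-zero to integers.

## X:A fold statistics

For a condition, the A:X fold is `2^(median log2 A − median log2 X)` over
per-probe replicate means. Medians are taken on the log2 distributions; a
`linear_medians` switch computes the ratio of linear-scale medians instead —
the two agree except in pathological distributions, and the log2-median form
matches how the intensity distributions are summarized and plotted in this
field. Significance is a two-sided Mann–Whitney test (exact for small
samples without ties, normal approximation with tie correction otherwise,
scipy's automatic policy). The fold is invariant under common additive log2
shifts and the Mann–Whitney p under monotone transforms; both are property
tests.

Low-expression filtering removes a probe only when its replicate-mean value
is below the threshold in *every* listed condition — the filter targets
probes that are never reliably measured, not stage-specific silence. The
filter interacts with the fold estimate: truncating the lower tail of an
attenuated (location-shifted) X distribution at a fixed threshold biases the
difference of medians toward zero, so parameter-recovery experiments on
synthetic data estimate the fold on the unfiltered matrix, where the planted
shift is exact.

The quantile sweep divides the pooled X+A distribution into n quantiles
(default 10) and reports, for probes at or above each cut: X/A counts, X
proportion, Fisher's exact p for composition above versus below the cut, the
difference of class medians, and a Mann–Whitney p. Boundary ties fall in the
upper (at-or-above) side.

`dcc_impairment_ratio` is the small but load-bearing arithmetic combining
two A:X folds — compensation-impaired over control — into the fold reduction
of relative X output (1.51/1.15 → 1.31).

## Stage-transition classification

Transitions are early (premeiotic→meiotic), late (meiotic→postmeiotic) and
net (premeiotic→postmeiotic); positive log2 FC means higher later. The
default per-probe test is Welch's unequal-variance t (a pooled-variance
switch exists for sensitivity runs; the choice is not dictated by the
underlying procedure, and Welch is the robust default). Probes with zero
variance in both stages are untestable and receive p = 1 with a warning, so
they can never be called. BH step-up q-values are computed genome-wide per
transition (all arms together, one FDR regime across arms); schemes fdr05 /
fdr01 / fdr005 flag q ≤ level, and the fold2 scheme flags |log2 FC| ≥ 1
regardless of p. Stricter FDR call sets are nested within looser ones given
identical p-values, and under a full null the realized false-positive
fraction stays within binomial tolerance of the nominal level (both are
tests).

Fisher's exact X-versus-A tests use the standard two-sided convention (sum
of hypergeometric probabilities of tables no more probable than observed,
with a 1e-7 relative tie guard); the implementation is cross-checked against
exhaustive enumeration for all 2×2 tables with margins ≤ 8. A zero margin
makes the test undefined; p = 1 is returned with a warning.

## Sheath-contamination qPCR

Ct values (well-averaged per plate) are normalized by subtracting the mean
control-gene Ct within the same dissection and plate, which removes per-plate
additive offsets exactly (property-tested). The log2 fold of dissection A
over B is `normCt_B − normCt_A` averaged over plates. The sheath effect is
`100·(Ps−Pn)/(Ps−M)`, signed, undefined (NaN) at Ps−M = 0; it is invariant
to rescaling both folds. The pooled "all genes" effect uses the ratio of
across-gene mean folds (not the mean of per-gene ratios), which is the
construction that reproduces the published pooled row (1.84, 0.66 → 36%).
One published per-gene row (CG1835, printed −9%) is inconsistent with its
own printed folds (−10.3%); the package reports full precision and does not
force the printed value.

The pairing unit for paired t-tests is the plate (each plate measures all
dissections); the pooled test runs over all gene×plate pairs, and the sign
test is a two-sided exact binomial on the number of genes with positive
Ps−Pn fold (ties drop out of the denominator; twelve of twelve positive
gives p = 2·(1/2)^12 ≈ 4.9×10⁻⁴). When every paired difference is exactly
zero the paired t is reported as p = 1 rather than NaN: there is nothing to
detect.

## Transgene factorial ANOVA

`fit_factorial_anova` fits a fully crossed fixed-effects OLS model with
sum-to-zero contrasts and returns Type II (or Type I) sums of squares, F and
p per term, ordered main effects → 2-way → 3-way. Type II SS for a term is
the RSS drop from adding it to the model containing every term not
containing it; the statsmodels implementation is cross-checked in tests
against an explicit least-squares model-comparison oracle on unbalanced
data (agreement to 1e-8) and against the balance property (Type I = Type II
term-by-term in balanced designs). Rank-deficient designs raise an error
listing aliased columns. Insert line is available in the simulated designs
but is not modelled as a factor by default — the fitted models are
fixed-effects factorials only.

## Synthetic-data generator

The generator is a pure function of (design, params, seed): one
`numpy.random.Generator` consumed in a fixed order (baselines by arm, stage
shifts by transition, replicate noise by column).

* **Baselines**: two-component log2 mixture — an expressed mode N(10, 2)
  and a low "unexpressed" noise mode N(4, 1) with default weight 0.30,
  reproducing the bimodal intensity distributions that motivate the
  low-expression filter.
* **Genome composition**: per-arm gene counts default to the expressed-probe
  counts of the stage-dissection arrays (1,943 X; 2,204 2L; 2,356 2R;
  2,335 3L; 3,009 3R; 58 chr4; ~11.9k probes total).
* **Dose model**: autosomal male dose 2, X dose 1. The X log2 level is
  reduced by log2(divisor): divisor 1 under `full_dc`, `attenuation_a`
  (default 1.5) under `no_dc_buffered`, and the raw dose limit 2 under
  `no_dc_raw`. The reduction applies to a gene's whole signal, so under
  no-compensation the X distribution is an exact location shift of the
  autosomal one — which is what makes closed-form recovery checks exact.
* **Stage structure**: per-gene log2 shifts between consecutive biological
  stages drawn from a mixture defaulting to 37% down (mean −0.86, sd 0.3),
  31% up (mean +0.92, sd 0.3), 32% unchanged — matching the observed
  transition proportions and magnitudes so synthetic count tables are
  realistically populated. A `premeiotic_with_sheath` condition shares the
  premeiotic germline trajectory (same cell population, different
  dissection) rather than receiving its own transition shift.
* **MSCI**: in meiotic samples, X genes are multiplied (linear scale) by
  `1 − φ + φ/s` — a fraction φ of cells silencing the X by factor s. The
  default MSCI scenario (φ = 0.3, s = 10) is illustrative, not an estimate:
  no quantitative MSCI strength is established for flies.
* **Sheath mixing**: contaminated columns are linear convex mixtures
  `(1−f)·germline + f·soma`, where the somatic profile is the dosage-
  compensated baseline without germline stage effects. The observed X:A
  under contamination follows the closed form `(1−f)/a + f` relative to the
  autosomes, exactly at zero noise.
* **Noise**: per-replicate N(0, noise_sd) in log2, default 0.25 — typical
  replicate-array reproducibility, and at three replicates it leaves ~0.9
  log2 stage effects individually detectable, as they are on real arrays.
  Experiments specifying a different noise level pass it explicitly.
* **qPCR**: `Ct = c0 − log2(expr) + N(0, noise_sd_ct)` per plate; control
  genes are generated with zero differential across dissections.

### What the generator does and does not emulate

It reproduces the features the statistics depend on: bimodal intensities,
arm structure, stage-wise effect mixtures, X-specific attenuation under the
contrasted regulation models, somatic contamination, and plate-replicated
Ct structure. It does not emulate probe-specific affinities, correlated
(co-regulated) genes, cell-type heterogeneity beyond the two-component
mixtures, amplification-efficiency variation, or read-level RNA-seq sampling
(RPKM tables are drawn directly). Passing tests therefore demonstrate that
the pipeline recovers what it is designed to measure under these models —
not that real arrays satisfy the models.

## Problem sizes and numerical choices

Simulation-based tests use the full ~11.9k-probe genome where the planted
effect is the object under test (attenuation recovery over 20 seeds, MSCI
power) and reduced genomes (1.2k–1.6k probes) for calibration loops run
hundreds of times (FDR null over 100 seeds, fold-interval coverage over 200
seeds); each configuration states its size in the test. Tolerances on
median-based recovery reflect median sampling error (~1.25·σ/√n per class).
Degenerate inputs are handled explicitly rather than propagating NaN:
zero-variance t-tests and zero-margin Fisher tables give p = 1 with
warnings, an all-tied sign test gives p = 1, and a zero Ps−M denominator
gives a NaN sheath effect.
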