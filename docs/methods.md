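# Methods

## The model

`epiclock` implements a multi-tissue DNA-methylation age predictor of the
penalized-regression family.  The data are Illumina-array beta values
β ∈ [0, 1] (methylated / total intensity) for a set of CpG probes across
samples with known chronological age.  Training regresses a *calibrated*
age on the beta values with an elastic net:

    F(age) ~ intercept + Σ_i w_i β_i,    penalty λ (α‖w‖₁ + (1−α)/2 ‖w‖₂²)

The CpGs with nonzero weights are the *clock CpGs*; prediction forms the
weighted average of their betas and pushes it through the inverse
calibration ("DNAm age").  The mixing parameter defaults to α = 0.5 and λ
is chosen by k-fold cross-validation (default 10 folds) minimizing mean
squared error on the transformed scale, with no one-standard-error rule.

### Calibration transform

Methylation drifts quickly during growth and roughly linearly afterwards,
so age enters the regression through a piecewise map with a knot at
`adult_age` (default 20 years):

    F(a) = log(a + 1) − log(adult_age + 1)      a ≤ adult_age
    F(a) = (a − adult_age) / (adult_age + 1)    a > adult_age

Natural logarithm; both branches have slope 1/(adult_age + 1) at the knot,
so F is continuous, strictly increasing and C¹, and exactly invertible.
The "+1" inside the log keeps F(0) finite so newborns (age 0) are valid
training samples.  The inverse is not clipped: a strongly positive linear
score maps beyond any human lifespan, which is meaningful (for example,
age-accelerated tumor tissue).

### Assumptions

- Age effects on clock CpGs are linear on the transformed scale and
  additive across CpGs.
- Beta values are comparable across samples once quantile-normalized to
  the training ("gold standard") distribution.
- Missingness is ignorable: probes with ≥ `max_missing` (default 10)
  missing training values are dropped; the rest are mean-imputed.

## Key parameters

| parameter | unit | default | why |
|---|---|---|---|
| `alpha` | – | 0.5 | equal L1/L2 mix; sparse but stable under correlated CpGs |
| `cv_folds` | – | 10 | standard CV granularity for n in the hundreds |
| `adult_age` | years | 20 | knot where the clock's tick rate settles |
| `max_missing` | count | 10 | probe exclusion threshold at training |
| solver tol | – | 1e-4 | on standardized predictors; selection is unchanged vs 1e-6 on the default scenario while the CV path stays fast on one core |

Predictors are standardized internally for the penalty; coefficients are
reported on the raw beta scale so a saved coefficient CSV alone suffices
for prediction.  CV folds are stratified by `dataset_id` when present
(round-robin after a seeded shuffle), so every fold spans every cohort;
this plus cyclic coordinate descent makes refits bit-identical for fixed
inputs and seed.

### Shrinking

`shrink_clock` produces a compact sub-clock by refitting the elastic net
restricted to the current clock CpGs while increasing λ (geometric binary
search, 60 iterations) until at most `target_size` coefficients survive.
Because sparsity changes in jumps along the path, the closest achievable
size ≤ target is returned with a warning when the exact size is not on
the path.  This joint refit preserves calibration better than coefficient
thresholding would.

## Normalization and imputation

The *gold standard* summarizes the training cohort: per-probe mean betas
plus the pooled sorted betas of the probe set of interest.  Test samples
are normalized by empirical quantile mapping: each sample's observed
values are ranked (average ranks for ties) and replaced by linear
interpolation into the reference quantile vector at matching plotting
positions.  This preserves within-sample rank order exactly (Kendall
τ = 1), is idempotent, maps a sample already distributed as the reference
onto itself, and never produces values outside [0, 1].  It deliberately
replaces mixture-model-based array normalization with a distribution-free
contract; a drop-in replacement can be slotted in at
`normalize_to_gold_standard`.

Imputation (after normalization, so imputed values are already on the
reference scale) substitutes the gold-standard probe mean; observed values
are never touched, and per-sample imputation counts are reported.  At
prediction time a sample missing more than half the clock CpGs is flagged;
one missing all of them gets an error record instead of a prediction.

## Downstream statistics

- **Accuracy report** — Pearson age correlation (NaN, not 0, when ages are
  constant), median absolute error in years, and mean (dnam − age)
  ("average age acceleration").
- **Age acceleration** — difference (dnam − age) or the residual from OLS
  of dnam on age within the evaluated sample set (mean 0, uncorrelated
  with age by construction; needs ≥ 3 samples and non-constant age).
- **LOOCV by dataset** — the clock is refit excluding one whole dataset
  per fold and evaluated on it; the held-out samples never enter the fit
  (verified by a label-poisoning test that requires bit-identical fold
  models).
- **Falconer heritability** — H² = 2(r_MZ − r_DZ) clamped to [0, 1] from
  within-pair correlations of acceleration.  Since "first twin" is
  arbitrary, the default estimator enters each pair in both orderings
  (symmetrized, deterministic); a random single ordering is available for
  plotting-style analyses.  Requires ≥ 3 pairs per zygosity.
- **Biweight midcorrelation** — median/MAD based robust correlation with
  the standard tuning constant 9; a zero-MAD vector falls back to
  mean-centered unit weights for that side.
- **Meta-analysis of age effects** — per probe, Pearson correlations with
  age computed strictly within dataset (implicitly conditioning out
  dataset and tissue), Fisher-z transformed and Stouffer-combined with
  √(n−3) weights; reported as a signed log10 p (positive =
  hypermethylates with age).  Calibration is checked by a KS test for
  uniform null p-values.
- **Tissue F statistic** — per probe, extra-sum-of-squares F for tissue
  indicators on top of an age-only OLS model.  No p-value is attached:
  across a methylome most probes show some tissue effect, so the raw F is
  the informative ranking quantity.
- **Enrichment** — two-sided Fisher exact tests of clock-CpG membership
  against annotation categories (island/shore etc.), optionally run
  separately on the positively and negatively age-correlated subsets.  No
  multiple-testing correction by default; apply Bonferroni externally
  when scanning many categories.
- **Coefficient of variation** — sample SD (n−1) over mean, for
  multi-tissue same-donor comparisons.

## The synthetic-data generator

`simulate_methylome` emulates a 27K/450K-style cohort: `n_causal` of
`n_probes` CpGs drift with age, linearly on the transformed scale, with a
193:160-style split between hyper- and hypomethylating probes; Gaussian
dataset and tissue offsets; Gaussian beta-scale noise; clamping to [0, 1]
after noise (truncation bias is negligible at the default noise SD 0.02).
Ages are uniform on [0, 101] years by default.

Effect sizes are parameterized by the quantity real clock tables report:
the mean absolute difference between median betas of old (> 55 y) and
young (< 35 y) subjects, default 0.032.  Per-probe amplitudes are drawn
uniform within ±50% of the target and rescaled analytically (by the
inverse of the normalized transformed-age gap between the old and young
strata under the configured age law) so the realized old/young gap hits
the target; the default scenario measures 0.033.

Probe-level biology (causal set, signs, amplitudes, baselines) is drawn
from `probe_seed`, sample-level draws from `seed`, so
`simulate_train_test` can produce train/test cohorts that share biology —
without that, cross-cohort prediction would be meaningless.

`simulate_twin_cohort` draws acceleration = g + e per twin with
var(g) = h²·SD², MZ pairs sharing g fully and DZ pairs correlating 0.5 in
g, so Falconer's formula is unbiased for the configured h².
`twin_pairs_with_exact_correlations` constructs pair values whose
within-zygosity correlations are exact to machine precision, for worked
examples.

### What the generator does not emulate

Cell-type composition mixtures, probe chemistry (type I vs II), dye bias,
cancer methylation dysregulation, or non-uniform real-world age
distributions.  Passing recovery tests therefore demonstrates the
estimator's correctness under the stated generative model, not its
accuracy on real arrays.

## Problem sizes and numerical choices

The default recovery scenario is 400 training / 100 test samples by 2,000
probes with 150 causal CpGs, five seeds — chosen as the smallest cohort at
which elastic-net selection is stable (held-out r ≥ 0.9, > 50% of selected
CpGs causal) while a full CV fit takes seconds on one core.  Twin
recovery uses 300 + 300 pairs over 20 seeds.  Ties in quantile
normalization use average ranks; degenerate designs (constant betas,
constant age, single tissue, rank-deficient tissue design) raise typed
errors or return NaN rather than silently producing numbers.

## Known limitations

- The clock is only as transportable as the beta distribution: batches far
  from the gold standard are corrected only up to a monotone map.
- `shrink_clock` cannot always hit an exact target size.
- Falconer's formula inherits its classical assumptions (no shared-
  environment difference between MZ and DZ pairs, additivity); estimates
  are clamped, so values near 0 or 1 are boundary-biased.
- The meta-analysis assumes approximate normality of Fisher-z within each
  dataset (n ≥ ~10 per dataset for good calibration).
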