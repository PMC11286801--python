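# Methods

This note documents the statistical machinery in `clockforge`: the models,
their assumptions, the tunable parameters that matter, what the synthetic
data generator does and does not emulate, and the numerical choices that a
reader reproducing the results should know about.

## Epigenetic clocks

A clock is a sparse linear predictor of transformed age from CpG beta
values,

    t(age_i) = b0 + sum_j beta_ij * b_j + e_i,

fit by elastic-net regression with mixing parameter `alpha = 0.5`, the
midpoint between ridge and lasso. `alpha` is a convention of the field, not
a tuned quantity, and is exposed but not optimized. The penalty strength
lambda is chosen by internal 10-fold cross-validation on the training set
over a grid of 100 log-spaced values from `lambda_max` (the smallest
penalty with an all-zero solution) down to `lambda_max * 1e-4`, taking the
minimum of the mean CV error; a one-standard-error rule is available
(`lambda_rule="1se"`) and the choice is recorded in the model metadata.
Predictors are standardized internally (population standard deviation);
coefficients are reported on the original beta scale, so saved clock files
can be applied to raw beta matrices. Columns that are constant up to float
noise are dropped from the penalized fit (their coefficient is exactly 0).

Missing betas are mean-imputed per probe within the training set before
fitting, because coordinate-descent solvers need complete columns.
Screening statistics (below) instead use pairwise deletion.

### Age transforms

Three bijective regression scales, attached to the clock and serialized
with it:

* **identity** — no transformation; the default for single-species
  pan-tissue clocks.
* **log-linear** — logarithmic below a maturity age `m` and linear above,
  `f(a) = log((a + c) / (m + c))` for `a < m`, `f(a) = (a - m)/(m + c)`
  otherwise, continuous at the joint. Defaults: `m = 0.3` y (vole sexual
  maturity), offset `c = 0.06` y (just below the youngest animal in the
  reference design). This compresses fast juvenile methylation change in
  dual-species absolute-age clocks. The piecewise form is the standard
  pan-tissue-clock construction; the transform used for published
  dual-species clocks is not fully specified in print, so this is a
  documented implementation choice.
* **relative** — age divided by the species' maximum recorded lifespan
  (prairie vole 5.3 y, human 122.5 y, from the AnAge database), giving
  values in [0, 1] comparable across species. Predictions that would map
  to a negative age are clamped to zero with a warning.

### Cross-validation

Accuracy is estimated by leave-one-sample-out (LOO) or k-fold CV in which
the entire fitting procedure — imputation, standardization, penalty grid,
internal CV selection — is repeated from scratch on each training fold.
Reported metrics are the Pearson correlation R between predicted and
chronological age and the median absolute error (MAE) in years, overall
and per stratum (tissue, group, species). Strata with fewer than two
evaluated samples report R as undefined rather than failing.

**A calibration caveat that matters for null experiments.** When the data
carry no age signal, the internally selected penalty usually lands at
`lambda_max` and the fold model is intercept-only. Its LOO prediction is
the training-fold mean `(S - y_i)/(n - 1)`, an exactly decreasing function
of the held-out value, so the cross-validated R of a null clock is biased
toward -1, not centered at 0. Empirically, permuting ages on a
60-sample / 200-probe dataset gives mean LOOCV R around -0.3 over 20
permutations. Cross-validated R of a near-null predictor should therefore
never be interpreted as "0 means no signal"; the sign of the bias is
harmless for detecting real clocks (it deflates, never inflates, R) but a
permutation null band must be computed empirically, not assumed symmetric
around zero.

## Age acceleration and group comparisons

Age acceleration is the residual of an OLS regression of DNAm age on
chronological age (per stratum when requested); positive means
epigenetically older. Residuals sum to zero within each regression stratum
by construction, so acceleration is only meaningful as a contrast between
subgroups of the regression population.

Two designs test a group effect (pair-bonded vs sex-naive):

1. **Covariate-adjusted Wald test** — OLS of acceleration on the group
   indicator plus covariates (default sex and tissue, dummy-coded with the
   alphabetically first level as reference); t = coef/se with residual
   degrees of freedom, two-sided. The covariate set is configurable; sex
   and tissue are the defaults because they are the stratification
   variables used throughout the analyses.
2. **Cross-applied group clocks** — a clock trained on all samples of one
   group is applied to adults (age > 0.3 y, strict) of the other.
   Estimates are age-adjusted by regressing them on chronological age
   *within the evaluation group* and keeping the residual; per-tissue
   one-sample two-sided t-tests then ask whether the mean deviation
   differs from 0. If all deviations in a tissue are identical the t-test
   is reported as degenerate rather than raising.

Two structural properties of design 2, verified empirically and worth
knowing before interpreting results:

* The within-group age adjustment absorbs any effect that is purely a
  *rate* (slope) change. A group that ages, say, 1.5x faster produces a
  steeper estimate-vs-age line, which the adjustment removes exactly, so
  the per-tissue mean deviations stay centered at zero. The test detects
  *level* shifts (a group being uniformly older/younger than its age
  predicts), not rate differences. Simulations with a 1.5x aging-rate
  multiplier at n = 40 per tissue per group confirm the per-tissue tests
  reject only at chance level, while the unadjusted deviation from the
  identity line carries the signal strongly.
* Because per-tissue means of residuals from a pooled regression are
  weakly negatively coupled (they sum to ~0 across tissues), the t-tests
  are very mildly conservative; the measured null rejection rate at
  nominal 5% over 400 simulated tissue tests was 4.0%.

## EWAS screening

**Age.** Per tissue, each CpG's Pearson correlation r with age
(pairwise-complete), `t = r * sqrt((n-2)/(1-r^2))` with a two-sided p from
the t distribution on n-2 df, and the Fisher z-score
`z = atanh(r) * sqrt(n-3)`. |r| is clipped at `1 - 1e-12` before `atanh`
so perfect correlations give large finite z rather than infinity.
Zero-variance CpGs are emitted with p = 1 and a flag, never dropped
silently.

**Trait.** Per sex-by-tissue stratum, restricted to adults (> 0.3 y,
because below that age one group cannot exist), an OLS fit of
`beta ~ trait + age` per CpG; the Wald statistic of the trait coefficient
with n-3 residual df gives the two-sided p. Direction "gain" means
hypermethylated in the non-reference level (sex-naive is the conventional
reference). The screen operates on beta values, matching the convention of
the standard screening workflow; an M-value variant is not provided.

**Meta-analysis.** Stouffer's weighted z,
`z_meta = sum(w_i z_i)/sqrt(sum w_i^2)` with `w_i = sqrt(n_i)` (unit
weights available). A single stratum passes through unchanged; records
with missing z are excluded with a count.

**Selection and overlap.** Thresholds are nominal and strict (p < 1e-5
for age, p < 0.005 for the trait); no multiple-testing correction is
applied to the headline selections, though BH-adjusted p-values are
available as an optional column. The cross-stratum overlap keeps probes
significant in at least `min_strata` strata (default 3) with identical
direction everywhere they are significant. A probe with a genuine effect
in a single tissue is truly significant in the two sex-strata of that
tissue, so it needs only one chance hit among the remaining strata (an
expected ~0.4 probes per run at these thresholds) to enter a min-3
overlap list; the overlap list is a high-enrichment summary, not a pure
multi-tissue set.

## Genomic-context enrichment

Foreground CpGs (a selection) are contrasted with a background (default:
all annotated probes; for chromatin states, all probes with a non-NA
state) by Fisher's exact test on the 2x2 table
(foreground / background-minus-foreground) x (in / out of category). The
odds ratio is the sample odds ratio `(a*d)/(b*c)`, with infinity encoded
explicitly for empty background cells, and the two-sided p is the standard
exact convention (sum of table probabilities no more likely than
observed). When the foreground covers the whole background there is no
contrast and OR = 1, p = 1 is reported. Significance stars follow strict
thresholds 0.05 / 0.01 / 0.001 / 0.0001.

TSS-distance bins default to promoter (-2000..+500 bp, signed, negative =
upstream), proximal (within 5 kb, excluding the promoter window) and
distal (everything else); the bins are a conventional choice and are
configurable. The CpG-island contrast is a Welch two-sample t-test of the
aging Fisher z-scores of island vs non-island CpGs.

## Synthetic data generator

For probe j and sample i the generator draws

    logit(beta_ij) ~ Normal(mu_j + a_j * F_i + s_j * [male_i]
                            + d_{j,tissue_i} + g_j * [bonded_i, affected],
                            sigma)

and maps through the logistic, so betas are strictly inside (0, 1).
Baselines `mu_j` come from a bimodal mixture (modes at logit +/-2,
sd 0.5), imitating the genome-wide U-shaped beta distribution. The age
regressor is F = age/lifespan * 5.3 — i.e. age in years for voles, and
lifespan-scaled for an optional long-lived second species, so aging
effects are conserved on the relative-age scale across species.

Default study conditions mirror the reference design: four tissues
(blood, brain, ear, liver), both sexes, pair-bonded vs sex-naive groups
allocated round-robin, ages uniform on [0.063, 1.31] years with
pair-bonded animals restricted to > 0.3 y, vole lifespan 5.3 y. The
benchmark configuration is 200 samples, 2000 probes, 100 age CpGs at
|2| logits/year, 30 sex CpGs (|1| logit), 100 tissue CpGs (+1 logit in
one tissue each), 5 multi-tissue and 50 single-tissue group CpGs
(|1| logit), residual sd 0.3 logits. Every spiked CpG is registered in a
ground-truth table, so sensitivity and false-discovery proportion of any
selection can be scored exactly.

Effects are additive on the *logit* scale while the screening models are
linear on the *beta* scale — a deliberate mild mismatch mirroring real
data, where linear screens are approximations. An optional placement rule
puts the age CpGs in promoters or islands to exercise the enrichment
stack. The generator does not simulate array chemistry, batch effects,
probe cross-reactivity, cell-composition shifts, or read-level noise, so
passing recovery benchmarks demonstrates correctness of the statistical
machinery under the assumed generative model, not robustness to
real-world artifacts.

## Numerical choices

* Elastic-net paths are solved to tolerance 1e-3 during penalty
  selection; the final model is refit at the chosen penalty, warm-started
  from the path solution, at 1e-5. Fixed-penalty fits (used for solver
  verification) are solved at 1e-12. The selection-stage tolerance
  trades a sub-1% perturbation of the CV curve for a several-fold
  speedup of leave-one-out evaluation.
* Fold assignment is seeded and shuffled; LOO needs no assignment seed
  but each fold's internal CV is seeded deterministically from the base
  seed, so repeated runs are bit-identical.
* Problem sizes used in the shipped analyses: the clock benchmark runs
  LOOCV at n = 200 with 2000 probes; calibration experiments use 60-320
  samples and 200-20,000 probes depending on how many replicates the
  experiment needs. These sizes were chosen so each experiment is a few
  minutes at most on one core while keeping Monte-Carlo error well below
  the effect sizes under test.
* Coordinates are 1-based inclusive in annotation; BED export converts
  to 0-based half-open. Probes-as-rows is the on-disk matrix convention,
  with an orientation flag for transposed inputs.

## Known limitations

* The sex estimator (nearest centroid on the 50 CpGs most correlated
  with annotated sex, leave-one-out for training samples) is a simple
  reproducible construction, not a reimplementation of any published
  estimator; with real data a dedicated X/Y-probe-based check is
  preferable.
* The pipeline's hierarchical-clustering QC uses 1 - Pearson distance
  with average linkage; purity is evaluated by cutting the tree at the
  label cardinality, which underestimates separation when clusters are
  nested or unbalanced.
* Trait EWAS assumes a binary trait and a single age covariate;
  interactions (e.g. group x age) are out of scope, which is exactly why
  a pure aging-rate difference is invisible to both the trait screen and
  the cross-applied clock test (see above).
* Dual-species fits apply no per-species sample weighting; with strongly
  unbalanced species blocks the clock is dominated by the larger block
  (a `--species-balance` style reweighting is deliberately not applied
  by default).
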