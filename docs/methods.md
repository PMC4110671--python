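# Methods

`methylrisk` implements a blood-cell DNA-methylation risk-signature
workflow: an epigenome-wide association scan over array beta values, a
stacked elastic-net classifier collapsed to a sparse linear signature,
and the validation battery used to judge such a signature on
independent prospective cohorts. A synthetic-data module generates
cohorts with the statistical structure the analysis assumes, so every
stage can be exercised and checked against planted ground truth.

## Data model

Methylation is represented as beta values, the fraction of methylated
signal at a CpG: beta = Max(M,0)/(Max(M,0)+Max(U,0)+100), where M and U
are the methylated/unmethylated fluorescence intensities. The +100
offset is the array-platform convention; it keeps the ratio in [0, 1)
and stabilises low-intensity probes. Matrices are CpG x sample;
per-sample covariates (binary group label, age in years, categorical
batch, cancer status, optional follow-up time and event flag, free-form
epidemiological factors) live in a sample sheet. All file formats are
plain text (TSV beta matrix, CSV sheets/annotations/signatures, GMT
gene sets) and all readers reject invariant violations — duplicate
ids, betas outside [0, 1) — naming the offending cell, rather than
coercing.

## Synthetic cohorts

The generator emulates a two-arm array study on the logit scale, where
effects are additive and the inverse logit keeps betas inside (0, 1):

- Per-CpG baselines are drawn from a two-component logit-normal mixture
  (modes near beta 0.1 and 0.85, logit SD 0.5, 40% methylated mode),
  mimicking the bimodal landscape of promoter arrays.
- A configurable subset of CpGs ("planted") receives a carrier-only
  mean shift of `effect_delta` logits, with a `hyper_fraction` (default
  0.57) of positive directions. When an annotation is supplied, the
  hypermethylated planted CpGs are drawn with weight `pcgt_enrichment`
  (default 3) toward CpGs of a polycomb-target-like gene set, giving
  the enrichment stage real signal.
- Confounders: per-(batch, CpG) intercepts ~ N(0, `batch_sd`), small
  per-CpG age slopes (~N(0, 0.005) per year) and cancer-status offsets
  (~N(0, 0.1)), plus i.i.d. Gaussian residual noise of SD `noise_sd`.
- Prospective cohorts reuse the discovery cohort's per-CpG baselines
  and covariate slopes (one "platform"), scale the planted effects by
  `attenuation`, and add uniform follow-up times, an event flag for the
  uncensored fraction of cases, and epidemiological factors drawn
  independently of case status (so factor tests are null by design).

Default `noise_sd` is 1.0 logit. This is the realistic magnitude of
between-person variation in blood methylation and it keeps single CpGs
from perfectly separating 72+72 cohorts: with an effect of 2 logits the
per-CpG standardized difference is then ~1.9, large enough for reliable
recovery yet small enough that the per-CpG logistic MLE exists. Much
smaller residual SDs make planted CpGs separate the groups exactly, at
which point any honest logistic scan must flag rather than test them.

What the generator does **not** emulate: probe-type chemistry
differences, cell-composition mixtures, SNP-affected probes,
correlation between neighbouring CpGs, and non-Gaussian batch
structure. Passing tests therefore demonstrate the statistical
machinery is correct under the declared generative model, not that the
pipeline is robust to every artefact of real arrays.

All randomness derives from one integer seed through independent
sub-streams (`numpy` `SeedSequence` spawn keys), so every artifact is
reproducible bit-for-bit.

## Differential methylation scan

For each CpG, a logistic regression of group status on (beta, age,
batch indicator contrasts, cancer status) is fitted by maximum
likelihood (statsmodels); the beta term's Wald z gives a two-sided
p-value. Wald rather than likelihood-ratio testing is the cheapest
per-CpG choice and standard for EWAS scans. CpGs whose fit does not
converge or whose likelihood is monotone (perfect separation, detected
by fitted probabilities within 1e-6 of the outcomes) are flagged and
conservatively assigned p = 1, with the direction taken from the raw
group contrast; all-missing CpGs are dropped.

Multiple testing uses q-values: pi0 is estimated on the lambda grid
0.05, 0.10, ..., 0.95 via pi0(lambda) = #{p > lambda}/(m(1-lambda))
with a cubic-polynomial smoother evaluated at the right end of the grid
and clipped to (0, 1]; q-values are the pi0-adjusted step-up transform,
which reduces exactly to Benjamini-Hochberg when pi0 = 1. Candidates
are CpGs with q strictly below the FDR threshold (default 0.3, the
relaxed discovery setting). The hyper/hypo split of the candidates is
tested against Binomial(n, 1/2) with an exact two-sided test under the
point-probability rule.

## Signature derivation

Base learner: elastic-net penalized logistic regression, objective

    -(1/n) sum_i [y_i eta_i - log(1 + exp(eta_i))]
        + lambda (alpha ||b||_1 + (1-alpha)/2 ||b||_2^2),

with mixing alpha = 0.1 (ridge-leaning, keeps correlated CpGs
together). The path over a 30-point log-spaced lambda grid (data-driven
maximum, min ratio 0.01) is solved by iteratively-reweighted least
squares with cyclic coordinate descent, warm starts, and a saturation
stop (the path halts once >99% of the null deviance is explained,
carrying the last fit forward — smaller penalties only overfit). The
solver is numba-compiled: one signature derivation needs on the order
of a thousand cross-validated paths, which rules out slower generic
solvers on a single CPU. Features are imputed (per-CpG mean) and
standardized to zero mean, unit variance before penalization; the
training means and scales are stored in the signature so scoring new
cohorts is self-contained.

Ensemble: `n_base` (default 100) base classifiers are fitted, each with
its own stratified 10-fold cross-validation partition (sub-seeds
derived from the global seed). Within each base fit, lambda minimises
the summed out-of-fold binomial deviance (no one-standard-error rule;
ties favour the sparser penalty) and the model is refit on all data at
the chosen lambda. The meta step fits a logistic model of the outcome
on the n_samples x n_base matrix of out-of-fold linear predictors with
non-negative weights and a free intercept (L-BFGS-B with bounds);
non-negativity preserves each base classifier's orientation. Because
every base score is linear in the standardized betas, the stacked model
collapses exactly to one coefficient vector — the weighted sum of base
coefficient vectors — and CpGs with a combined coefficient of exactly
zero are dropped. A `mean` meta rule (equal weights) is available as a
degenerate alternative. Positive coefficients mark CpGs hypermethylated
in carriers.

The base learners train on the FDR-selected candidate CpGs by default
(`use_all_cpgs` lifts the restriction). The signature's intercept-free
linear score is all that downstream validation uses, since rank-based
AUC is shift-invariant.

## Validation

- **Scoring**: score = sum over signature CpGs present in the cohort of
  coefficient x (beta - training mean)/training scale. Missing probes
  (platform differences) are intersected away without renormalising the
  remaining coefficients; missing individual betas contribute the
  training mean (zero after standardization). Both counts are reported.
- **Discrimination**: AUC computed by midranks over all case-control
  pairs (ties count 1/2), reported with Somers' Dxy = 2 AUC - 1, a 95%
  CI from the DeLong placement-variance estimator, and a one-sided
  p-value for AUC > 0.5 (the risk-prediction hypothesis is
  directional). With zero variance (all scores tied) the p-value is 0.5.
- **Dichotomisation**: "high" = score strictly above the evaluated
  group's arithmetic mean. The mean (not the median) is the declared
  reading of an "above average" split; with all scores equal, everyone
  is "low".
- **Survival**: Kaplan-Meier curves and the two-group log-rank test come
  from lifelines. The hazard ratio uses an in-package Cox fit for a
  single binary covariate with Breslow tie handling (lifelines
  implements Efron only), Newton-Raphson to |gradient| < 1e-8, Wald 95%
  CI. When every event falls in one group the partial likelihood is
  monotone and the HR is reported as non-estimable rather than as a
  number; the same applies to a single-event dataset, where no finite
  maximiser exists. With zero events the KM curves are still returned
  (constant at 1) and the log-rank p is NaN with a warning.
- **Factor tests**: 2x2 tables use Fisher's exact test, two-sided by the
  point-probability rule (sum of hypergeometric probabilities not
  exceeding the observed one, with 1+1e-7 relative slack against float
  ordering); continuous factors use Welch's unequal-variance t with
  Satterthwaite degrees of freedom, accepted as summary statistics so
  printed mean (SD) tables can be checked directly.

## Enrichment

Over-representation replaces ranked GSEA: for a fixed CpG list the
hypergeometric upper tail is the standard reduction. Query CpGs are
mapped to genes through the one-gene-per-row annotation and
deduplicated (a gene with three query CpGs counts once); the universe
is the scanned CpG set mapped to genes, not the genome.
Benjamini-Hochberg adjusts across sets. A second helper tests the
overlap of two CpG sets within a probe universe with the same upper
tail.

## Numerical choices and edge cases

- Two-sided exact tests return exactly 1.0 when the observed table/count
  sits at the distribution's mode (no term excluded), avoiding
  1 - 1e-16 artefacts from summing the full support.
- Coordinate-descent tolerance 1e-4 (max coefficient change) for CV
  work; oracle comparisons in the tests tighten it to 1e-9. IRLS
  weights are floored at 1e-5.
- Elastic-net support size is not exactly monotone along the penalty
  path (coordinates may re-enter); the property holds and is tested at
  coarse grain (4x-separated penalties).
- Lambda-grid maximum uses alpha floored at 1e-3 so ridge-leaning
  mixtures still get a finite grid.
- Covariates with no variation (e.g. cancer status in a cohort sampled
  before any diagnosis) are dropped from the scan design rather than
  left to make every per-CpG fit singular.
- Signature size does not shrink monotonically with signal strength:
  at weaker effects cross-validation tends to select a denser penalty,
  spreading smaller coefficients over more CpGs. What is monotone is
  the candidate count, and the signature collapses to empty (a
  "no signal retained" error) in the signal-free limit.
- Degenerate all-constant feature matrices yield an all-zero fit with a
  warning; a derivation in which every base fit is all-zero (no signal)
  raises rather than returning an empty signature.
- Byte-identical outputs: all writers format floats with 12 significant
  digits; rerunning any stage with the same seed reproduces files
  bit-for-bit.

## Problem sizes

The package's reference study conditions are desk-scale: 5,000 CpGs
with 500 planted effects, 72+72 discovery samples, 120+120 prospective
samples, 100 base classifiers. The full 27,578-CpG scale of a real
27k array is available through `SimConfig(n_cpgs=...)`. At the
reference scale a complete derivation (scan + 100-classifier stack)
takes a few minutes on one CPU; unit tests and examples use smaller
cohorts (hundreds to 2,000 CpGs, 2-10 base classifiers) chosen to keep
each check fast while preserving the tested property.

## Known limitations

- The per-CpG scan treats CpGs independently; no surrogate-variable or
  inflation correction is applied beyond the modelled covariates.
- The q-value pi0 smoother is a cubic polynomial on the lambda grid, a
  simple stand-in for spline smoothers; under very non-uniform p-value
  distributions the two can differ.
- The Cox model is single-covariate by design; multivariable adjustment
  and time-dependent effects are out of scope.
- Real-data preprocessing (IDAT parsing, normalisation, cell-type
  deconvolution) is explicitly not provided; the package starts from a
  beta matrix.
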