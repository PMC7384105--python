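# Methods

## The model

`lcpa` implements a latent class profile analysis (LPA) of multifacetted
adult outcomes in a cohort of children referred for possible autism around
age 2 (an EDX-style early-diagnosis cohort).  A finite mixture with K
latent classes explains the joint distribution of 15 adult indicators;
conditional on class membership the indicators are independent, with
family-specific conditional distributions:

* **Gaussian** (10 standardized scale totals — verbal and nonverbal IQ,
  hyperactivity, irritability, ABCL total, depression, positive and
  negative affect, well-being, daily living skills): class-specific means
  μ_jk with a **class-invariant** variance σ²_j.
* **Ordinal** (symptom severity 1–10, work 1–7, living situation 1–3,
  friendships 0–3): proportional-odds cumulative logit,
  P(Y_j = c | k) = F(τ_jc − η_jk) − F(τ_j,c−1 − η_jk) with F the standard
  logistic CDF, class-invariant cutpoints τ_j and class locations η_jk
  anchored at η_j1 = 0.
* **Count** (number of medicines): Poisson with class-specific log-rate
  λ_jk.  The likelihood is plain Poisson; a post-fit Pearson χ²/df
  diagnostic (`dispersion_diagnostic`) reports residual overdispersion.
  An extra dispersion parameter would change the model's parameter count,
  which is pinned by the published selection table (see below).

The free-parameter count is (K−1) mixing weights + Σ_gaussian (K means +
1 variance) + Σ_ordinal ((L_j−1) cutpoints + (K−1) locations) + Σ_count K
log-rates; for the default 15-indicator set this is 16K + 25 (57, 73, 89,
105 for K = 2..5).  The class-invariant variances, the anchored
cumulative-logit parameterization and the dispersion-free Poisson are the
unique combination under which these counts reproduce the published
selection table, which is the only constraint the source analysis
provides on its ordinal identification; they are therefore the defaults.
A class-specific-variance option exists (`count_parameters(...,
class_specific_variance=True)`) but is off by default.

## Estimation

Maximum likelihood by EM under **FIML/MAR**: each participant contributes
the likelihood of their observed indicators only, which is valid when
missingness depends only on observed data.  A row with no observed
indicator contributes a likelihood factor of exactly 1 and is excluded
from estimation (its posterior is the prior); BIC uses n = number of rows
with at least one observed indicator.

* E-step in log space (log-sum-exp), posterior rows normalized to 1.
* M-step: closed forms for mixing weights, Gaussian means, the pooled
  (class-invariant) variance, and Poisson rates.  The ordinal (τ_j, η_j)
  update maximizes the responsibility-weighted cumulative-logit likelihood
  on collapsed class-by-level weight tables via warm-started L-BFGS-B with
  an analytic gradient, keeping cutpoints ordered through a
  log-increment parameterization.  The update is capped at 60 inner
  iterations and never returns a point worse than its warm start, so the
  overall procedure is a generalized EM and the observed-data
  log-likelihood is monotone (checked every iteration, tolerance 1e-8).
* Starts: one k-means start on the (mean-imputed) standardized Gaussian
  block plus seeded random-assignment restarts; the library default is
  n_restarts=20, and the test and analysis runs use 2–5 restarts, which
  on the well-separated calibrated cohorts reach the same optimum (checked
  against truth-initialized EM).
* Convergence: relative log-likelihood change < 1e-6 (max 500
  iterations); variance floor 1e-4; a class whose total responsibility
  falls below 1e-3·n aborts the start ("empty class") and the next start
  runs.
* Natural logs throughout; BIC = 2·negLL + p·ln(n), smaller is better;
  per-K ties break toward fewer classes.

Label order is not identified in a mixture; `relabel_canonical` reorders
classes best-outcome-first by the anchor indicator (default adult verbal
IQ), re-anchoring ordinal locations so probabilities are untouched.

## Preprocessing

Item totals are prorated (`sum_observed × n_items / n_observed`) when at
least 80% of items are complete, otherwise missing.  Continuous
indicators are standardized to mean 0, sample variance 1 over observed
values of the analysed sample (no imputation — this matches the FIML
treatment downstream), and reversed where needed so that higher processed
scores always mean a poorer outcome.  Which scales are reversed is config
(default: IQ, positive affect, well-being and daily living are reversed).
Missingness is carried by an explicit mask, never a sentinel value,
because 0 is a legal count/ordinal score.

## Profiling

Participants are assigned to their modal class (exact ties to the lowest
index, logged).  Prevalences are reported raw and attrition-weighted;
weights are inverse-probability-of-retention weights from a logistic
dropout model on the attrition-associated covariates (minority status,
maternal education), normalized to mean 1 — the source analysis does not
specify its weighting method, so this choice is explicit and swappable.
Per-variable "variance explained" is the one-way ANOVA R² (between-class
SS over total SS) over observed values with modal labels, ordinal
variables scored by their integers — a simple descriptive percentage, not
a model-based entropy; a posterior-weighted decomposition was considered
and rejected as the default because the quantity is described as a simple
percentage of variance.

## Prediction

Staged multinomial logistic regression of the adult class on childhood
measures, Newton–Raphson with step halving.  The stage plan: nonclinical
covariates (race, gender, maternal education 1–5 treated as numeric,
site) — always retained regardless of significance, as the benchmark;
+ age-2 symptom severity; + age-2 verbal and nonverbal IQ (the baseline
model); then age-3 / age-5 / age-9 updates in which the baseline's linear
predictors enter as **fixed per-logit offsets** and only the re-assessed
measures (plus a free intercept per logit) are estimated.  This
frozen-offset construction is what makes the age-9 block tests have
(K−1)×(block size) degrees of freedom — 3 df for severity alone, 6 df for
the two IQ measures with K=4.  Wald block tests use the inverse observed
information; likelihood-ratio tests are provided as a companion with the
same df bookkeeping.  Detected separation or a singular Hessian triggers
an automatic ridge of 1e-4 with a warning.  Rows are complete cases per
stage (counts logged); late recruits are excluded from all predictive
analyses via the cohort's `include_predictive` flag.

## Internal validation

Harrell's bootstrap optimism correction.  Performance is the per-class
mean predicted probability of a participant's own assigned class.  Per
replicate: resample participants with replacement, refit the full
prediction model from scratch, and take (apparent performance of the
refit model on the bootstrap sample) − (its performance on the original
sample); the mean over B=100 replicates is the optimism, and adjusted =
naive − optimism holds exactly by construction.  The one-sentence
published description is ambiguous about which model is evaluated where;
the standard estimator from the cited methodology is the default and a
literal-sentence variant is behind `variant="literal"`.  Class labels are
treated as fixed in the loop (the LPA stage is not refit) — the
correction targets the prediction model only.  Replicates missing a class
are skipped and logged; more than 20% skipped is an error.  Bootstrap
draws are unstratified by default (stratified available).

## The synthetic cohort generator

No data were deposited with the source analysis, so every stage is
exercised on seeded synthetic cohorts calibrated to its published
four-class typology:

* Class labels from prevalences (0.22, 0.26, 0.25, 0.27).
* Gaussian indicators: truncated normals on each instrument's published
  range.  The underlying parameters are solved so the post-truncation
  mean and SD equal the published class cells; for cells whose SD/mean
  ratio no truncated normal attains (skewed scales near their floor —
  depression, hyperactivity, irritability, negative affect), the mean is
  matched exactly and the SD residual is minimized and stored in
  `sd_residuals` rather than silently absorbed.
* Ordinal indicators: the model's own cumulative-logit family.  Cutpoint
  spacing is set from the average within-class SD (latent logistic SD
  π/√3 divided by the score-scale SD) and class locations are solved by
  bisection to match the published class mean scores.
* Counts: Poisson with the published class mean as rate.
* Missingness: per-variable rates matched to the published observation
  counts, imposed MAR — the masking probability depends only on the
  always-observed maternal-education covariate (multiplier exp(0.4·z),
  normalized so the marginal rate is preserved), never on the masked
  value or, given the covariate, the class.
* Childhood predictors (severity, VIQ, NVIQ at ages 2/3/5/9; daily
  living at 2): class-conditional Gaussians whose class separation is the
  adult-profile separation scaled by a per-wave signal (0.55, 0.72, 0.73,
  0.85 at ages 2, 3, 5, 9).  These scalars are synthetic choices that
  reproduce the qualitative developmental pattern — prediction improves
  from 2 to 3, barely from 3 to 5, most by 9 — with age-9 naive
  own-class probabilities around 0.8 rather than full separability.  The
  age-2 daily-living population parameters are likewise synthetic
  stand-ins (not published).  `predictor_signal=0` gives
  class-uninformative predictors for null studies.
* Structure: late recruits (the third site) lack waves 2–5 and are
  flagged out of predictive analyses; the age-5 assessment exists only at
  the first site; attrition weights fall with minority status and low
  maternal education.

What passing tests on this generator do **not** show: real cohorts are
not conditionally independent given class, their skewed scales are not
truncated normals, their attrition is dynamic rather than a static
weight, and the true number of outcome "types" is a modelling idealization.
Recovery results here demonstrate the pipeline's correctness, not
clinical validity.

## Known limitations and scale-dependent behavior

Because the published profiles have strongly class-specific SDs while the
model's variances are class-invariant (forced by the published parameter
counts), the calibrated generator is deliberately heteroscedastic
relative to the fitted family.  The extra log-likelihood a fifth class
extracts from this misfit grows linearly with n (~0.13 nats/row) while
the BIC penalty per class grows as 8·ln(n): at the study's n=123 the
four-class model is selected in ~80–90% of replicates — mirroring the
source analysis, whose own 4→5 log-likelihood gain (22.3 nats at n=123)
is the same order — but by n=500 a fifth class usually wins
(`analysis/02_select_classes.py` tabulates this crossover).  Similarly,
"every class mean within 0.15 pooled-SD" is tighter than the sampling
noise of the extreme cell among 40 class-by-variable cells at n=1000
(cell SE ≈ 0.07 pooled-SD), so the corresponding recovery check fails for
most seeds even when computed from the true labels.  Both behaviors are
properties of the study conditions, not estimator defects; the relevant
tests assert the stated conditions and their docstrings note the
mechanism.

## Problem sizes used

Tests and analysis scripts run the generator at n=123–1000 (10–20
replicates for enumeration studies, 50 seeded runs × B=100 for the
optimism properties), chosen to keep each study's Monte Carlo error well
inside the margins it asserts.
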