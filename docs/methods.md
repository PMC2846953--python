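# Methods

This note documents the statistical model, the synthetic-data design, the
numerical choices and the known limitations of `bophmars`.

## The modeling workflow

The pipeline treats each biomarker of potential harm (WBC, EPI8, DEH11,
HDL) as a continuous response and searches for an interpretable linear
model in transformed predictors.

**Screening.**  A random forest (scikit-learn `RandomForestRegressor`,
`min_samples_leaf=5`, `max_features="sqrt"`) is fit to all candidate
predictors; variable importance is permutation importance (clipped at
zero; impurity importance is available as an alternative).  The nested
top-k sets, k = 1…30, are scored by pooled k-fold cross-validated R² of a
forest restricted to each set, with one shared seeded fold assignment so
the sequence is comparable across k.  "Natural cut points" of that
sequence are operationalized deterministically: *small* is the smallest
set within 0.02 of the sequence maximum, *medium* the smallest within
0.005 (never smaller than small), *large* the full 30-variable set; both
tolerances are configuration keys.  Each working set is then augmented
with all nine exposure biomarkers and the binary smoking-status indicator
before spline fitting.

**Spline engine.**  The forward pass adds reflected hinge pairs
max(0, x−c) / max(0, c−x) greedily.  The knot search is exact over
observed data values, subject to `min_span` (default 3): candidate knots
are every `min_span`-th order statistic with at least `min_span`
observations on each side, which prevents degenerate knots in ties and
tails.  Scoring uses the identity span{1, h⁺, h⁻} = span{1, x, h⁺}, so
the RSS for every knot of a variable reduces to one matrix product
against the current orthonormal basis plus a vectorized 2×2 solve; this
is algebraically exact, not an approximation.  Model types: 0 restricts
entries to linear terms, 1 allows additive hinge transforms, 2 allows
two-way hinge products (parents are existing non-interaction terms; a
binary child enters a product linearly).  The *entry penalty* (0 or 0.01)
is charged on the normalized lack-of-fit score once per newly entered
variable, favoring re-use of variables already in the model; we read the
"penalty for adding new variables" as this forward-pass entry cost rather
than a per-variable GCV charge — the two readings are not equivalent and
the choice is flagged here.

The backward pass deletes, at each step, the term whose removal least
increases RSS (computed from the inverse Gram diagonal), and returns the
subset minimizing GCV = (RSS/n)/(1 − C(M)/n)² with complexity
C(M) = (#terms + 1) + d·(#distinct knots).  The per-knot charge d is not
fixed by the source description; the conventional d = 3 when interactions
are searched and d = 2 otherwise is used, exposed in `FitConfig`.
GCV R² replaces the error variance in ordinary R² by GCV; an
intercept-only model with complexity 1 therefore has slightly negative
GCV R² at small n.

**Model selection.**  The default grid is 3 predictor sets × 3 model
types × 4 initial-basis counts (10, 20, 30, 60) × 2 entry penalties = 72
cells.  Among models with GCV R² within 0.01 of the best, the preferred
model has the fewest distinct variables, then the fewest parameters, then
the lowest model type, with insertion order as the final stable
tie-break.

**Threshold reparametrization.**  max(0, x−c) = IFGT(x, c) − c and
max(0, c−x) = c − IFLT(x, c) convert the fitted hinge model exactly
(fitted values preserved to float rounding) into the threshold basis
used in the coefficient tables.  At x = c both IFGT and IFLT return c —
the boundary belongs to the "otherwise" branch; strictness matters only
on a measure-zero set.  Knots are printed at full observed-value
precision, trimmed of trailing zeros.  Interaction products have no
threshold form and pass through unchanged with a warning.  The alcohol
variable is offered in both codings that appear in final models: the
ordinal cumulative dummy `DRINK.GT.1.PER.WK` and the collapsed
drinks-at-all indicator `DRINK.EQ.Y`.

**Final inference.**  Final refits use *unimputed* data: rows missing the
response or any model variable (categoricals included — the explicit
missing category is a device for the screening/spline stage only) are
dropped and counted.  Standard errors are classical OLS; p values are
two-sided from the t distribution with n − p − 1 degrees of freedom.
Validation reports both the *applied* R² (analysis-set coefficients,
validation-set mean in the denominator, so a non-transferable model is
visible as applied R² ≤ 0) and a fresh refit of the same basis, plus a
per-term significance-stability comparison at α = 0.05 without
multiplicity correction.  A basis function that is unidentifiable in a
partition (e.g. an interaction with no support among 20 % of subjects)
raises an error by default; the pipeline drops it with a warning.

**Importance.**  All transformations of one source variable form one
group (so four AST knot transforms are a single AST group).  Marginal R²
fits the group alone; delta R² is the drop in full-model R² on removal.
Nesting guarantees delta R² ≥ 0 and marginal R² ≤ full R²; in an
orthogonal design the deltas sum to the full R².

## Synthetic cohort design

The generator emulates the study conditions: 3585 smokers and 1077
nonsmokers, ~60 variables (responses, nine BOE, labs, demographics,
lifestyle, vitals and decoy questionnaire items), sparse MCAR
missingness (2 % per predictor), and below-limit-of-quantification
censoring of the exposure biomarkers in nonsmokers.

* **Joint structure** — a Gaussian copula: latent multivariate normal
  with correlation 0.5 among the nine BOE and 0.3 between BOE and the
  smoking-related labs (CRP, TRIG, HGB), mapped through per-variable
  marginal quantile transforms.  This preserves rank correlations and
  creates realistic collinearity for the screening stage; it claims no
  fidelity to the real study's marginals, which were never published.
* **Marginals** — log-normal for biomarkers and urine outputs with
  medians elevated in smokers (e.g. serum cotinine 1.2 vs 210 ng/mL);
  normal (clipped to physiologic ranges) for most labs and
  anthropometrics; two-component log-normal mixtures give AST and ALKPH
  the heavy pathological tails needed to support the reference models'
  high knots (AST 126, ALKPH 184 U/L); categorical variables are coded by
  probability thresholds on the latent normal.  Creatinine clearance is
  derived exactly as 24 h urine creatinine / serum creatinine.
* **Responses** — evaluated from the reference threshold-basis models;
  noise variance is σ² = V(1−R²)/R² with V the cohort variance of the
  linear predictor, so the population R² equals the nominal value.  By
  default the drawn noise vector is additionally centered, orthogonalized
  against the linear predictor and rescaled to exactly σ (the
  `mvrnorm(empirical=TRUE)` convention), making the cohort-level R² exact
  rather than approximate; `empirical_noise=False` restores iid noise.
* **Censoring** — each BOE's quantification threshold is its nonsmoker
  60th percentile; values below it are flagged, and flagged values are
  removed with probability 0.5 (exercising both branches of the BLLOQ
  substitution rule: flagged-and-missing becomes 0, flagged-with-value is
  kept).
* **Order of operations** — responses are generated from the complete
  predictor values; missingness and censoring are injected afterwards.
  Downstream refits therefore see mild errors-in-predictors for
  below-LOQ transforms (e.g. TOTNN.IFLT.57); at the default rates the
  effect on recovered R² and coefficients is well inside the sampling
  bands the tests allow.

What passing tests show — and do not.  Recovery of the generating R² and
coefficients demonstrates that the preprocessing, basis evaluation and
inference stack is correct *under the generator's assumptions* (MCAR
missingness, copula dependence, exogenous noise).  It says nothing about
informative missingness, inter-site variation, questionnaire structure or
any real cohort's marginals, none of which are modeled.

## Data-preparation rules

Fixed order: BLLOQ substitution → 80/20 split → per-target drop of rows
with a missing response → stratified median imputation → encoding.  The
split precedes imputation because medians are computed separately for
smokers/nonsmokers and for the analysis/validation partitions (mean of
the two central values for even strata).  Two parallel tables are kept:
the imputed one feeds screening and spline fitting; final refits use the
unimputed one.  Nominal variables emit the *full* indicator set (the
spline stage selects individual indicators, exactly how single indicators
like RACE.EQ.BLACK arise); ordinal variables emit cumulative
strictly-greater indicators.  Whether the original split was stratified
by smoking status is unknown; unstratified sampling is the default with
stratification behind a flag.  SMKYRS is excluded automatically when a
cohort contains only nonsmokers.

## Problem sizes and defaults

Unit and property tests run on purpose-built small tables.  The
end-to-end pipeline test uses the compact cohort (800 subjects, 25
predictors, the same smoker:nonsmoker ratio) with 300-tree screening
forests and 5-fold set evaluation; the full 72-cell grid completes in
about a minute and a half on one core.  Recovery checks run at the full
study size, where cohort generation takes about a second.  The ranking
operation's default of 10,000 trees matches the original screening run
and is practical at study scale, though tests use smaller forests.

## Known limitations

* Strict out-of-bag permutation importance is not implemented
  (scikit-learn exposes no OOB prediction path per tree); permutation
  importance is computed on the training table instead.
* No three-way interactions, smoothed/cubic spline variants, or
  cluster-merging of near-adjacent knots on one variable (the refit warns
  when knots fall within `min_span` of each other only via the usual
  collinearity diagnostics).
* Multiple imputation, informative missingness and robust/sandwich
  standard errors are out of scope.
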