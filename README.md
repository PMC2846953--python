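# bophmars

Adaptive regression modeling of **biomarkers of potential harm** (BOPH) in
a population of adult cigarette smokers and nonsmokers.

Cross-sectional exposure studies measure, alongside demographics and
clinical labs, two families of biomarkers: *biomarkers of exposure* (BOE —
serum cotinine, total NNAL, 1-hydroxypyrene, carboxyhemoglobin, mercapturic
acids, …) that quantify intake of cigarette-smoke constituents, and
*biomarkers of potential harm* on disease-relevant pathways — white blood
cell count (WBC, inflammation), 24 h urine 8-epi-prostaglandin F2α (EPI8,
oxidative stress), 24 h urine 11-dehydro-thromboxane B2 (DEH11, platelet
activation) and HDL cholesterol (lipid metabolism).  This package
implements, as a tested and reusable pipeline, the data-mining workflow
used to relate the two:

1. **Screening** — a random forest ranks every candidate predictor; nested
   top-*k* sets carry cross-validated R²; *large* (30 variables), *medium*
   and *small* working sets are chosen at natural cut points of the cv-R²
   sequence.
2. **Spline model discovery** — a MARS-style engine builds piecewise-linear
   models from reflected hinge pairs max(0, x−c) / max(0, c−x) with an
   exact search over observed-value knots, prunes terms by generalized
   cross-validation

       GCV = (RSS/n) / (1 − C(M)/n)²,   C(M) = (#terms+1) + d·(#knots),

   and is run over a 72-cell control grid (3 predictor sets × 3 model
   types × 4 initial-basis counts {10, 20, 30, 60} × 2 variable-entry
   penalties {0, 0.01}).  A preferred model is selected for fit
   (GCV R²) and parsimony (fewest predictors).
3. **Interpretable refit** — the hinge model is reparametrized exactly into
   the threshold basis used in the printed coefficient tables
   (`X.IFGT.c` = x if x > c else c; `X.IFLT.c` = min(x, c);
   `RACE.EQ.BLACK`, `DRINK.GT.1.PER.WK`, …) and refit by complete-case OLS
   on unimputed data, with standard errors, t and p values.
4. **Validation and importance** — the selected model is applied *and*
   refit on a held-out 20 % validation partition; group-wise marginal and
   delta R² decompose each source variable's contribution.

The original study data are proprietary, so the package ships a **seeded
synthetic cohort generator** (Gaussian-copula predictors; log-normal
exposure biomarkers elevated in smokers and frequently below the limit of
quantification in nonsmokers; MCAR missingness; BLLOQ flags) whose four
responses are generated from the published final coefficient models with
noise calibrated so each model's population R² equals its nominal value
(0.29 WBC, 0.41 EPI8, 0.29 DEH11, 0.39 HDL).  Every stage of the pipeline
can therefore be checked against a known ground truth.

## Worked example

```python
import bophmars as bm
from bophmars.synthetic import generate_cohort, default_config

cohort = generate_cohort(default_config(seed=1))      # 4662 subjects
cohort, _ = bm.apply_blloq_rule(cohort)               # flagged-missing -> 0
cohort = bm.split_analysis_validation(cohort, 0.8, seed=1001)

fit = bm.refit_ols(bm.reference_model("HDL"),
                   cohort.partition("analysis"), "HDL", meta=cohort.meta)
print(f"R2 = {fit.r2:.3f}  (n used = {fit.n_used})")
print(fit.params.head(4).round(4).to_string(index=False))
```

prints

```
R2 = 0.390  (n used = 3281)
    Parameters   Value  Std Error  t value  P value
     Intercept 58.4544     2.6973  21.6713      0.0
 COTIN.IFGT.31 -0.0301     0.0035  -8.5264      0.0
COTIN.IFGT.193  0.0271     0.0046   5.9438      0.0
  TRIG.IFGT.52 -0.5616     0.0699  -8.0384      0.0
```

The refit R² of 0.390 recovers the generating model's nominal 0.39, and
each estimate (e.g. −0.0301 for the cotinine transform above 31 ng/mL)
sits within sampling error of its generating coefficient.  The full
discovery pipeline is one call:

```python
run = bm.run_response(cohort, "HDL", seed=1)   # screen -> grid -> refit
print(run.summary_row)                          # five fit statistics
```

or from the shell:

```bash
bophmars simulate --seed 1 --out sim/ --small
bophmars run --in sim/ --target HDL --seed 1 --out out/
```

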