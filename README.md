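# traumatriage

Derivation, internal validation and deployment-ready scoring of a
vital-signs-based prediction model for **24-hour mortality in adult
trauma patients**, of the kind used for triage in busy emergency rooms
where only routinely recorded vital signs are available.

The package implements, as a tested and reusable pipeline, the full
derivation procedure of a multicentre cohort study: logistic regression
with restricted cubic splines for systolic blood pressure (SBP) and
heart rate (HR) and a linear term for the Glasgow coma scale (GCS),
per-hospital multiple imputation of missing vital signs, grouped
backward selection, bootstrap internal validation with optimism and
uniform shrinkage, and the published final model as a frozen scorer.
A synthetic-cohort generator reproduces the statistical structure of the
study data so that every stage is testable without the deposited data.

## The model

For a patient with vitals (SBP, HR, GCS), the probability of death
within 24 h of first vital-sign recording is

$$\Pr(\text{death}) = F\bigl(\beta_0 + \textstyle\sum_i \beta_i B_i(\text{SBP})
  + \sum_j \gamma_j B_j(\text{HR}) + \delta\,\text{GCS}\bigr),
  \qquad F(y) = \frac{1}{1+e^{-y}},$$

where the $B_k$ are restricted cubic spline basis functions with four
knots at the 5th/35th/65th/95th percentiles (SBP knots 80/110/121/147
mmHg, HR knots 70/86/92/118 beats/min).  With $n$ knots there are
$n-1$ basis functions; the first is the variable itself and the rest are
truncated cubic terms with boundary corrections that keep the fitted
curve linear outside the outer knots (the parameterisation produced by
Stata's `mkspline, cubic`, on which the published coefficients live).

The derivation chain is: per-hospital chained-equations imputation
(m = the worst hospital's incomplete-case percentage) → Rubin's-rules
pooling → grouped Wald backward selection at the 0.2 level → bootstrap
replication of the whole procedure (fresh imputation per replicate) →
stability filter (variables selected in >50% of replicates) → linear
shrinkage (mean bootstrap calibration slope) with re-estimated
intercept.

## Worked example

Score a patient with the published (before-shrinkage) model:

```python
>>> from traumatriage import published_model
>>> model = published_model(shrunk=False)
>>> model.linear_predictor(sbp=118, hr=88, gcs=15)
-4.095465922873196
>>> model.predict_probability(sbp=118, hr=88, gcs=15)
0.016375370823664744
>>> model.predict_probability(sbp=80, hr=130, gcs=6)
0.486253465097645
```

A patient with normal vitals and a fully alert GCS of 15 has a
predicted 24-hour mortality of about 1.6%; a hypotensive, tachycardic
patient with GCS 6 is at about 49%.  The after-shrinkage model
(`published_model(shrunk=True)`) has no published intercept and
therefore returns linear predictors and rankings only, unless you
supply a re-estimated intercept.

Run the full analysis chain on a synthetic study-scale cohort:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_screen_and_fit.py --seed 1
python analysis/03_internal_validation.py --seed 1
python analysis/04_sensitivity_analyses.py --seed 1
```

The validation step prints, for seed 1:

```
bootstrap: 50 replicates, 0 failures
inclusion frequency: sbp: 0.98, hr: 0.56, gcs: 1.00
stability-filtered model: sbp, gcs
apparent AUROCC 0.839 (IQR 0.832-0.849)
optimism 0.018 -> optimism-corrected AUROCC 0.821
shrinkage factor 0.944; re-estimated intercept 3.311
calibration slope 1.057; Hosmer-Lemeshow p 0.493 (IQR 0.382-0.626)
```

i.e. the model discriminates well (AUROCC ≈ 0.84), overfitting is
modest (optimism ≈ 0.02, shrinkage ≈ 0.94), and predicted risks track
observed mortality (calibration slope ≈ 1, non-significant
Hosmer-Lemeshow test).  At this sample size (1629 admissions, ~90
events) heart rate is a borderline predictor: it is selected in roughly
half of bootstrap replicates and the stability filter may exclude it,
which is exactly the instability the bootstrap step is designed to
expose.  Tables (sample characteristics, pooled coefficients, cut-off
operating characteristics, sensitivity analyses, the SBP×GCS risk
heatmap) are written under `results/`.

There is also a CLI over the same library:
`traumatriage generate|impute|fit|validate|score|heatmap|run|sensitivity`.

## Layout

- `src/traumatriage/` — the library: `cohort` (schema/IO/outcomes),
  `synthetic` (cohort generator), `splines` (restricted cubic bases),
  `imputation` (per-hospital chained equations), `modeling` (pooled
  fits, grouped Wald tests, backward selection), `validation`
  (bootstrap optimism/stability/shrinkage), `metrics` (AUROCC,
  calibration, cut-off tables), `scoring` (the deployable model),
  `pipeline` + `cli` (orchestration).
- `analysis/` — numbered narrative drivers for the four stages.
- `tests/` — unit, property and acceptance tests.
- `docs/methods.md` — modelling assumptions, parameter choices and
  limitations.
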