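# Methods notes

## Model and derivation procedure

The outcome is death within 24 hours of the first vital-sign recording;
patients discharged alive before 24 hours count as alive (a worst-case
sensitivity analysis recodes them as dead).  The a-priori candidate
model is logistic regression on three routinely recorded vital signs:
systolic blood pressure (SBP) and heart rate (HR) entered as restricted
cubic splines with four knots, and the Glasgow coma scale (GCS) entered
linearly.  Sample-size reasoning follows the ten-events-per-free-
parameter rule: three vitals × three variables each → 90 events.

**Spline basis.**  A restricted cubic spline with knots
$k_1 < \dots < k_n$ contributes $n-1$ basis functions: $B_1(x) = x$ and,
for $j = 1..n-2$,

$$B_{j+1}(x) = \frac{(x-k_j)_+^3 - \bigl[(x-k_{n-1})_+^3 (k_n-k_j) -
 (x-k_n)_+^3 (k_{n-1}-k_j)\bigr]/(k_n-k_{n-1})}{(k_n-k_1)^2}.$$

This is the truncated-power form with boundary corrections produced by
Stata's `mkspline, cubic`; the $(k_n-k_1)^2$ divisor keeps each basis on
roughly the scale of the raw variable, which is the scale of the
published coefficient table the scorer reproduces.  The basis is $C^2$:
value, first and second derivatives are continuous at every knot and
the function is linear outside $[k_1, k_n]$; the test suite checks all
of this plus agreement with an independent term-by-term evaluation.
Knots sit at equally spaced percentiles — (5, 35, 65, 95) for four
knots, (5, 50, 95) for three, (5, 27.5, 50, 72.5, 95) for five — using
the linear-interpolation empirical percentile (numpy's default;
percentile dialects differ across software by up to a unit in sparse
tails).  In the pipeline knots are computed per imputed dataset and the
final model freezes their elementwise median.

**Missing data.**  Vital signs and time-to-arrival are imputed by
chained equations separately within each hospital, then the completed
per-hospital sets are concatenated.  The number of imputations is the
ceiling of the worst hospital's incomplete-case percentage (e.g. 51%
→ 51 datasets), with a floor of 2.  The default per-variable method is
type-1 predictive mean matching (Bayesian linear regression, donor pool
of 5) for all four imputed variables; PMM is robust to the skewed
vital-sign distributions and automatically keeps GCS on its observed
integer scale in [3, 15].  Ordinal-logistic imputation for GCS and pure
linear-regression draws are available by configuration; the
ordinal-logistic route falls back to PMM when the fit fails, and PMM is
the default because fitting a 13-category ordered logit inside every
hospital stratum of every imputation cycle is fragile and slow at the
stratum sizes this design produces.  Categorical variables, if ever
missing, use multinomial-logistic draws.  The 24-hour outcome is always
a predictor in the conditional models and is itself never imputed; rows
missing the outcome are excluded with a logged count (conservative
choice).  Ten chained-equation cycles are run (configurable; the
procedure's source does not state a count; chained equations typically
stabilise well before ten cycles at these missingness levels).
Hospitals with fewer than 20 rows or a constant predictor fall back to
pooled (all-hospital) imputation with a warning.  Random-number streams
are derived per hospital × imputation from one master seed, so results
are bitwise reproducible.

**Pooling and selection.**  Per-dataset maximum-likelihood logistic
fits are pooled with Rubin's rules: coefficients by the mean,
covariance as $\bar W + (1 + 1/m)B$.  Predictor significance uses
grouped Wald tests ($c^\top \Sigma^{-1} c$ against $\chi^2_{df}$, all
spline coefficients of one vital jointly); a 1-df block reduces exactly
to the squared z-test.  Backward selection at the 0.2 level first
simplifies splines hierarchically (4 → 3 knots → linear) whenever the
joint test of the nonlinear components is nonsignificant, then removes
the group with the largest joint p ≥ 0.2, refits, and repeats.  The
same 0.2 level governs both reduction and removal (configurable).  Ties
break by largest p then reverse listing order, making the result
invariant to term order.  GCS is offered to selection as linear in the
primary pipeline (a configuration flag offers it as a spline instead);
the lowess screen supports this choice with a departure-from-linearity
index (fraction of the smoothed log-odds variation a straight line
leaves unexplained; values above ~0.2 flag curvature).  The index is
advisory: with ~90 events it is noisy, and the functional-form decision
is an a-priori modelling choice, not an automated one.

**Internal validation.**  The complete procedure — resample patients
with replacement from the original incomplete cohort, impute afresh,
select, pool — is replicated in B bootstrap samples (300 at full scale;
desk-scale runs use 50, with 5 imputations per replicate since
replicating the full worst-hospital m hundreds of times adds nothing at
these sizes).  Each replicate model is evaluated in its own sample and
in the original imputed stack (medians across imputed datasets, the
same convention used to report all multiply-imputed performance
measures).  Optimism is the mean bootstrap-minus-original AUROCC
difference; the shrinkage factor is the mean calibration slope of the
replicate linear predictor in the original sample — the standard
bootstrap uniform-shrinkage estimator, chosen because the source
procedure states the factor but not the estimator (a heuristic
model-chi-square alternative exists but is not implemented).  The final
model keeps variables selected originally and in >50% of replicates
(strictly greater), multiplies non-intercept coefficients by the
shrinkage factor, and re-estimates the intercept per imputed dataset by
an intercept-only logistic fit with the shrunk linear predictor as
offset (solved robustly as a bracketed root of the score equation),
pooled by the mean — so mean predicted risk equals observed mortality
by construction.  Replicate-level failures (separation in a resample)
are logged and skipped; more than 20% failures aborts the run.

**Performance metrics.**  AUROCC is the Mann–Whitney concordance
(ties half-weighted).  The Hosmer–Lemeshow test uses 10 near-equal-size
risk groups (df = groups − 2; groups of zero expected count merge with
a neighbour; 2 groups is rejected as df would be 0).  The calibration
slope is the coefficient of a logistic refit of the outcome on the
linear predictor.  The cut-off table reports, for each target
sensitivity, the largest probability cut-off achieving at least it;
false-positive percentages are on the base of all non-events and
false-negative percentages on all events — the bases of the published
table's percentage columns are not defined, so raw counts are emitted
alongside and either convention can be recomputed.  AUROCC comparisons
between models use a paired DeLong test per imputed dataset with the
median p reported; the source prints comparison p-values without naming
a method, so exact agreement is not claimed.

## Synthetic cohort generator

The generator emulates the study conditions and is the test bed for
every stage: n = 1629 admissions (default) across three hospitals with
weights 0.40/0.35/0.25; 6% target 24-hour mortality reached by
bisection of the intercept (tolerance 0.1 percentage points on the
realised covariates); 2% early live discharges drawn independently of
vitals; age 15 + gamma(2, 12) (median ≈ 35); 80% male; mechanism-of-
injury frequencies matching the published sample table; log-normal
time-to-arrival (median ≈ 7 h) mildly shorter for sicker patients.
Vitals come from a two-component mixture: a 90% "stable" component
(SBP ≈ N(118, 12), HR ≈ N(89, 13), GCS mass 0.70 at 15 with a rising
spread over 3–14) and a 10% physiologically deranged component with
lower SBP, higher HR and low GCS, coupled through a shared severity
latent — giving the negative SBP–HR correlation one expects in shock
(an assumption: the source reports no inter-vital correlations).  The
true log-odds are parameterised directly on the package's own spline
basis at fixed knots (the published locations), nonlinear in SBP and
HR and linear in GCS, with coefficients matching the published
before-shrinkage table (HR basis 1 uses −0.005, a value that prints as
−0.00 at table precision but is not exactly zero), so generator truth
and fitted coefficients share a basis and parameter recovery is
well-defined.  Missingness is missing-at-random by construction: a
single uniform draw per patient shared across the four maskable
variables (documentation failures cluster within patients), compared
against per-hospital, per-variable rates that yield ~20%/18%/20%/6%
overall missingness for SBP/HR/GCS/arrival-time and incomplete-case
proportions of ~1%, ~17% and ~50% across hospitals; rates may be
multiplied up for non-survivors or by age (observed fields only).

What the generator does **not** reproduce: the real joint distribution
of vitals beyond the mixture sketch above, injury-severity anatomy,
hospital case-mix differences (hospitals differ only in size and
missingness), or non-random missingness.  Passing tests therefore show
that the *procedure* behaves correctly under a faithful MAR/logistic
data-generating process, not that the published coefficients are the
truth of any real population.

## Numerical choices and degenerate inputs

- Logistic fits: Newton MLE with a BFGS fallback; nonconvergence,
  |coefficient| > 50, or a single-class outcome raise a fit failure
  naming the imputation index.  Rare mechanism-of-injury categories
  (<10 patients) merge into "other" in the full-model design to avoid
  quasi-separated dummies.
- Lowess screening spreads tied predictor values deterministically over
  a quarter of the smallest level gap before smoothing; otherwise the
  local regression is degenerate at heavy ties such as GCS 15.
  Smoothed probabilities are clipped to [1e-3, 1 − 1e-3] before the
  log-odds transform.
- Knot placement raises a degenerate-knots error naming the variable
  when ties collapse two percentiles.
- The scorer refuses missing inputs (it never imputes), rejects GCS
  outside [3, 15], and scores but warns on vitals far outside the knot
  span (splines extrapolate linearly there by construction).
- The published after-shrinkage intercept was not printed, so the
  published shrunk model emits linear predictors only unless the user
  supplies a re-estimated intercept; the unshrunk variant (constant
  2.21) gives absolute probabilities.  Multiplying the printed unshrunk
  table by the printed shrinkage factor 0.90 reproduces the printed
  shrunk SBP and HR rows at two decimals but not the GCS row
  (−0.23 × 0.90 = −0.207 → −0.21 vs printed −0.20): the published
  shrinkage was evidently applied to unrounded coefficients.

## Problem sizes used in tests and the acceptance script

Structure-recovery checks run at n = 10,000 (complete data, 10 seeds);
imputation behaviour at n = 4,000 with m = 5; the validation machinery
at n = 2,000 with B = 50 and 5 imputations per replicate; the
acceptance script runs the full chain once at the study scale
(n = 1629, m from the worst-hospital rule, B = 50).  These sizes were
chosen so the whole suite exercises every stage at statistically
meaningful scale while staying comfortably runnable on a laptop core;
the 300-replicate, m = 51 full-scale configuration is available through
the same interfaces (`RunConfig(B=300, m="auto")`).

## Known limitations

- Selection p-values are computed on the pooled Rubin fit with a
  chi-square reference, not the Barnard–Rubin small-sample F; with
  ~50 imputations and n ≈ 1600 the difference is negligible.
- No multilevel (random-effects) imputation or modelling across
  hospitals; stratification is the design's approach.
- Bootstrap resampling is unstratified by default (a flag enables
  per-hospital stratification); the source does not state which was
  used.
- At the study scale heart rate is a borderline predictor (bootstrap
  inclusion ≈ 0.5), so desk-scale runs may finish with an SBP + GCS
  model; this mirrors the reported finding that the reduced SBP + GCS
  model performs on par with the three-vital model.
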