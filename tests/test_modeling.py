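"""Pooled fitting, Rubin's rules, grouped Wald tests, backward selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from traumatriage import (CohortSpec, backward_select, default_full_spec,
                          fit_pooled, generate_cohort, joint_wald,
                          lowess_screen, truth_of)
from traumatriage.imputation import ImputedStack
from traumatriage.modeling import (FitFailureError, ModelSpec, PooledFit,
                                   Term, linear, rcs)


def test_modelspec_rejects_duplicates_and_bad_knot_counts():
    with pytest.raises(ValueError):
        ModelSpec((linear("sbp"), rcs("sbp", 4)))
    with pytest.raises(ValueError):
        rcs("sbp", 6)


def test_modelspec_roundtrips_through_dict():
    spec = default_full_spec(fixed_knots={"sbp": (80, 110, 121, 147)})
    again = ModelSpec.from_dict(spec.to_dict())
    assert again == spec


def test_m1_pooled_fit_equals_single_mle(stack_10k):
    spec = default_full_spec()
    pooled = fit_pooled(stack_10k, spec)
    import statsmodels.api as sm
    from traumatriage.modeling import build_design

    X, _, _ = build_design(stack_10k.datasets[0], spec)
    res = sm.Logit(stack_10k.datasets[0]["died_24h"].astype(float), X).fit(disp=0)
    assert np.allclose(pooled.params, res.params, atol=1e-8)
    assert np.allclose(pooled.cov, res.cov_params(), atol=1e-8)


def test_rubin_two_imputation_closed_form():
    """fit_pooled on a two-dataset stack matches manually pooling the two
    per-dataset MLEs with W-bar + (1 + 1/m) B."""
    import statsmodels.api as sm

    from traumatriage.modeling import build_design

    spec = ModelSpec((linear("gcs"),))
    d1 = generate_cohort(CohortSpec(n=1500, seed=61)).df
    d2 = d1.copy()
    # perturb one dataset as an imputation would
    d2.loc[d2.index[:200], "gcs"] = 15
    pooled = fit_pooled(ImputedStack([d1, d2]), spec)

    params, covs = [], []
    for d in (d1, d2):
        X, _, _ = build_design(d, spec)
        res = sm.Logit(d["died_24h"].astype(float), X).fit(disp=0)
        params.append(res.params)
        covs.append(res.cov_params())
    mean_params = (params[0] + params[1]) / 2
    wbar = (covs[0] + covs[1]) / 2
    dev = [p - mean_params for p in params]
    between = np.outer(dev[0], dev[0]) + np.outer(dev[1], dev[1])  # / (m-1) = 1
    expected = wbar + (1 + 1 / 2) * between
    assert np.allclose(pooled.params, mean_params, atol=1e-12)
    assert np.allclose(pooled.cov, expected, atol=1e-12)


def test_pooled_variance_at_least_within_variance():
    """On real imputed stacks the pooled diagonal dominates W-bar."""
    from traumatriage import impose_missingness, mice_impute

    spec = CohortSpec(n=2000, seed=9)
    masked = impose_missingness(generate_cohort(spec), spec)
    stack = mice_impute(masked, m=4, seed=9)
    fit = fit_pooled(stack, default_full_spec(fixed_knots=spec.knots))
    total = np.diag(fit.cov)
    within = np.diag(fit.within_cov)
    assert np.all(total >= within - 1e-12)
    assert np.any(total > within + 1e-12)


def test_joint_wald_one_df_equals_squared_z(stack_10k):
    fit = fit_pooled(stack_10k, default_full_spec())
    z = fit.params["gcs"] / fit.se()["gcs"]
    p_z = 2 * stats.norm.sf(abs(z))
    assert joint_wald(fit, "gcs") == pytest.approx(p_z, abs=1e-10)


def test_joint_wald_matches_brute_force_quadratic_form():
    idx = ["a", "b", "c"]
    coefs = pd.Series([0.3, -0.2, 0.15], index=idx)
    S = np.array([[0.04, 0.01, 0.0], [0.01, 0.05, -0.01], [0.0, -0.01, 0.03]])
    fit = PooledFit(
        params=coefs, cov=pd.DataFrame(S, index=idx, columns=idx),
        within_cov=pd.DataFrame(S, index=idx, columns=idx), m=1,
        spec=ModelSpec((rcs("v", 4),)), groups={"v": idx},
        knots_by_dataset=[], nobs=0,
    )
    stat = coefs.to_numpy() @ np.linalg.inv(S) @ coefs.to_numpy()
    assert joint_wald(fit, "v") == pytest.approx(stats.chi2.sf(stat, 3), abs=1e-12)


def test_joint_wald_zero_block_gives_p_one():
    idx = ["a", "b"]
    fit = PooledFit(
        params=pd.Series([0.0, 0.0], index=idx),
        cov=pd.DataFrame(np.eye(2), index=idx, columns=idx),
        within_cov=pd.DataFrame(np.eye(2), index=idx, columns=idx), m=1,
        spec=ModelSpec((rcs("v", 3),)), groups={"v": idx},
        knots_by_dataset=[], nobs=0,
    )
    assert joint_wald(fit, "v") == pytest.approx(1.0)


def test_lowess_flags_nonlinear_vitals_not_gcs():
    cohort = generate_cohort(CohortSpec(n=20000, seed=5))
    indexes = {v: lowess_screen(cohort, v)[3] for v in ("sbp", "hr", "gcs")}
    assert indexes["gcs"] < 0.2  # truth is linear in the log odds
    assert indexes["sbp"] > 0.2  # truth is J-shaped
    assert indexes["hr"] > 0.2


def test_lowess_errors_on_constant_input(complete_cohort_4k):
    cohort = complete_cohort_4k.copy()
    cohort.df["sbp"] = 120.0
    with pytest.raises(ValueError):
        lowess_screen(cohort, "sbp")
    cohort2 = complete_cohort_4k.copy()
    cohort2.df["died_24h"] = False
    with pytest.raises(ValueError):
        lowess_screen(cohort2, "sbp")


def test_alpha_one_keeps_full_spec(stack_10k):
    full = default_full_spec()
    selected, trace = backward_select(stack_10k, full, alpha=1.0)
    assert selected.terms == full.terms


def test_selection_invariant_to_term_order(stack_10k):
    spec_a = ModelSpec((rcs("sbp", 4), rcs("hr", 4), linear("gcs")))
    spec_b = ModelSpec((linear("gcs"), rcs("hr", 4), rcs("sbp", 4)))
    sel_a, _ = backward_select(stack_10k, spec_a)
    sel_b, _ = backward_select(stack_10k, spec_b)
    assert {t.variable: (t.form, t.k) for t in sel_a.terms} == \
           {t.variable: (t.form, t.k) for t in sel_b.terms}


def test_null_cohort_usually_empties_the_model():
    drops = 0
    n_seeds = 6
    for seed in range(n_seeds):
        spec = CohortSpec(
            n=1500, seed=900 + seed,
            true_coefficients={"sbp": (0, 0, 0), "hr": (0, 0, 0), "gcs": 0.0},
        )
        stack = ImputedStack.from_complete(generate_cohort(spec))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel, _ = backward_select(stack, default_full_spec())
        if not sel.terms:
            drops += 1
    assert drops >= n_seeds // 2


def test_single_class_outcome_raises(stack_10k):
    df = stack_10k.datasets[0].copy()
    df["died_24h"] = False
    with pytest.raises(FitFailureError):
        fit_pooled(ImputedStack([df]), default_full_spec())
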