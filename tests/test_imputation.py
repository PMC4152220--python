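"""Chained-equations imputation: the m rule, validity, and MAR behaviour."""

import numpy as np
import pandas as pd
import pytest

from traumatriage import (CohortSpec, choose_m, fit_pooled, generate_cohort,
                          impose_missingness, mice_impute, truth_of)
from traumatriage.cohort import Cohort
from traumatriage.imputation import ImputationError, ImputedStack
from traumatriage.modeling import ModelSpec, linear, rcs


def _hospital_cohort(proportions, n_per=200, seed=0):
    """Cohort where hospital i has exactly the given incomplete fraction."""
    rng = np.random.default_rng(seed)
    frames = []
    for i, prop in enumerate(proportions):
        spec = CohortSpec(n=n_per, seed=seed + i,
                          hospital_weights={f"h{i}": 1.0})
        df = generate_cohort(spec).df
        k = int(round(prop * n_per))
        df.loc[df.index[:k], "sbp"] = np.nan
        frames.append(df)
    return Cohort(pd.concat(frames, ignore_index=True))


def test_choose_m_is_worst_hospital_percentage():
    cohort = _hospital_cohort([0.01, 0.30, 0.51])
    assert choose_m(cohort) == 51


def test_choose_m_complete_cohort_is_zero(complete_cohort_4k):
    assert choose_m(complete_cohort_4k) == 0


def test_choose_m_single_hospital():
    cohort = _hospital_cohort([0.10])
    assert choose_m(cohort) == 10


def test_choose_m_minimum_two_when_anything_missing():
    cohort = _hospital_cohort([0.005])
    assert choose_m(cohort) == 2


def test_complete_cohort_imputes_to_identical_copies(complete_cohort_4k):
    stack = mice_impute(complete_cohort_4k, m=2, seed=0)
    assert stack.m == 2
    pd.testing.assert_frame_equal(stack.datasets[0], stack.datasets[1])
    pd.testing.assert_frame_equal(stack.datasets[0], complete_cohort_4k.df)


def test_observed_cells_never_change(masked_cohort_4k):
    stack = mice_impute(masked_cohort_4k, m=3, seed=1)
    for var in ("sbp", "hr", "gcs", "tti_hours"):
        obs = masked_cohort_4k.df[var].notna()
        for df in stack:
            assert (df.loc[obs, var] == masked_cohort_4k.df.loc[obs, var]).all()
            assert df[var].notna().all()


def test_imputed_gcs_stays_integer_in_range(masked_cohort_4k):
    stack = mice_impute(masked_cohort_4k, m=2, seed=2)
    for df in stack:
        gcs = df["gcs"]
        assert gcs.between(3, 15).all()
        assert (gcs == gcs.round()).all()


def test_between_imputation_variance_positive(masked_cohort_4k):
    stack = mice_impute(masked_cohort_4k, m=4, seed=3)
    miss = masked_cohort_4k.df["sbp"].isna()
    means = [df.loc[miss, "sbp"].mean() for df in stack]
    assert np.var(means) > 0


def test_imputed_marginal_close_to_premasking_truth():
    spec = CohortSpec(n=4000, seed=11)
    complete = generate_cohort(spec)
    masked = impose_missingness(complete, spec)
    stack = mice_impute(masked, m=3, seed=11)
    miss = masked.df["sbp"].isna()
    true_mean = complete.df.loc[miss, "sbp"].mean()
    for df in stack:
        assert abs(df.loc[miss, "sbp"].mean() - true_mean) / true_mean < 0.05


def test_m_below_two_rejected_when_values_missing(masked_cohort_4k):
    with pytest.raises(ImputationError):
        mice_impute(masked_cohort_4k, m=1, seed=0)


def test_small_stratum_falls_back_to_pooled_model():
    spec = CohortSpec(n=400, seed=5,
                      hospital_weights={"a": 0.96, "b": 0.04})
    spec.missingness["rates"] = {
        v: {"a": 0.2, "b": 0.3} for v in ("sbp", "hr", "gcs", "tti_hours")
    }
    masked = impose_missingness(generate_cohort(spec), spec)
    assert (masked.df["hospital_id"] == "b").sum() < 20
    with pytest.warns(UserWarning, match="pooled"):
        stack = mice_impute(masked, m=2, seed=5)
    for df in stack:
        assert df[["sbp", "hr", "gcs", "tti_hours"]].notna().all().all()


def test_ordinal_gcs_imputation_stays_on_scale():
    spec = CohortSpec(n=1200, seed=21)
    masked = impose_missingness(generate_cohort(spec), spec)
    stack = mice_impute(masked, m=2, seed=21, iterations=3,
                        methods={"gcs": "ordinal"})
    for df in stack:
        assert df["gcs"].between(3, 15).all()
        assert (df["gcs"] == df["gcs"].round()).all()


def test_linear_method_clips_gcs_to_scale():
    spec = CohortSpec(n=1200, seed=22)
    masked = impose_missingness(generate_cohort(spec), spec)
    stack = mice_impute(masked, m=2, seed=22, iterations=3,
                        methods={"gcs": "linear", "sbp": "linear"})
    for df in stack:
        assert df["gcs"].between(3, 15).all()
        assert df["sbp"].notna().all()


def test_deterministic_under_fixed_seed(masked_cohort_4k):
    a = mice_impute(masked_cohort_4k, m=2, seed=42)
    b = mice_impute(masked_cohort_4k, m=2, seed=42)
    for da, db in zip(a, b):
        pd.testing.assert_frame_equal(da, db)


def test_mi_corrects_outcome_dependent_mar_and_keeps_coverage():
    """With missingness depending strongly on the outcome, dropping
    incomplete cases biases the model intercept (selection on the
    outcome); multiple imputation removes most of that bias and its
    pooled confidence intervals cover the generator truth."""
    mspec = ModelSpec((rcs("sbp", 4), rcs("hr", 4), linear("gcs")),
                      fixed_knots=dict(CohortSpec().knots))
    bias_mi, bias_cc = [], []
    covered = total = 0
    n_seeds = 20
    for seed in range(n_seeds):
        spec = CohortSpec(n=4000, seed=700 + seed)
        spec.missingness["died_multiplier"] = 3.0
        complete = generate_cohort(spec)
        truth = dict(truth_of(spec), const=complete.truth["intercept"])
        masked = impose_missingness(complete, spec)
        stack = mice_impute(masked, m=5, seed=seed)
        fit_mi = fit_pooled(stack, mspec)
        cc = masked.df.dropna(subset=["sbp", "hr", "gcs", "tti_hours"])
        fit_cc = fit_pooled(ImputedStack([cc.reset_index(drop=True)]), mspec)
        bias_mi.append(fit_mi.params["const"] - truth["const"])
        bias_cc.append(fit_cc.params["const"] - truth["const"])
        se = fit_mi.se()
        for name, tv in truth.items():
            total += 1
            covered += abs(fit_mi.params[name] - tv) <= 1.96 * se[name]
    assert abs(np.mean(bias_mi)) < abs(np.mean(bias_cc))
    assert covered / total >= 0.90
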