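"""Metric implementations against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

from traumatriage import (auroc, calibration_slope, cutoff_table, delong_test,
                          hosmer_lemeshow, pooled_metric)
from traumatriage.metrics import UndefinedMetricError, calibration_bins


def auc_oracle(p, y):
    """O(n^2) pairwise concordance with half credit for ties."""
    pos = p[y]
    neg = p[~y]
    wins = sum((pi > ni) + 0.5 * (pi == ni) for pi in pos for ni in neg)
    return wins / (len(pos) * len(neg))


def test_auroc_equals_pairwise_concordance_on_random_vectors(rng):
    for _ in range(50):
        n = rng.integers(8, 40)
        p = rng.choice(np.round(rng.random(6), 2), size=n)  # force ties
        y = rng.random(n) < 0.4
        if y.all() or not y.any():
            continue
        assert auroc(p, y) == pytest.approx(auc_oracle(p, y), abs=1e-12)


def test_auroc_boundaries():
    y = np.array([False, False, True, True])
    assert auroc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
    assert auroc(np.full(4, 0.3), y) == 0.5
    with pytest.raises(UndefinedMetricError):
        auroc(np.array([0.1, 0.2]), np.array([True, True]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_auroc_complement_symmetry_and_monotone_invariance(seed):
    rng = np.random.default_rng(seed)
    n = 30
    p = rng.random(n)
    y = np.r_[True, False, rng.random(n - 2) < 0.5]
    a = auroc(p, y)
    assert a + auroc(1 - p, y) == pytest.approx(1.0, abs=1e-12)
    assert auroc(np.exp(3 * p), y) == pytest.approx(a, abs=1e-12)


def test_hosmer_lemeshow_matches_hand_arithmetic():
    # three risk groups of three, each contributing exactly 1/3 by hand:
    # g1: p=.1 x3, O=0: (0-.3)^2 / (.3*(1-.3/3)) = .09/.27 = 1/3
    # g2: p=.2 x3, O=1: (1-.6)^2 / (.6*(1-.6/3)) = .16/.48 = 1/3
    # g3: p=.5 x3, O=2: (2-1.5)^2 / (1.5*(1-1.5/3)) = .25/.75 = 1/3
    p = np.r_[np.full(3, 0.1), np.full(3, 0.2), np.full(3, 0.5)]
    y = np.array([False, False, False,
                  True, False, False,
                  True, True, False])
    with pytest.warns(UserWarning, match="fewer"):
        stat, pval = hosmer_lemeshow(p, y, groups=3)
    assert stat == pytest.approx(1.0, abs=1e-12)
    assert pval == pytest.approx(stats.chi2.sf(1.0, 1), abs=1e-12)


def test_hosmer_lemeshow_rejects_degenerate_group_count():
    p = np.linspace(0.01, 0.99, 50)
    y = p > 0.5
    with pytest.raises(ValueError):
        hosmer_lemeshow(p, y, groups=2)


def test_hosmer_lemeshow_type_one_error_near_nominal(rng):
    """Predictions drawn from the true model: ~5% rejections at 0.05."""
    rejections = 0
    n_sim = 200
    for _ in range(n_sim):
        lp = rng.normal(-2.5, 1.2, size=1200)
        p = expit(lp)
        y = rng.random(1200) < p
        if y.sum() < 5:
            continue
        _, pval = hosmer_lemeshow(p, y)
        rejections += pval < 0.05
    assert rejections / n_sim < 0.12


def test_calibration_slope_halves_under_doubled_lp(rng):
    lp = rng.normal(-2.0, 1.5, size=50_000)
    y = rng.random(len(lp)) < expit(lp)
    assert calibration_slope(lp, y) == pytest.approx(1.0, abs=0.05)
    assert calibration_slope(2 * lp, y) == pytest.approx(0.5, abs=0.05)
    assert calibration_slope(-lp, y) < 0


def test_cutoff_table_matches_exhaustive_sweep(rng):
    p = rng.random(10).round(2)
    y = np.array([True] * 4 + [False] * 6)
    table = cutoff_table(p, y, sensitivities=[100, 75, 50])
    for _, row in table.iterrows():
        target = row["target_sensitivity"] / 100
        # brute force: best (largest) cutoff among all candidate thresholds
        best = None
        for t in np.unique(p):
            sens = (p[y] >= t).mean()
            if sens >= target and (best is None or t > best):
                best = t
        assert row["cutoff"] == pytest.approx(best)
        assert row["specificity"] == pytest.approx(100 * (p[~y] < best).mean())
        assert row["false_positives"] == (p[~y] >= best).sum()
        assert row["false_negatives"] == (p[y] < best).sum()


def test_cutoff_table_boundaries():
    p = np.r_[np.linspace(0.6, 0.9, 4), np.linspace(0.1, 0.4, 6)]
    y = np.array([True] * 4 + [False] * 6)
    perfect = cutoff_table(p, y, sensitivities=[95, 50])
    assert (perfect["specificity"] == 100.0).all()
    # sensitivity 100 with overlapping predictions catches all non-events
    p2 = np.r_[np.full(4, 0.2), np.full(6, 0.5)]
    t = cutoff_table(p2, y, sensitivities=[100])
    assert t.loc[0, "specificity"] == 0.0
    assert t.loc[0, "false_positives"] == 6


def test_cutoff_table_specificity_nonincreasing_in_sensitivity(rng):
    p = rng.random(500)
    y = rng.random(500) < 0.3
    t = cutoff_table(p, y)
    spec_by_rising_sens = t.sort_values("target_sensitivity")["specificity"]
    assert (np.diff(spec_by_rising_sens) <= 1e-12).all()


def test_pooled_metric_median_iqr():
    m = pooled_metric([0.85, 0.85, 0.86])
    assert m.median == pytest.approx(0.85)
    single = pooled_metric([0.7])
    assert single.median == single.q25 == single.q75 == 0.7
    grid = pooled_metric(np.linspace(0.1, 0.9, 9))
    assert grid.median == pytest.approx(0.5)


def test_calibration_bins_partition_counts(rng):
    p = rng.random(1000)
    y = rng.random(1000) < p
    bins = calibration_bins(p, y, bins=10)
    assert bins["count"].sum() == 1000
    assert bins["observed_proportion"].between(0, 1).all()
    assert bins["mean_predicted"].is_monotonic_increasing


def test_delong_detects_better_predictor(rng):
    n = 2000
    y = rng.random(n) < 0.3
    signal = y + rng.normal(0, 0.8, n)
    noise = rng.normal(0, 1, n)
    auc_a, auc_b, p = delong_test(signal, noise, y)
    assert auc_a > 0.7 and abs(auc_b - 0.5) < 0.1
    assert p < 0.001
    _, _, p_same = delong_test(signal, signal + 1e-9, y)
    assert p_same > 0.9
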