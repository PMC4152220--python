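"""The deployable scorer and the published-model constants."""

import numpy as np
import pandas as pd
import pytest

from traumatriage import FinalModel, KnotSet, published_model
from traumatriage.scoring import (MissingInputError, RangeWarning,
                                  shrink_published_coefficients)
from test_splines import oracle_basis


def test_zero_coefficients_return_intercept():
    model = FinalModel(
        coefficients={"sbp": (0, 0, 0), "hr": (0, 0, 0), "gcs": (0.0,)},
        knots={"sbp": (80, 110, 121, 147), "hr": (70, 86, 92, 118)},
        intercept=-1.5,
    )
    assert model.linear_predictor(sbp=100, hr=90, gcs=10) == pytest.approx(-1.5)


def test_published_unshrunk_lp_matches_term_by_term_oracle():
    model = published_model(shrunk=False)
    sbp, hr, gcs = 118.0, 88.0, 15
    b_sbp = oracle_basis(sbp, (80, 110, 121, 147))
    b_hr = oracle_basis(hr, (70, 86, 92, 118))
    expected = (
        2.21
        + np.dot([-0.02, -0.04, 0.38], b_sbp)
        + np.dot([-0.00, -0.02, 0.22], b_hr)
        + (-0.23) * gcs
    )
    assert model.linear_predictor(sbp=sbp, hr=hr, gcs=gcs) == pytest.approx(
        expected, abs=1e-12
    )
    assert model.predict_probability(sbp=sbp, hr=hr, gcs=gcs) == pytest.approx(
        1 / (1 + np.exp(-expected)), abs=1e-12
    )


def test_lower_gcs_raises_predicted_risk():
    model = published_model(shrunk=False)
    lp_alert = model.linear_predictor(sbp=120, hr=90, gcs=15)
    lp_coma = model.linear_predictor(sbp=120, hr=90, gcs=3)
    assert lp_coma > lp_alert  # negative GCS coefficient


def test_probability_monotone_in_gcs_nonmonotone_in_sbp_hr():
    model = published_model(shrunk=False)
    gcs = np.arange(3, 16)
    p = model.predict_probability(sbp=np.full(13, 120.0), hr=np.full(13, 90.0),
                                  gcs=gcs)
    assert np.all(np.diff(p) < 0)
    sbp = np.arange(80.0, 160.0, 1.0)
    lp_sbp = model.linear_predictor(sbp=sbp, hr=np.full_like(sbp, 90.0),
                                    gcs=np.full_like(sbp, 15.0))
    assert np.any(np.diff(lp_sbp) > 0) and np.any(np.diff(lp_sbp) < 0)
    hr = np.arange(70.0, 120.0, 0.5)
    lp_hr = model.linear_predictor(sbp=np.full_like(hr, 120.0), hr=hr,
                                   gcs=np.full_like(hr, 15.0))
    assert np.any(np.diff(lp_hr) > 0) and np.any(np.diff(lp_hr) < 0)


def test_shrunk_published_model_has_no_intercept():
    model = published_model(shrunk=True)
    assert model.intercept is None
    lp = model.linear_predictor(sbp=100, hr=90, gcs=10)  # rankings still work
    assert np.isfinite(lp)
    with pytest.raises(ValueError, match="intercept"):
        model.predict_probability(sbp=100, hr=90, gcs=10)
    with_const = published_model(shrunk=True, intercept=1.0)
    assert 0 < with_const.predict_probability(sbp=100, hr=90, gcs=10) < 1


def test_printed_shrinkage_arithmetic_on_published_rows():
    shrunk = shrink_published_coefficients(0.90, decimals=2)
    assert shrunk["sbp"][2] == pytest.approx(0.34)  # 0.38 * 0.90 -> 0.34
    assert shrunk["hr"][2] == pytest.approx(0.20)  # 0.22 * 0.90 -> 0.20
    # the GCS row does not survive naive rounding: -0.23 * 0.90 = -0.207,
    # which rounds to -0.21 while the published table prints -0.20 (the
    # authors shrank unrounded coefficients); assert the arithmetic fact
    assert shrunk["gcs"] == pytest.approx(-0.21)


def test_scorer_refuses_missing_inputs():
    model = published_model(shrunk=False)
    with pytest.raises(MissingInputError):
        model.linear_predictor(sbp=np.nan, hr=90, gcs=10)
    with pytest.raises(MissingInputError):
        model.score_frame(pd.DataFrame({"sbp": [100.0], "hr": [90.0]}))


def test_out_of_range_vitals_scored_with_warning():
    model = published_model(shrunk=False)
    with pytest.warns(RangeWarning):
        lp = model.linear_predictor(sbp=300.0, hr=90.0, gcs=15)
    assert np.isfinite(lp)


def test_gcs_outside_scale_rejected():
    model = published_model(shrunk=False)
    with pytest.raises(ValueError, match="gcs"):
        model.linear_predictor(sbp=120, hr=90, gcs=17)


def test_batch_scoring_equals_rowwise_calls(rng):
    model = published_model(shrunk=False)
    df = pd.DataFrame({
        "sbp": rng.uniform(80, 150, 20).round(0),
        "hr": rng.uniform(70, 118, 20).round(0),
        "gcs": rng.integers(3, 16, 20),
    })
    scored = model.score_frame(df)
    for _, row in scored.iterrows():
        single = model.predict_probability(sbp=row["sbp"], hr=row["hr"],
                                           gcs=row["gcs"])
        assert row["probability"] == pytest.approx(single, abs=1e-14)
    again = model.score_frame(df)
    pd.testing.assert_frame_equal(scored, again)  # bitwise reproducible


def test_json_roundtrip(tmp_path):
    model = published_model(shrunk=False)
    path = tmp_path / "model.json"
    model.to_json(path)
    again = FinalModel.from_json(path)
    assert again.linear_predictor(sbp=100, hr=95, gcs=7) == pytest.approx(
        model.linear_predictor(sbp=100, hr=95, gcs=7), abs=1e-14
    )
    assert again.shrinkage == model.shrinkage
    assert again.provenance == "published"


def test_heatmap_grid_and_monotonicity():
    model = published_model(shrunk=False)
    single = model.risk_heatmap([100.0], [10.0], hr_fixed=90.0)
    assert single.iloc[0, 0] == pytest.approx(
        model.predict_probability(sbp=100, hr=90, gcs=10)
    )
    grid = model.risk_heatmap(np.arange(60, 201, 10.0), np.arange(3, 16.0),
                              hr_fixed=88.0)
    assert grid.shape == (15, 13)
    # probability decreases along increasing GCS in every SBP row
    assert (grid.diff(axis=1).iloc[:, 1:] < 0).all().all()
    # reduced model without heart rate needs no hr_fixed
    reduced = FinalModel(
        coefficients={"sbp": (-0.02, -0.04, 0.34), "gcs": (-0.2,)},
        knots={"sbp": (80, 110, 121, 147)}, intercept=1.0,
    )
    assert reduced.risk_heatmap([120.0], [15.0]).shape == (1, 1)


def test_coefficient_count_must_match_basis():
    with pytest.raises(ValueError):
        FinalModel(coefficients={"sbp": (-0.02, -0.04)},
                   knots={"sbp": (80, 110, 121, 147)}, intercept=0.0)
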