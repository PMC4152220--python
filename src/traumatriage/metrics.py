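"""Discrimination, calibration and operating-characteristic summaries.

Metrics are computed per imputed dataset and pooled as median with
interquartile range, the reporting convention used for multiply imputed
performance measures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """The metric is undefined (e.g. a single-class outcome)."""


def _check_classes(outcome) -> np.ndarray:
    y = np.asarray(outcome, dtype=bool)
    if y.all() or not y.any():
        raise UndefinedMetricError("outcome contains a single class")
    return y


def auroc(predicted, outcome) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties counted half)."""
    y = _check_classes(outcome)
    return float(roc_auc_score(y, np.asarray(predicted, dtype=float)))


def hosmer_lemeshow(predicted, outcome, groups: int = 10):
    """Hosmer-Lemeshow goodness-of-fit test on deciles of risk.

    Patients are ordered by predicted probability and split into
    ``groups`` near-equal-size risk groups; the statistic is
    sum (O - E)^2 / (E (1 - E/n_g)) referred to chi-square with
    ``groups - 2`` degrees of freedom.  Groups with zero expected count
    are merged with their neighbour.
    """
    if groups < 3:
        raise ValueError("Hosmer-Lemeshow needs >=3 groups (df = groups - 2)")
    p = np.asarray(predicted, dtype=float)
    y = _check_classes(outcome).astype(float)
    if len(p) < 10 * groups:
        warnings.warn(f"fewer than {10 * groups} observations for {groups} risk groups")
    order = np.argsort(p, kind="mergesort")
    p, y = p[order], y[order]
    bins = [(b.sum(), float(p[i].sum()), len(i))
            for i, b in ((idx, y[idx]) for idx in np.array_split(np.arange(len(p)), groups))
            if len(i)]
    merged = []
    for obs, exp, n in bins:
        if exp == 0 or exp == n:
            if merged:
                o0, e0, n0 = merged.pop()
                merged.append((o0 + obs, e0 + exp, n0 + n))
                logger.info("merged a degenerate risk group with its neighbour")
                continue
        merged.append((obs, exp, n))
    stat = 0.0
    for obs, exp, n in merged:
        denom = exp * (1.0 - exp / n)
        if denom <= 0:
            continue
        stat += (obs - exp) ** 2 / denom
    df = groups - 2
    return float(stat), float(stats.chi2.sf(stat, df))


def calibration_slope(linear_predictor, outcome) -> float:
    """Slope of a logistic refit of the outcome on a linear predictor.

    A slope of 1 indicates well-scaled predictions; below 1, the model's
    risk estimates are too extreme (overfitting).
    """
    y = _check_classes(outcome).astype(float)
    lp = np.asarray(linear_predictor, dtype=float)
    X = sm.add_constant(lp)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # separation
        raise UndefinedMetricError(f"calibration refit failed: {exc}") from exc
    if abs(res.params[1]) > 1e3:
        raise UndefinedMetricError("calibration refit separated")
    return float(res.params[1])


def calibration_bins(predicted, outcome, bins: int = 10) -> pd.DataFrame:
    """Observed event proportion across quantile bins of predicted risk."""
    p = np.asarray(predicted, dtype=float)
    y = _check_classes(outcome).astype(float)
    order = np.argsort(p, kind="mergesort")
    rows = []
    for idx in np.array_split(order, bins):
        if len(idx) == 0:
            continue
        rows.append({
            "mean_predicted": float(p[idx].mean()),
            "observed_proportion": float(y[idx].mean()),
            "count": int(len(idx)),
        })
    return pd.DataFrame(rows)


def cutoff_table(predicted, outcome, sensitivities=None) -> pd.DataFrame:
    """Operating characteristics at target sensitivity levels.

    For each target sensitivity (percent), the largest probability
    cutoff achieving at least that sensitivity (predictions at or above
    the cutoff are test-positive).  False-positive percentages are on
    the base of all non-events and false-negative percentages on the
    base of all events; raw counts are emitted so either percentage
    convention can be recomputed.
    """
    if sensitivities is None:
        sensitivities = list(range(95, 45, -5))
    p = np.asarray(predicted, dtype=float)
    y = _check_classes(outcome)
    ev = np.sort(p[y])[::-1]  # event probabilities, descending
    non = p[~y]
    n_ev, n_non = len(ev), len(non)
    rows = []
    for s in sensitivities:
        k = int(np.ceil(s / 100.0 * n_ev))
        if k < 1 or k > n_ev:
            raise UndefinedMetricError(f"sensitivity {s}% unattainable with {n_ev} events")
        cut = ev[k - 1]
        sens = float((ev >= cut).sum()) / n_ev
        fp = int((non >= cut).sum())
        fn = int((ev < cut).sum())
        rows.append({
            "target_sensitivity": s,
            "sensitivity": 100.0 * sens,
            "specificity": 100.0 * (1.0 - fp / n_non),
            "cutoff": cut,
            "false_positives": fp,
            "false_positive_pct": 100.0 * fp / n_non,
            "false_negatives": fn,
            "false_negative_pct": 100.0 * fn / n_ev,
        })
    return pd.DataFrame(rows)


@dataclass
class MedianIQR:
    median: float
    q25: float
    q75: float

    def __repr__(self):
        return f"{self.median:.3g} (IQR {self.q25:.3g}-{self.q75:.3g})"


def pooled_metric(values) -> MedianIQR:
    """Median and interquartile range of a per-imputation metric."""
    v = np.asarray(list(values), dtype=float)
    if len(v) == 0:
        raise ValueError("no values to pool")
    return MedianIQR(float(np.median(v)), float(np.percentile(v, 25)),
                     float(np.percentile(v, 75)))


def delong_test(pred_a, pred_b, outcome):
    """Paired comparison of two correlated AUCs (DeLong).

    Returns ``(auc_a, auc_b, p_value)`` for the two-sided test of equal
    areas when both prediction vectors are evaluated on the same
    outcomes.
    """
    y = _check_classes(outcome)
    preds = np.vstack([np.asarray(pred_a, dtype=float), np.asarray(pred_b, dtype=float)])
    pos, neg = preds[:, y], preds[:, ~y]
    m, n = pos.shape[1], neg.shape[1]

    def midrank(x):
        order = np.argsort(x, kind="mergesort")
        ranks = stats.rankdata(x)  # average ranks handle ties
        del order
        return ranks

    aucs = np.empty(2)
    v01 = np.empty((2, m))
    v10 = np.empty((2, n))
    for r in range(2):
        allv = np.concatenate([pos[r], neg[r]])
        tx = midrank(pos[r])
        ty = midrank(neg[r])
        tz = midrank(allv)
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01)
    s10 = np.cov(v10)
    var = (s01 / m + s10 / n)
    d = aucs[0] - aucs[1]
    se2 = var[0, 0] + var[1, 1] - 2 * var[0, 1]
    if se2 <= 0:
        return float(aucs[0]), float(aucs[1]), 1.0
    z = d / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(aucs[0]), float(aucs[1]), float(p)
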