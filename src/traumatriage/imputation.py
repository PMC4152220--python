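"""Multiple imputation by chained equations, run separately per hospital.

The number of imputed datasets follows the rule used in the source study
design: compute, within each hospital, the proportion of patients with at
least one missing value among the modelled variables, and create as many
datasets as the percentage in the hospital with the most missing data
(e.g. proportions of 1%, 30% and 51% give m = 51).

Each hospital's records are imputed separately, then the per-hospital
completed sets are concatenated into m full datasets.  The default
per-variable method is predictive mean matching (type-1 matching, donor
pool of 5): a Bayesian linear regression of the variable on all other
schema variables plus the outcome, with imputed values drawn from the
observed values of the nearest predicted-mean donors.  PMM is robust to
the skewed vital-sign distributions and, for the Glasgow coma scale,
automatically returns observed integers in [3, 15].  Pure
linear-regression draws and ordinal-logistic imputation are available per
variable by configuration; categorical variables use multinomial
logistic draws.  The 24-hour outcome is always included as a predictor
and is itself never imputed: rows missing the outcome are excluded with
a logged count.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, MODELLED_VARIABLES, MECHANISMS

logger = logging.getLogger(__name__)

DEFAULT_METHODS = {
    "sbp": "pmm",
    "hr": "pmm",
    "tti_hours": "pmm",
    "gcs": "pmm",  # "ordinal" available; PMM keeps donors in [3, 15]
    "mechanism": "nominal",
    "sex": "nominal",
}

#: variables whose imputed values must stay in a closed range
RANGES = {"gcs": (3, 15)}


class ImputationError(RuntimeError):
    pass


@dataclass
class ImputedStack:
    """m completed copies of a cohort, tagged by imputation index."""

    datasets: list
    rule_trace: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def to_long_frame(self) -> pd.DataFrame:
        """Single long-format frame with an ``imputation`` column (1-based)."""
        frames = []
        for i, df in enumerate(self.datasets, start=1):
            f = df.copy()
            f.insert(0, "imputation", i)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_complete(cls, cohort: Cohort, m: int = 1) -> "ImputedStack":
        if cohort.df[MODELLED_VARIABLES].isna().any().any():
            raise ImputationError("cohort has missing modelled values")
        return cls([cohort.df.copy() for _ in range(m)], {"m": m, "note": "complete"})


def choose_m(cohort: Cohort, modelled_variables=None) -> int:
    """Number of imputed datasets: ceiling of the worst hospital's
    incomplete-case percentage; 0 if nothing is missing, at least 2
    otherwise."""
    variables = MODELLED_VARIABLES if modelled_variables is None else modelled_variables
    df = cohort.df
    incomplete = df[variables].isna().any(axis=1)
    if not incomplete.any():
        return 0
    worst = incomplete.groupby(df["hospital_id"]).mean().max()
    return max(2, math.ceil(100.0 * worst))


def _encode_predictors(df: pd.DataFrame, target: str) -> np.ndarray:
    """Numeric design matrix (with intercept) from all other variables."""
    cols = [np.ones(len(df))]
    if target != "age":
        cols.append(df["age"].to_numpy(dtype=float))
    for var in ("tti_hours", "sbp", "hr", "gcs"):
        if var != target:
            cols.append(df[var].to_numpy(dtype=float))
    if target != "sex":
        cols.append((df["sex"] == "male").to_numpy(dtype=float))
    cols.append(df["transferred"].to_numpy(dtype=float))
    if target != "mechanism":
        for mech in MECHANISMS[1:]:  # reference: fall
            cols.append((df["mechanism"] == mech).to_numpy(dtype=float))
    cols.append(df["died_24h"].to_numpy(dtype=float))
    return np.column_stack(cols)


def _bayes_lm_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Posterior-style draw (beta*, sigma*) and the MLE beta-hat."""
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    s2 = float(resid @ resid) / dof
    s2_star = s2 * dof / max(rng.chisquare(dof), 1e-12)
    cov = s2_star * np.linalg.inv(XtX)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    beta_star = beta_hat + L @ rng.standard_normal(p)
    return beta_hat, beta_star, math.sqrt(s2_star)


def _impute_continuous(df, var, miss_mask, method, rng, donors=5):
    X = _encode_predictors(df, var)
    y_obs = df.loc[~miss_mask, var].to_numpy(dtype=float)
    X_obs, X_mis = X[~miss_mask.to_numpy()], X[miss_mask.to_numpy()]
    beta_hat, beta_star, sigma_star = _bayes_lm_draw(X_obs, y_obs, rng)
    if method == "linear":
        draws = X_mis @ beta_star + sigma_star * rng.standard_normal(len(X_mis))
        if var in RANGES:
            lo, hi = RANGES[var]
            draws = np.clip(np.round(draws), lo, hi)
        return draws
    # type-1 PMM: observed predictions with beta-hat, missing with beta*
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star
    order = np.argsort(pred_obs)
    pred_sorted = pred_obs[order]
    y_sorted = y_obs[order]
    pos = np.searchsorted(pred_sorted, pred_mis)
    out = np.empty(len(pred_mis))
    k = min(donors, len(y_obs))
    for i, (pm, po) in enumerate(zip(pred_mis, pos)):
        lo = max(0, po - k)
        hi = min(len(y_sorted), po + k)
        window = np.arange(lo, hi)
        nearest = window[np.argsort(np.abs(pred_sorted[window] - pm))[:k]]
        out[i] = y_sorted[rng.choice(nearest)]
    return out


def _impute_ordinal(df, var, miss_mask, rng):
    """Ordinal-logistic imputation; falls back to PMM on failure."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    X = _encode_predictors(df, var)[:, 1:]  # OrderedModel forbids a constant
    y_obs = df.loc[~miss_mask, var].to_numpy(dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(y_obs, X[~miss_mask.to_numpy()], distr="logit")
            res = model.fit(method="bfgs", maxiter=200, disp=0)
        probs = np.asarray(res.model.predict(res.params, exog=X[miss_mask.to_numpy()]))
        levels = np.sort(np.unique(y_obs))
        cum = probs.cumsum(axis=1)
        u = rng.random(len(cum))
        idx = (u[:, None] > cum).sum(axis=1)
        return levels[np.clip(idx, 0, len(levels) - 1)]
    except Exception:  # noqa: BLE001 - any fit failure falls back to PMM
        logger.warning("%s: ordinal imputation failed, falling back to PMM", var)
        return _impute_continuous(df, var, miss_mask, "pmm", rng)


def _impute_nominal(df, var, miss_mask, rng):
    from sklearn.linear_model import LogisticRegression

    X = _encode_predictors(df, var)[:, 1:]
    y_obs = df.loc[~miss_mask, var].astype(str).to_numpy()
    classes = np.unique(y_obs)
    if len(classes) == 1:
        return np.repeat(classes[0], int(miss_mask.sum()))
    clf = LogisticRegression(max_iter=500)
    clf.fit(X[~miss_mask.to_numpy()], y_obs)
    probs = clf.predict_proba(X[miss_mask.to_numpy()])
    cum = probs.cumsum(axis=1)
    u = rng.random(len(cum))
    idx = (u[:, None] > cum).sum(axis=1)
    return clf.classes_[np.clip(idx, 0, len(clf.classes_) - 1)]


def _chained_equations(df: pd.DataFrame, fill_rows: pd.Series, methods: dict,
                       iterations: int, rng: np.random.Generator,
                       donors: int = 5) -> pd.DataFrame:
    """One completed copy of ``df``; only rows in ``fill_rows`` keep their
    imputed values (the rest may serve as donors/predictors)."""
    work = df.copy()
    miss = {v: work[v].isna() for v in methods if work[v].isna().any()}
    if not miss:
        return work
    # initial fill: random draws from the observed margin
    for var, mask in miss.items():
        observed = work.loc[~mask, var].to_numpy()
        if len(observed) == 0:
            raise ImputationError(f"{var}: no observed values to impute from")
        work.loc[mask, var] = rng.choice(observed, size=int(mask.sum()))
    order = sorted(miss, key=lambda v: miss[v].sum())
    for _ in range(iterations):
        for var in order:
            mask = miss[var]
            work.loc[mask, var] = np.nan
            method = methods[var]
            if method in ("pmm", "linear"):
                vals = _impute_continuous(work, var, mask, method, rng, donors)
            elif method == "ordinal":
                vals = _impute_ordinal(work, var, mask, rng)
            elif method == "nominal":
                vals = _impute_nominal(work, var, mask, rng)
            else:
                raise ValueError(f"unknown imputation method {method!r} for {var}")
            work.loc[mask, var] = vals
    out = df.copy()
    for var, mask in miss.items():
        keep = mask & fill_rows
        out.loc[keep, var] = work.loc[keep, var]
    return out


def mice_impute(
    cohort: Cohort,
    m: int,
    outcome_in_model: bool = True,
    seed: int = 0,
    methods: dict | None = None,
    iterations: int = 10,
    min_stratum: int = 20,
    donors: int = 5,
) -> ImputedStack:
    """Impute a cohort m times, separately within each hospital stratum.

    Hospitals with fewer than ``min_stratum`` rows (or with a constant
    predictor) are imputed from the pooled all-hospital model instead,
    with a logged warning.  Random-number substreams are derived
    deterministically per hospital and imputation from ``seed``.
    ``outcome_in_model=False`` drops the 24-hour outcome from the
    conditional models (available for sensitivity checks only; the
    default follows standard practice and keeps it).
    """
    methods = {**DEFAULT_METHODS, **(methods or {})}
    df = cohort.df
    missing_outcome = df["died_24h"].isna() if df["died_24h"].dtype != bool else pd.Series(False, index=df.index)
    if missing_outcome.any():
        logger.warning("excluding %d rows with missing outcome", missing_outcome.sum())
        df = df[~missing_outcome]
    df = df.reset_index(drop=True)

    has_missing = df[MODELLED_VARIABLES].isna().any().any()
    if not has_missing:
        return ImputedStack([df.copy() for _ in range(max(m, 1))], {"m": m, "note": "complete"})
    if m < 2:
        raise ImputationError("m must be >= 2 when values are missing")
    if not outcome_in_model:
        methods = dict(methods)

    hospitals = sorted(df["hospital_id"].unique())
    trace = {"m": m, "strata": {}, "fallback": []}
    plans = []  # (stratum_frame, fill_rows_mask, hospital_index)
    pooled_rows = pd.Series(False, index=df.index)
    for h_idx, h in enumerate(hospitals):
        rows = df["hospital_id"] == h
        stratum = df[rows]
        n_missing = int(stratum[MODELLED_VARIABLES].isna().any(axis=1).sum())
        trace["strata"][h] = {"n": int(rows.sum()), "incomplete": n_missing}
        if n_missing == 0:
            continue
        degenerate = rows.sum() < min_stratum or any(
            stratum[v].dropna().nunique() < 2 for v in MODELLED_VARIABLES
        )
        if degenerate:
            warnings.warn(
                f"hospital {h!r}: stratum too small or degenerate; "
                "imputing from the pooled model"
            )
            trace["fallback"].append(h)
            pooled_rows |= rows
        else:
            plans.append((rows, h_idx))

    work = df.copy()
    if not outcome_in_model:
        work = work.assign(died_24h=False)  # constant column: no outcome signal
    datasets = []
    for i in range(m):
        completed = df.copy()
        for rows, h_idx in plans:
            rng = np.random.default_rng([int(seed), 2, h_idx, i])
            sub = _chained_equations(
                work[rows], pd.Series(True, index=work.index[rows]),
                methods, iterations, rng, donors,
            )
            completed.loc[rows, MODELLED_VARIABLES] = sub[MODELLED_VARIABLES]
        if pooled_rows.any():
            rng = np.random.default_rng([int(seed), 2, 999, i])
            sub = _chained_equations(work, pooled_rows, methods, iterations, rng, donors)
            completed.loc[pooled_rows, MODELLED_VARIABLES] = sub.loc[
                pooled_rows, MODELLED_VARIABLES
            ]
        if completed[MODELLED_VARIABLES].isna().any().any():
            raise ImputationError("imputation left missing values behind")
        datasets.append(completed)
    return ImputedStack(datasets, trace)
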