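"""Pooled logistic modelling on multiply imputed data.

Per-dataset maximum-likelihood logistic fits are combined with Rubin's
rules (pooled coefficient = mean across imputations; pooled covariance =
mean within-imputation covariance plus (1 + 1/m) times the
between-imputation covariance).  Predictor significance is assessed with
grouped Wald tests: all spline coefficients belonging to one vital sign
are tested jointly against zero.  Backward selection removes, at each
step, the predictor group with the largest joint p-value at or above the
working level (default 0.2), after first trying to simplify splines
whose nonlinear components are jointly nonsignificant (4 knots -> 3
knots -> linear).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import Cohort, MECHANISMS
from .imputation import ImputedStack
from .splines import KnotSet, place_knots, rcs_basis

#: default flag threshold for the lowess linearity index (fraction of the
#: smoothed log-odds variation left unexplained by a straight line)
LINEARITY_FLAG = 0.20


class FitFailureError(RuntimeError):
    """A per-imputation logistic fit failed (separation / nonconvergence)."""


@dataclass(frozen=True)
class Term:
    variable: str
    form: str  # "linear" or "rcs"
    k: int = 0  # knot count when form == "rcs"

    def label(self) -> str:
        return self.variable if self.form == "linear" else f"{self.variable} rcs({self.k})"


def rcs(variable: str, k: int = 4) -> Term:
    if k not in (3, 4, 5):
        raise ValueError("restricted cubic splines support 3-5 knots")
    return Term(variable, "rcs", k)


def linear(variable: str) -> Term:
    return Term(variable, "linear")


@dataclass(frozen=True)
class ModelSpec:
    """Predictors and their functional forms.

    ``terms`` are subject to selection; ``extra_covariates`` (age, sex,
    transfer status, mechanism of injury) are forced in regardless of
    significance, as in the full-model sensitivity analysis.
    ``fixed_knots`` pins spline knots (e.g. to generator truth or the
    published locations); otherwise knots are placed at equally spaced
    percentiles of each dataset.
    """

    terms: tuple
    extra_covariates: tuple = ()
    fixed_knots: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [t.variable for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("each variable may appear at most once")
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "extra_covariates", tuple(self.extra_covariates))

    def variables(self) -> list:
        return [t.variable for t in self.terms]

    def term_for(self, variable: str) -> Term:
        for t in self.terms:
            if t.variable == variable:
                return t
        raise KeyError(variable)

    def drop(self, variable: str) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t.variable != variable))

    def reduce(self, variable: str) -> "ModelSpec":
        """One hierarchical simplification step: rcs(5)->rcs(4)->rcs(3)->linear."""
        new_terms = []
        for t in self.terms:
            if t.variable == variable:
                if t.form != "rcs":
                    raise ValueError(f"{variable} is already linear")
                t = linear(variable) if t.k <= 3 else rcs(variable, t.k - 1)
            new_terms.append(t)
        return replace(self, terms=tuple(new_terms))

    def to_dict(self) -> dict:
        return {
            "terms": [{"variable": t.variable, "form": t.form, "k": t.k} for t in self.terms],
            "extra_covariates": list(self.extra_covariates),
            "fixed_knots": {v: list(k) for v, k in self.fixed_knots.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            tuple(Term(t["variable"], t["form"], t.get("k", 0)) for t in d["terms"]),
            tuple(d.get("extra_covariates", ())),
            {v: tuple(k) for v, k in d.get("fixed_knots", {}).items()},
        )


def default_full_spec(gcs_as_spline: bool = False, fixed_knots: dict | None = None,
                      extra_covariates: tuple = ()) -> ModelSpec:
    """The a-priori full model: SBP and HR as 4-knot splines, GCS linear.

    The lowess screen supports treating GCS as linear; ``gcs_as_spline``
    offers it to selection as a 4-knot spline instead.
    """
    terms = (rcs("sbp", 4), rcs("hr", 4),
             rcs("gcs", 4) if gcs_as_spline else linear("gcs"))
    return ModelSpec(terms, extra_covariates, fixed_knots or {})


def build_design(df: pd.DataFrame, spec: ModelSpec):
    """Design matrix for one completed dataset.

    Returns ``(X, groups, knots)``: X a DataFrame with a ``const``
    column, ``groups`` mapping each selectable variable to its column
    names, and ``knots`` the per-variable KnotSet used.
    """
    cols = {"const": np.ones(len(df))}
    groups: dict = {}
    knots: dict = {}
    for t in spec.terms:
        x = df[t.variable].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"{t.variable}: design requires complete data")
        if t.form == "linear":
            cols[t.variable] = x
            groups[t.variable] = [t.variable]
        else:
            if t.variable in spec.fixed_knots:
                ks = KnotSet(t.variable, tuple(spec.fixed_knots[t.variable]))
                if ks.n_knots != t.k:
                    raise ValueError(
                        f"{t.variable}: fixed knots have {ks.n_knots} knots, term wants {t.k}"
                    )
            else:
                ks = place_knots(x, t.k, t.variable)
            basis = rcs_basis(x, ks).values
            names = [f"{t.variable}_b{i + 1}" for i in range(basis.shape[1])]
            for name, col in zip(names, basis.T):
                cols[name] = col
            groups[t.variable] = names
            knots[t.variable] = ks
    for cov in spec.extra_covariates:
        if cov == "age":
            cols["age"] = df["age"].to_numpy(dtype=float)
        elif cov == "sex":
            cols["sex_male"] = (df["sex"] == "male").to_numpy(dtype=float)
        elif cov == "transferred":
            cols["transferred"] = df["transferred"].to_numpy(dtype=float)
        elif cov == "mechanism":
            # rare categories (fewer than 10 patients) are merged into
            # "other" to avoid quasi-separation of their dummy columns
            mech_col = df["mechanism"].copy()
            counts = mech_col.value_counts()
            rare = counts[counts < 10].index
            mech_col = mech_col.where(~mech_col.isin(rare), "other")
            for mech in MECHANISMS[1:]:  # reference category: fall
                if (mech_col == mech).any():
                    cols[f"mech_{mech}"] = (mech_col == mech).to_numpy(dtype=float)
        else:
            cols[cov] = df[cov].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    return X, groups, knots


@dataclass
class PooledFit:
    """Rubin-pooled logistic fit across an imputed stack."""

    params: pd.Series
    cov: pd.DataFrame
    within_cov: pd.DataFrame
    m: int
    spec: ModelSpec
    groups: dict
    knots_by_dataset: list
    nobs: int

    @property
    def knots_median(self) -> dict:
        """Per-variable knots: elementwise median across imputed datasets."""
        out = {}
        for var in self.knots_by_dataset[0] if self.knots_by_dataset else {}:
            locs = np.median(
                [ks[var].locations for ks in self.knots_by_dataset], axis=0
            )
            out[var] = KnotSet(var, tuple(locs))
        return out

    def group_p(self, variable: str) -> float:
        return joint_wald(self, variable)

    def group_p_values(self) -> dict:
        return {v: joint_wald(self, v) for v in self.groups}

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def summary_frame(self) -> pd.DataFrame:
        se = self.se()
        z = stats.norm.ppf(0.975)
        return pd.DataFrame({
            "coef": self.params,
            "se": se,
            "ci_low": self.params - z * se,
            "ci_high": self.params + z * se,
        })


def _fit_one(df: pd.DataFrame, spec: ModelSpec, outcome: np.ndarray):
    X, groups, knots = build_design(df, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.simplefilter("ignore", category=FutureWarning)
        try:
            model = sm.Logit(outcome.astype(float), X)
            try:
                res = model.fit(disp=0, maxiter=200, method="newton")
            except Exception:
                res = model.fit(disp=0, maxiter=1000, method="bfgs")
        except Exception as exc:  # separation, singularity, nonconvergence
            raise FitFailureError(str(exc)) from exc
    if not res.mle_retvals.get("converged", True):
        res = model.fit(disp=0, maxiter=1000, method="bfgs",
                        start_params=res.params)
        if not res.mle_retvals.get("converged", True):
            raise FitFailureError("logistic fit did not converge")
    if np.abs(res.params).max() > 50:
        raise FitFailureError("diverging coefficients suggest separation")
    return res, groups, knots


def fit_pooled(stack: ImputedStack, spec: ModelSpec,
               outcome: str | np.ndarray = "died_24h") -> PooledFit:
    """Fit the model in every imputed dataset and pool with Rubin's rules.

    ``outcome`` is a column name or an explicit boolean vector (used by
    the worst-case sensitivity analysis).
    """
    params, covs, knots_list = [], [], []
    groups = None
    for i, df in enumerate(stack):
        y = df[outcome].to_numpy(dtype=bool) if isinstance(outcome, str) else np.asarray(outcome, dtype=bool)
        if y.sum() == 0 or y.sum() == len(y):
            raise FitFailureError(f"imputation {i + 1}: outcome has a single class")
        try:
            res, groups, knots = _fit_one(df, spec, y)
        except FitFailureError as exc:
            raise FitFailureError(f"imputation {i + 1}: {exc}") from exc
        params.append(res.params)
        covs.append(res.cov_params())
        knots_list.append(knots)
    P = pd.concat(params, axis=1)
    pooled = P.mean(axis=1)
    W = sum(covs) / len(covs)
    m = len(covs)
    if m > 1:
        centred = P.sub(pooled, axis=0)
        B = centred @ centred.T / (m - 1)
        T = W + (1.0 + 1.0 / m) * B
    else:
        T = W
    nobs = len(stack.datasets[0])
    return PooledFit(pooled, pd.DataFrame(T, index=pooled.index, columns=pooled.index),
                     pd.DataFrame(W, index=pooled.index, columns=pooled.index),
                     m, spec, groups, knots_list, nobs)


def joint_wald(fit: PooledFit, variable: str, nonlinear_only: bool = False) -> float:
    """Joint Wald test that a variable's coefficient block is zero.

    ``nonlinear_only`` restricts the block to the spline basis columns
    beyond the first (a test of departure from linearity).  The statistic
    c' Sigma_block^{-1} c is referred to a chi-square with df = block
    size; a 1-df block reduces to the square of the coefficient z-test.
    """
    names = fit.groups[variable]
    if nonlinear_only:
        names = names[1:]
        if not names:
            return 1.0
    c = fit.params[names].to_numpy()
    S = fit.cov.loc[names, names].to_numpy()
    try:
        stat = float(c @ np.linalg.solve(S, c))
    except np.linalg.LinAlgError as exc:
        raise FitFailureError(f"{variable}: singular block covariance") from exc
    return float(stats.chi2.sf(stat, df=len(names)))


def lowess_screen(cohort: Cohort, variable: str, outcome: str = "died_24h",
                  frac: float = 2 / 3):
    """Univariate lowess of early mortality on one vital sign.

    Smooths the binary outcome on the observed values, transforms the
    smoothed probability to the log-odds scale (clipped away from 0/1),
    and summarises departure from linearity as sqrt(1 - R^2) of the best
    straight-line fit to the smoothed log-odds.  The index supports, but
    does not automate, the linear-versus-spline choice; values above
    ~0.2 flag visible curvature.

    Returns ``(grid, smoothed_probability, smoothed_log_odds, index)``.
    """
    df = cohort.df
    mask = df[variable].notna()
    x = df.loc[mask, variable].to_numpy(dtype=float)
    y = df.loc[mask, outcome].to_numpy(dtype=float)
    if len(x) < 100:
        raise ValueError(f"{variable}: need >=100 observed pairs, have {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError(f"{variable} is constant")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    # heavy ties (e.g. the mass of Glasgow coma scale scores at 15) make the
    # local linear fit degenerate; spread tied values deterministically over
    # a fraction of the smallest level gap before smoothing
    uniq = np.unique(x)
    if len(uniq) < len(x):
        gap = np.min(np.diff(uniq)) if len(uniq) > 1 else 1.0
        order = np.argsort(x, kind="mergesort")
        xs = x[order]
        jitter = np.zeros_like(xs)
        start = 0
        for end in np.r_[np.nonzero(np.diff(xs))[0] + 1, len(xs)]:
            g = end - start
            if g > 1:
                jitter[start:end] = np.linspace(-0.25, 0.25, g) * gap
            start = end
        x = xs + jitter
        y = y[order]
    sm_xy = lowess(y, x, frac=frac, it=0)
    grid, p_hat = sm_xy[:, 0], np.clip(sm_xy[:, 1], 1e-3, 1 - 1e-3)
    log_odds = np.log(p_hat / (1 - p_hat))
    slope, intercept = np.polyfit(grid, log_odds, 1)
    resid = log_odds - (intercept + slope * grid)
    total = log_odds - log_odds.mean()
    denom = float(total @ total)
    index = float(np.sqrt((resid @ resid) / denom)) if denom > 0 else 0.0
    return grid, p_hat, log_odds, index


def backward_select(stack: ImputedStack, full_spec: ModelSpec, alpha: float = 0.2,
                    outcome: str | np.ndarray = "died_24h"):
    """Grouped backward selection on the Rubin-pooled fit.

    At each round, first simplify the spline term whose nonlinear
    components are least significant (joint p >= alpha), one knot step at
    a time; once no simplification applies, remove the variable with the
    largest grouped joint p >= alpha (ties broken by reverse listing
    order, making the result invariant to how the candidate terms are
    listed); refit and repeat until all remaining groups have p < alpha.

    Returns ``(selected_spec, trace)``.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    spec = full_spec
    trace = []
    while True:
        if not spec.terms:
            warnings.warn("backward selection removed every predictor; "
                          "returning intercept-only model")
            trace.append({"action": "stop", "reason": "empty model"})
            return spec, trace
        fit = fit_pooled(stack, spec, outcome=outcome)
        # (a) hierarchical spline simplification
        candidates = []
        for t in spec.terms:
            if t.form == "rcs":
                p_nl = joint_wald(fit, t.variable, nonlinear_only=True)
                if p_nl >= alpha:
                    candidates.append((p_nl, t.variable))
        if candidates:
            p_nl, var = max(candidates, key=lambda c: (c[0], -spec.variables().index(c[1])))
            spec = spec.reduce(var)
            trace.append({"action": "reduce", "variable": var, "p": p_nl,
                          "to": spec.term_for(var).label()})
            continue
        # (b) group removal
        p_values = fit.group_p_values()
        worst_var, worst_p = None, -1.0
        for var in reversed(spec.variables()):
            p = p_values[var]
            if p >= alpha and p > worst_p:
                worst_var, worst_p = var, p
        if worst_var is None:
            trace.append({"action": "stop", "p_values": p_values})
            return spec, trace
        spec = spec.drop(worst_var)
        trace.append({"action": "remove", "variable": worst_var, "p": worst_p})
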