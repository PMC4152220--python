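"""Bootstrap internal validation: stability, optimism, shrinkage.

The complete modelling procedure (fresh imputation, grouped backward
selection, Rubin pooling) is replicated in bootstrap samples drawn with
replacement from the original, incomplete cohort.  Each replicate model
is evaluated both in its own bootstrap sample and in the original
sample; optimism is the mean difference in AUROCC between the two, and
the linear shrinkage factor is the mean calibration slope of the
replicate model's linear predictor in the original sample (the standard
bootstrap uniform-shrinkage estimator).  The final model keeps only
variables selected in the original sample and in more than half of the
bootstrap samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .imputation import ImputedStack, mice_impute
from .metrics import auroc, calibration_slope
from .modeling import FitFailureError, ModelSpec, PooledFit, backward_select, fit_pooled
from .scoring import FinalModel, RangeWarning

logger = logging.getLogger(__name__)


class BootstrapError(RuntimeError):
    pass


@dataclass
class BootstrapReport:
    """Aggregated record of a bootstrap internal-validation run."""

    B: int
    per_replicate: list
    inclusion_frequency: dict
    optimism: float
    shrinkage: float
    n_failures: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "optimism": self.optimism,
            "shrinkage": self.shrinkage,
            "inclusion_frequency": self.inclusion_frequency,
            "n_failures": self.n_failures,
            "seed": self.seed,
            "per_replicate": self.per_replicate,
        }


def _frozen_scorer(fit: PooledFit) -> FinalModel:
    """Freeze a pooled fit into a deployable scorer (median knots)."""
    knots = fit.knots_median
    coefs = {}
    for var, names in fit.groups.items():
        coefs[var] = tuple(fit.params[n] for n in names)
    return FinalModel(coefficients=coefs, knots=knots,
                      intercept=float(fit.params["const"]), provenance="fitted")


def _median_auc(scorer: FinalModel, stack: ImputedStack, outcome: str) -> float:
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RangeWarning)
        for df in stack:
            lp = scorer.linear_predictor(df[scorer.variables])
            vals.append(auroc(lp, df[outcome].to_numpy(dtype=bool)))
    return float(np.median(vals))


def _median_slope(scorer: FinalModel, stack: ImputedStack, outcome: str) -> float:
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RangeWarning)
        for df in stack:
            lp = scorer.linear_predictor(df[scorer.variables])
            vals.append(calibration_slope(lp, df[outcome].to_numpy(dtype=bool)))
    return float(np.median(vals))


def bootstrap_validate(
    cohort: Cohort,
    full_spec: ModelSpec,
    original_stack: ImputedStack,
    B: int = 300,
    m_boot: int = 5,
    seed: int = 0,
    alpha: float = 0.2,
    outcome: str = "died_24h",
    stratify_by_hospital: bool = False,
    mice_kwargs: dict | None = None,
) -> BootstrapReport:
    """Replicate the modelling procedure in B bootstrap samples.

    Each replicate resamples patients with replacement from the original
    (incomplete) cohort, imputes it afresh with ``m_boot`` imputations,
    runs grouped backward selection and Rubin pooling, then evaluates
    AUROCC in the bootstrap stack and in ``original_stack`` and fits the
    calibration slope of the replicate linear predictor in the original
    stack (all summarised as medians across imputed datasets).
    Replicate-level fit failures are logged and skipped; more than 20%
    failures aborts.  Bitwise deterministic for fixed seed and B.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if cohort.n_events == 0:
        raise ValueError("cohort has no events")
    df = cohort.df.reset_index(drop=True)
    n = len(df)
    candidates = full_spec.variables()
    mice_kwargs = mice_kwargs or {}
    has_missing = df[[t.variable for t in full_spec.terms]].isna().any().any() or \
        df[["sbp", "hr", "gcs", "tti_hours"]].isna().any().any()

    per_replicate = []
    failures = 0
    counts = {v: 0 for v in candidates}
    for b in range(B):
        rng = np.random.default_rng([int(seed), 3, b])
        if stratify_by_hospital:
            idx = np.concatenate([
                rng.choice(grp_idx.to_numpy(), size=len(grp_idx), replace=True)
                for _, grp_idx in df.groupby("hospital_id").groups.items()
            ])
        else:
            idx = rng.integers(0, n, size=n)
        boot = Cohort(df.iloc[idx].reset_index(drop=True), provenance=cohort.provenance)
        try:
            if has_missing:
                boot_stack = mice_impute(boot, m=max(2, m_boot),
                                         seed=int(rng.integers(0, 2**31 - 1)),
                                         **mice_kwargs)
            else:
                boot_stack = ImputedStack.from_complete(boot, m=1)
            sel_spec, _ = backward_select(boot_stack, full_spec, alpha=alpha,
                                          outcome=outcome)
            if not sel_spec.terms:
                raise FitFailureError("bootstrap selection emptied the model")
            fit = fit_pooled(boot_stack, sel_spec, outcome=outcome)
            scorer = _frozen_scorer(fit)
            rec = {
                "replicate": b,
                "selected": sorted(sel_spec.variables()),
                "forms": {t.variable: t.label() for t in sel_spec.terms},
                "auc_boot": _median_auc(scorer, boot_stack, outcome),
                "auc_orig": _median_auc(scorer, original_stack, outcome),
                "slope_orig": _median_slope(scorer, original_stack, outcome),
            }
        except (FitFailureError, ValueError) as exc:
            failures += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            if failures > 0.2 * B:
                raise BootstrapError(
                    f"{failures} of {b + 1} bootstrap replicates failed"
                ) from exc
            continue
        for v in rec["selected"]:
            counts[v] += 1
        per_replicate.append(rec)

    n_ok = len(per_replicate)
    if n_ok == 0:
        raise BootstrapError("no bootstrap replicate succeeded")
    optimism = float(np.mean([r["auc_boot"] - r["auc_orig"] for r in per_replicate]))
    shrinkage = float(np.mean([r["slope_orig"] for r in per_replicate]))
    freq = {v: counts[v] / n_ok for v in candidates}
    return BootstrapReport(B=B, per_replicate=per_replicate,
                           inclusion_frequency=freq, optimism=optimism,
                           shrinkage=shrinkage, n_failures=failures, seed=seed)


def stability_filter(original_spec: ModelSpec, report: BootstrapReport,
                     threshold: float = 0.5) -> ModelSpec:
    """Keep variables selected originally and in >threshold of replicates."""
    missing = [v for v in original_spec.variables()
               if v not in report.inclusion_frequency]
    if missing:
        raise ValueError(f"report does not cover candidates {missing}")
    keep = [v for v in original_spec.variables()
            if report.inclusion_frequency[v] > threshold]
    if not keep:
        import warnings

        warnings.warn("no variable is bootstrap-stable; returning intercept-only")
    return ModelSpec(tuple(t for t in original_spec.terms if t.variable in keep),
                     original_spec.extra_covariates, original_spec.fixed_knots)


def _offset_intercept_mle(y: np.ndarray, offset: np.ndarray) -> float:
    """Intercept-only logistic MLE with a fixed offset.

    The score sum(y - expit(a + offset)) is strictly decreasing in -a,
    so the root is bracketed and found with brentq (robust to the
    extreme offsets bootstrap models can produce).
    """
    from scipy.optimize import brentq
    from scipy.special import expit as _expit

    score = lambda a: float(np.sum(y - _expit(a + offset)))  # noqa: E731
    lo, hi = -60.0, 60.0
    if score(lo) <= 0 or score(hi) >= 0:
        raise ValueError("offset intercept MLE is unbounded (degenerate offsets)")
    return float(brentq(score, lo, hi, xtol=1e-10))


def shrink(fit: PooledFit, report: BootstrapReport, stack: ImputedStack,
           outcome: str = "died_24h") -> FinalModel:
    """Apply the bootstrap linear shrinkage factor and re-estimate the intercept.

    Every non-intercept coefficient is multiplied by the shrinkage
    factor; the intercept is then re-estimated by refitting, in each
    imputed dataset, an intercept-only logistic model with the shrunk
    linear predictor as a fixed offset, pooled across datasets by
    Rubin's rules (simple mean for a scalar), so predicted probabilities
    stay calibrated in the large.
    """
    s = report.shrinkage if isinstance(report, BootstrapReport) else float(report)
    if s <= 0:
        raise ValueError(f"pathological bootstrap: shrinkage factor {s} <= 0")
    knots = fit.knots_median
    coefs = {var: tuple(s * fit.params[n] for n in names)
             for var, names in fit.groups.items()}
    unshrunk = FinalModel(
        coefficients={var: tuple(fit.params[n] for n in names)
                      for var, names in fit.groups.items()},
        knots=dict(knots), intercept=0.0)
    alphas = []
    for df in stack:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RangeWarning)
            lp_terms = unshrunk.linear_predictor(df[unshrunk.variables]) * s
        y = df[outcome].to_numpy(dtype=float)
        alphas.append(_offset_intercept_mle(y, lp_terms))
    intercept = float(np.mean(alphas))
    return FinalModel(coefficients=coefs, knots=dict(knots), intercept=intercept,
                      shrinkage=s, provenance="fitted")
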