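"""Orchestration of the full derivation and the sensitivity analyses.

The primary analysis chain is: impute (per hospital, m from the
worst-hospital incomplete-case rule) -> lowess screening -> grouped
backward selection at the 0.2 level -> bootstrap validation (fresh
imputation per replicate) -> stability filter (>50% inclusion) ->
linear shrinkage with intercept re-estimation -> performance report.

Sensitivity analyses: a reduced model with the two strongest predictors,
a full model forcing in age, sex, transfer status and mechanism of
injury, a worst-case recoding of early live discharges as deaths, and a
complete-case analysis without imputation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, MODELLED_VARIABLES, VITALS, worst_case_outcome
from .imputation import ImputedStack, choose_m, mice_impute
from .metrics import (auroc, calibration_bins, calibration_slope, cutoff_table,
                      delong_test, hosmer_lemeshow, pooled_metric)
from .modeling import (ModelSpec, backward_select, build_design,
                       default_full_spec, fit_pooled, lowess_screen)
from .validation import bootstrap_validate, shrink, stability_filter

logger = logging.getLogger(__name__)

ANALYSES = ("primary", "reduced", "full", "worst_case", "complete_case")


@dataclass
class RunConfig:
    """Knobs of a pipeline run.

    ``m="auto"`` applies the worst-hospital incomplete-case rule;
    desk-scale runs may fix a smaller m.  ``B`` is the number of
    bootstrap replicates (300 in the source procedure) and ``m_boot``
    the per-replicate imputation count.
    """

    seed: int = 0
    m: int | str = "auto"
    B: int = 300
    m_boot: int = 5
    alpha: float = 0.2
    gcs_as_spline: bool = False
    analysis: str = "primary"
    outdir: str | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.B < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if self.analysis not in ANALYSES:
            raise ValueError(f"analysis must be one of {ANALYSES}")


def pooled_predictions(fit, stack: ImputedStack) -> list:
    """Per-dataset linear predictors of a pooled fit (includes any forced
    covariates, unlike the frozen three-variable scorer)."""
    out = []
    for df in stack:
        X, _, _ = build_design(df, fit.spec)
        out.append(X.to_numpy() @ fit.params.reindex(X.columns).to_numpy())
    return out


def performance_summary(lps: list, stack: ImputedStack, outcome="died_24h",
                        hl_groups: int = 10) -> dict:
    """Median/IQR discrimination and calibration across imputed datasets."""
    from scipy.special import expit

    aucs, hls, slopes = [], [], []
    tables = []
    bins = None
    for lp, df in zip(lps, stack):
        y = df[outcome].to_numpy(dtype=bool) if isinstance(outcome, str) else outcome
        p = expit(lp)
        aucs.append(auroc(p, y))
        hls.append(hosmer_lemeshow(p, y, groups=hl_groups)[1])
        slopes.append(calibration_slope(lp, y))
        tables.append(cutoff_table(p, y))
        if bins is None:
            bins = calibration_bins(p, y)
    cut = (
        pd.concat(tables)
        .groupby("target_sensitivity", sort=False)
        .median()
        .reset_index()
    )
    return {
        "auroc": pooled_metric(aucs),
        "hl_p": pooled_metric(hls),
        "calibration_slope": float(np.median(slopes)),
        "calibration_bins": bins,
        "cutoff_table": cut,
        "per_dataset_auroc": aucs,
    }


def run_primary(cohort: Cohort, config: RunConfig) -> dict:
    """Execute the full derivation; returns a dict of artifacts."""
    cohort.validate(for_fitting=True)
    df = cohort.df
    n_events = cohort.n_events
    logger.info("cohort: %d patients, %d events (%.1f%%), %d hospitals",
                len(df), n_events, 100 * n_events / len(df),
                df["hospital_id"].nunique())

    m = choose_m(cohort) if config.m == "auto" else int(config.m)
    has_missing = df[MODELLED_VARIABLES].isna().any().any()
    if has_missing:
        stack = mice_impute(cohort, m=max(m, 2), seed=config.seed)
    else:
        stack = ImputedStack.from_complete(cohort, m=1)
    logger.info("imputation: m=%d", stack.m)

    screening = {}
    for v in VITALS:
        try:
            _, _, _, index = lowess_screen(cohort, v)
            screening[v] = index
        except ValueError as exc:
            logger.warning("lowess screen skipped for %s: %s", v, exc)

    full_spec = default_full_spec(gcs_as_spline=config.gcs_as_spline)
    selected_spec, trace = backward_select(stack, full_spec, alpha=config.alpha)
    fit = fit_pooled(stack, selected_spec)

    report = bootstrap_validate(cohort, full_spec, stack, B=config.B,
                                m_boot=config.m_boot, seed=config.seed,
                                alpha=config.alpha)
    stable_spec = stability_filter(selected_spec, report)
    if stable_spec.terms != selected_spec.terms:
        logger.info("stability filter changed the model; refitting")
        fit = fit_pooled(stack, stable_spec)
    final = shrink(fit, report, stack)

    import warnings

    with warnings.catch_warnings():
        from .scoring import RangeWarning

        warnings.simplefilter("ignore", RangeWarning)
        lps = [final.linear_predictor(d[final.variables]) for d in stack]
    perf = performance_summary(lps, stack)
    perf["optimism"] = report.optimism
    perf["optimism_corrected_auroc"] = perf["auroc"].median - report.optimism

    artifacts = {
        "config": config,
        "m": stack.m,
        "stack": stack,
        "screening": screening,
        "selection_trace": trace,
        "selected_spec": selected_spec,
        "stable_spec": stable_spec,
        "pooled_fit": fit,
        "bootstrap_report": report,
        "final_model": final,
        "performance": perf,
    }
    if config.outdir:
        _write_artifacts(artifacts, cohort, config)
    return artifacts


def _strongest_two(fit) -> list:
    p = fit.group_p_values()
    return sorted(p, key=lambda v: p[v])[:2]


def run_sensitivity(cohort: Cohort, config: RunConfig, primary: dict) -> dict:
    """The four sensitivity analyses, each compared with the final model.

    Comparisons report the analysis model's median AUROCC and a paired
    DeLong test (per imputed dataset, median p) against the final
    model's predictions on the same outcome and rows.
    """
    stack: ImputedStack = primary["stack"]
    final = primary["final_model"]
    fit = primary["pooled_fit"]
    out = {}

    # reduced: the two predictors with smallest grouped p
    strongest = _strongest_two(fit)
    red_terms = tuple(t for t in fit.spec.terms if t.variable in strongest)
    red_spec = ModelSpec(red_terms, fixed_knots=fit.spec.fixed_knots)
    red_fit = fit_pooled(stack, red_spec)
    out["reduced"] = _compare(red_fit, stack, final, "died_24h")
    out["reduced"]["variables"] = strongest

    # full: descriptive covariates forced in
    full_spec = ModelSpec(fit.spec.terms,
                          extra_covariates=("age", "sex", "transferred", "mechanism"),
                          fixed_knots=fit.spec.fixed_knots)
    full_fit = fit_pooled(stack, full_spec)
    out["full"] = _compare(full_fit, stack, final, "died_24h")

    # worst case: early live discharges recoded as deaths
    wc_outcome = worst_case_outcome(cohort.df)
    wc_spec, _ = backward_select(stack, default_full_spec(config.gcs_as_spline),
                                 alpha=config.alpha, outcome=wc_outcome)
    wc_fit = fit_pooled(stack, wc_spec if wc_spec.terms else fit.spec,
                        outcome=wc_outcome)
    out["worst_case"] = _compare(wc_fit, stack, final, wc_outcome)

    # complete case: rows with no missing modelled values, no imputation
    cc_rows = cohort.df[MODELLED_VARIABLES].notna().all(axis=1)
    cc_df = cohort.df[cc_rows].reset_index(drop=True)
    if not cc_df["died_24h"].any():
        raise ValueError("complete-case subset has no events")
    cc_cohort = Cohort(cc_df, provenance=cohort.provenance)
    cc_stack = ImputedStack.from_complete(cc_cohort, m=1)
    cc_spec, _ = backward_select(cc_stack, default_full_spec(config.gcs_as_spline),
                                 alpha=config.alpha)
    cc_fit = fit_pooled(cc_stack, cc_spec if cc_spec.terms else fit.spec)
    out["complete_case"] = _compare(cc_fit, cc_stack, final, "died_24h")
    out["complete_case"]["n"] = len(cc_df)
    return out


def _compare(alt_fit, stack: ImputedStack, final, outcome) -> dict:
    alt_lps = pooled_predictions(alt_fit, stack)
    aucs, ps = [], []
    for lp, df in zip(alt_lps, stack):
        y = df[outcome].to_numpy(dtype=bool) if isinstance(outcome, str) else outcome
        final_lp = final.linear_predictor(df[final.variables])
        a_alt, _, p = delong_test(lp, final_lp, y)
        aucs.append(a_alt)
        ps.append(p)
    return {
        "auroc": pooled_metric(aucs),
        "delong_p_median": float(np.median(ps)),
        "spec": alt_fit.spec.to_dict(),
    }


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def _write_artifacts(artifacts: dict, cohort: Cohort, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts["final_model"].to_json(outdir / "final_model.json")
    with open(outdir / "bootstrap_report.json", "w") as fh:
        json.dump(_jsonable(artifacts["bootstrap_report"].to_dict()), fh, indent=2)
    with open(outdir / "selection_trace.json", "w") as fh:
        json.dump(_jsonable({
            "trace": artifacts["selection_trace"],
            "selected": artifacts["selected_spec"].to_dict(),
            "stable": artifacts["stable_spec"].to_dict(),
        }), fh, indent=2)
    perf = artifacts["performance"]
    with open(outdir / "performance.json", "w") as fh:
        json.dump(_jsonable(perf), fh, indent=2)
    perf["cutoff_table"].to_csv(outdir / "cutoff_table.csv", index=False)
    manifest = {
        "version": __version__,
        "config": _jsonable(dataclasses.asdict(config)),
        "n": len(cohort),
        "n_events": cohort.n_events,
        "provenance": cohort.provenance,
        "m": artifacts["m"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
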