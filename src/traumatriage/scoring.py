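"""The deployable scorer: frozen knots, shrunk coefficients, intercept.

A :class:`FinalModel` holds everything needed to score a new patient
from systolic blood pressure, heart rate and Glasgow coma scale alone:
the spline knot locations, the (shrunk) coefficient of every basis
function and linear term, the re-estimated intercept, and the shrinkage
factor that was applied.

:func:`published_model` returns the model exactly as printed in the
source tables: percentile knots at 80/110/121/147 mmHg for systolic
blood pressure and 70/86/92/118 beats/min for heart rate (median values
across imputed datasets; complete-case values available), with either
the unshrunk coefficients and constant 2.21, or the after-shrinkage
coefficients.  The after-shrinkage constant was not published, so the
shrunk variant carries no intercept and emits linear predictors and
rankings only, unless the user supplies a re-estimated intercept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .splines import KnotSet, rcs_basis

#: published knot locations (median across imputed datasets)
PUBLISHED_KNOTS = {
    "sbp": (80.0, 110.0, 121.0, 147.0),
    "hr": (70.0, 86.0, 92.0, 118.0),
}
#: complete-case alternative knot locations
PUBLISHED_KNOTS_COMPLETE_CASE = {
    "sbp": (80.0, 110.0, 122.0, 149.0),
    "hr": (70.0, 85.0, 92.0, 119.0),
}
#: before-shrinkage coefficients and constant
PUBLISHED_COEFFICIENTS_UNSHRUNK = {
    "sbp": (-0.02, -0.04, 0.38),
    "hr": (-0.00, -0.02, 0.22),
    "gcs": -0.23,
}
PUBLISHED_INTERCEPT_UNSHRUNK = 2.21
#: after-shrinkage coefficients (shrinkage factor 0.90; constant not published)
PUBLISHED_COEFFICIENTS_SHRUNK = {
    "sbp": (-0.02, -0.04, 0.34),
    "hr": (-0.00, -0.02, 0.20),
    "gcs": -0.20,
}
PUBLISHED_SHRINKAGE = 0.90


class MissingInputError(ValueError):
    """The scorer does not impute; every input must be present."""


class RangeWarning(UserWarning):
    """Inputs far outside the knot span: scored by linear extrapolation."""


@dataclass
class FinalModel:
    """Frozen prediction model over vital signs.

    ``coefficients`` maps each variable to a coefficient tuple (length
    n_knots - 1 for spline variables, length 1 for linear terms);
    ``knots`` maps each spline variable to its :class:`KnotSet`.
    ``intercept`` may be ``None`` (rank-only model).
    """

    coefficients: dict
    knots: dict
    intercept: float | None
    shrinkage: float = 1.0
    provenance: str = "fitted"
    gcs_range: tuple = (3, 15)

    def __post_init__(self):
        for var, ks in self.knots.items():
            if not isinstance(ks, KnotSet):
                self.knots[var] = KnotSet(var, tuple(ks))
        self.coefficients = {
            v: tuple(np.atleast_1d(np.asarray(c, dtype=float)).tolist())
            for v, c in self.coefficients.items()
        }
        for var, coefs in self.coefficients.items():
            if var in self.knots and len(coefs) != self.knots[var].n_basis:
                raise ValueError(
                    f"{var}: {len(coefs)} coefficients for "
                    f"{self.knots[var].n_basis} basis functions"
                )

    @property
    def variables(self) -> list:
        return list(self.coefficients)

    # -- scoring ---------------------------------------------------------
    def linear_predictor(self, frame=None, **vitals) -> np.ndarray | float:
        """Intercept plus the sum of coefficient-weighted basis values.

        Accepts either a DataFrame with one column per model variable or
        keyword scalars/vectors (``sbp=..., hr=..., gcs=...``).  Missing
        values raise: the scorer does not impute.  Inputs far outside
        the knot span are scored (splines are linear beyond the boundary
        knots) but trigger a range warning.
        """
        data = frame if frame is not None else pd.DataFrame(
            {k: np.atleast_1d(v) for k, v in vitals.items()}
        )
        scalar = frame is None and all(np.ndim(v) == 0 for v in vitals.values())
        lp = np.zeros(len(data), dtype=float) + (self.intercept or 0.0)
        for var, coefs in self.coefficients.items():
            if var not in data:
                raise MissingInputError(f"input column {var!r} is required")
            x = np.asarray(data[var], dtype=float)
            if np.isnan(x).any():
                raise MissingInputError(f"{var}: missing values; the scorer does not impute")
            if var == "gcs":
                lo, hi = self.gcs_range
                if ((x < lo) | (x > hi)).any():
                    raise ValueError(f"gcs outside [{lo}, {hi}]")
            if var in self.knots:
                ks = self.knots[var]
                lo, hi = ks.locations[0], ks.locations[-1]
                span = hi - lo
                if ((x < lo - span) | (x > hi + span)).any():
                    warnings.warn(
                        f"{var}: values far outside the knot span "
                        f"[{lo}, {hi}]; extrapolating linearly",
                        RangeWarning,
                    )
                basis = rcs_basis(x, ks).values
                lp += basis @ np.asarray(coefs)
            else:
                lp += coefs[0] * x
        return float(lp[0]) if scalar else lp

    def predict_probability(self, frame=None, **vitals):
        """Inverse-logit of the linear predictor; requires an intercept."""
        if self.intercept is None:
            raise ValueError(
                "this model has no published intercept; it provides linear "
                "predictors and rankings only (supply a re-estimated "
                "intercept for absolute probabilities)"
            )
        lp = self.linear_predictor(frame, **vitals)
        return expit(lp)

    def score_frame(self, df: pd.DataFrame) -> pd.DataFrame:
        """Batch scoring: appends ``lp`` and (if possible) ``probability``."""
        absent = [v for v in self.variables if v not in df.columns]
        if absent:
            raise MissingInputError(f"input columns {absent} are required")
        out = df.copy()
        out["lp"] = self.linear_predictor(df[self.variables])
        if self.intercept is not None:
            out["probability"] = expit(out["lp"].to_numpy())
        return out

    def risk_heatmap(self, sbp_grid, gcs_grid, hr_fixed: float | None = None) -> pd.DataFrame:
        """Predicted probability on an SBP x GCS grid.

        ``hr_fixed`` must be given when heart rate is in the model; a
        reduced model (systolic blood pressure and Glasgow coma scale
        only) ignores it.  Rows are indexed by SBP, columns by GCS.
        """
        sbp_grid = np.atleast_1d(np.asarray(sbp_grid, dtype=float))
        gcs_grid = np.atleast_1d(np.asarray(gcs_grid, dtype=float))
        S, G = np.meshgrid(sbp_grid, gcs_grid, indexing="ij")
        cols = {"sbp": S.ravel(), "gcs": G.ravel()}
        if "hr" in self.coefficients:
            if hr_fixed is None:
                raise ValueError("hr_fixed is required: heart rate is in the model")
            cols["hr"] = np.full(S.size, float(hr_fixed))
        grid = pd.DataFrame(cols)
        probs = self.predict_probability(grid[self.variables])
        return pd.DataFrame(np.asarray(probs).reshape(S.shape),
                            index=pd.Index(sbp_grid, name="sbp"),
                            columns=pd.Index(gcs_grid, name="gcs"))

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coefficients": {v: list(c) for v, c in self.coefficients.items()},
            "knots": {v: ks.to_dict() for v, ks in self.knots.items()},
            "intercept": self.intercept,
            "shrinkage": self.shrinkage,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FinalModel":
        return cls(
            coefficients={v: tuple(c) for v, c in d["coefficients"].items()},
            knots={v: KnotSet.from_dict(k) for v, k in d["knots"].items()},
            intercept=d["intercept"],
            shrinkage=d.get("shrinkage", 1.0),
            provenance=d.get("provenance", "fitted"),
        )

    @classmethod
    def from_json(cls, path) -> "FinalModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def published_model(shrunk: bool = True, complete_case_knots: bool = False,
                    intercept: float | None = None) -> FinalModel:
    """The model exactly as printed in the source tables.

    ``shrunk=True`` uses the after-shrinkage coefficients; their
    constant was published as not applicable, so the returned model has
    no intercept (pass ``intercept=`` to enable absolute probabilities).
    ``shrunk=False`` uses the before-shrinkage coefficients with the
    published constant 2.21.
    """
    knots = PUBLISHED_KNOTS_COMPLETE_CASE if complete_case_knots else PUBLISHED_KNOTS
    if shrunk:
        coefs = PUBLISHED_COEFFICIENTS_SHRUNK
        const = intercept
        shrinkage = PUBLISHED_SHRINKAGE
    else:
        coefs = PUBLISHED_COEFFICIENTS_UNSHRUNK
        const = PUBLISHED_INTERCEPT_UNSHRUNK if intercept is None else intercept
        shrinkage = 1.0
    return FinalModel(
        coefficients={v: c for v, c in coefs.items()},
        knots={v: KnotSet(v, k) for v, k in knots.items()},
        intercept=const,
        shrinkage=shrinkage,
        provenance="published",
    )


def shrink_published_coefficients(factor: float = PUBLISHED_SHRINKAGE,
                                  decimals: int = 2) -> dict:
    """Apply a uniform shrinkage factor to the published unshrunk
    coefficients and round to the table's printed precision."""
    out = {}
    for var, coefs in PUBLISHED_COEFFICIENTS_UNSHRUNK.items():
        arr = np.round(np.atleast_1d(np.asarray(coefs)) * factor, decimals)
        out[var] = float(arr[0]) if np.ndim(coefs) == 0 else tuple(arr.tolist())
    return out
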