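"""Restricted cubic spline basis construction with percentile knot placement.

A restricted cubic spline with ``n`` knots is a piecewise cubic that is
constrained to be linear before the first and after the last knot; it
contributes ``n - 1`` basis functions.  The first basis function is the
variable itself.  Subsequent basis functions use the truncated-power
parameterisation with boundary-knot corrections (the form produced by
Stata's ``mkspline, cubic``), in which, for knots ``k_1 < ... < k_n`` and
``j = 1 .. n-2``::

    B_{j+1}(x) = [ (x - k_j)_+^3
                   - ((x - k_{n-1})_+^3 (k_n - k_j)
                      - (x - k_n)_+^3 (k_{n-1} - k_j)) / (k_n - k_{n-1})
                 ] / (k_n - k_1)^2

The division by ``(k_n - k_1)^2`` keeps every basis function on roughly
the scale of the raw variable, which is the scale of the published
coefficient table this package reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: equally spaced percentile schedules, indexed by knot count
PERCENTILE_SCHEDULES = {
    3: (5.0, 50.0, 95.0),
    4: (5.0, 35.0, 65.0, 95.0),
    5: (5.0, 27.5, 50.0, 72.5, 95.0),
}


class DegenerateKnotsError(ValueError):
    """Ties in the data collapsed two knots onto the same location."""


@dataclass(frozen=True)
class KnotSet:
    """Knot locations for one spline-transformed variable."""

    variable: str
    locations: tuple
    percentiles: tuple = ()

    def __post_init__(self):
        locs = tuple(float(v) for v in self.locations)
        object.__setattr__(self, "locations", locs)
        if len(locs) < 3:
            raise ValueError(f"{self.variable}: need at least 3 knots, got {len(locs)}")
        if any(b <= a for a, b in zip(locs, locs[1:])):
            raise DegenerateKnotsError(
                f"{self.variable}: knot locations {locs} are not strictly increasing"
            )

    @property
    def n_knots(self) -> int:
        return len(self.locations)

    @property
    def n_basis(self) -> int:
        return len(self.locations) - 1

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "locations": list(self.locations),
            "percentiles": list(self.percentiles),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnotSet":
        return cls(d["variable"], tuple(d["locations"]), tuple(d.get("percentiles", ())))


@dataclass
class BasisMatrix:
    """Evaluated spline basis: ``n_obs x (n_knots - 1)``, first column = x."""

    values: np.ndarray
    knots: KnotSet


def knot_percentiles(n_knots: int):
    """Equally spaced percentile schedule for a given knot count.

    Supports 3, 4 and 5 knots; the 4-knot schedule is (5, 35, 65, 95).
    """
    try:
        return PERCENTILE_SCHEDULES[int(n_knots)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(
            f"unsupported knot count {n_knots!r}; choose one of {sorted(PERCENTILE_SCHEDULES)}"
        ) from None


def place_knots(values, n_knots: int, variable: str = "x") -> KnotSet:
    """Place knots at the empirical percentiles of ``values``.

    Uses the linear-interpolation empirical percentile (numpy's default);
    percentile dialects differ between packages, so published knot
    locations from other software may differ by a unit in sparse tails.
    Missing values are ignored.
    """
    pct = knot_percentiles(n_knots)
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(np.unique(arr)) < n_knots:
        raise DegenerateKnotsError(
            f"{variable}: fewer than {n_knots} distinct values"
        )
    locs = np.percentile(arr, pct)
    if np.any(np.diff(locs) <= 0):
        raise DegenerateKnotsError(
            f"{variable}: ties collapse knots at percentiles {pct} -> {locs.tolist()}"
        )
    return KnotSet(variable, tuple(locs), tuple(pct))


def rcs_basis(values, knots: KnotSet) -> BasisMatrix:
    """Evaluate the restricted cubic spline basis at ``values``.

    Returns an ``n_obs x (n_knots - 1)`` matrix whose first column equals
    the raw variable.  NaN inputs propagate to NaN rows.
    """
    x = np.asarray(values, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    k = np.asarray(knots.locations, dtype=float)
    n = len(k)
    out = np.empty((len(x), n - 1))
    out[:, 0] = x
    denom = (k[-1] - k[0]) ** 2
    last_gap = k[-1] - k[-2]
    p3 = lambda t: np.clip(t, 0.0, None) ** 3  # noqa: E731 - truncated cube
    for j in range(n - 2):
        term = (
            p3(x - k[j])
            - (p3(x - k[-2]) * (k[-1] - k[j]) - p3(x - k[-1]) * (k[-2] - k[j]))
            / last_gap
        )
        out[:, j + 1] = term / denom
    values_out = out[0] if scalar else out
    return BasisMatrix(values_out, knots)


def spline_curve(x, knots: KnotSet, coefficients) -> np.ndarray:
    """Evaluate ``sum_j beta_j B_j(x)`` for a coefficient vector."""
    basis = rcs_basis(np.atleast_1d(np.asarray(x, dtype=float)), knots).values
    return basis @ np.asarray(coefficients, dtype=float)
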