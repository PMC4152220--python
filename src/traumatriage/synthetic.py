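"""Synthetic trauma cohorts with the statistical structure of the study data.

The generator emulates a multicentre admission cohort of adult trauma
patients: three hospitals of unequal size, ~6% 24-hour mortality, ~2%
early live discharges, skewed arrival-time and age distributions, vital
signs whose marginals match the published sample-characteristics table
(systolic blood pressure median 118, IQR 110-125 in survivors; heart
rate median 88; Glasgow coma scale with a heavy ceiling at 15), and
hospital-stratified missing-at-random missingness whose per-hospital
incomplete-case proportions span roughly 1% to 51%.

The true log-odds of death are parameterised directly on the restricted
cubic spline basis used by the fitting modules (fixed, spec-given knots),
nonlinear in systolic blood pressure and heart rate and linear in Glasgow
coma scale, so generator truth and fitted coefficients share a basis and
parameter recovery is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort, MECHANISMS, MODELLED_VARIABLES
from .splines import KnotSet, rcs_basis

#: generator-side knots: the published percentile-knot locations
DEFAULT_KNOTS = {
    "sbp": (80.0, 110.0, 121.0, 147.0),
    "hr": (70.0, 86.0, 92.0, 118.0),
}

#: published-table-like truth: nonlinear SBP and HR, linear GCS
DEFAULT_COEFFICIENTS = {
    "sbp": (-0.02, -0.04, 0.38),
    "hr": (-0.005, -0.02, 0.22),
    "gcs": -0.23,
}

#: per-hospital, per-variable missingness rates. Together with the shared
#: patient-level uniform draw these give overall missing fractions of
#: ~20% (sbp), ~17% (hr), ~20% (gcs) and ~6% (time to arrival), and
#: per-hospital incomplete-case proportions of ~1%, ~18% and ~50%.
DEFAULT_MISSINGNESS = {
    "sbp": {"a": 0.010, "b": 0.18, "c": 0.50},
    "hr": {"a": 0.008, "b": 0.16, "c": 0.45},
    "gcs": {"a": 0.010, "b": 0.18, "c": 0.50},
    "tti_hours": {"a": 0.005, "b": 0.05, "c": 0.14},
}

MECHANISM_PROBS = {
    "fall": 0.27, "railway": 0.07, "road_traffic": 0.46, "assault": 0.09,
    "burn": 0.06, "other": 0.045, "unknown": 0.005,
}


class CalibrationError(RuntimeError):
    """Intercept search could not reach the target mortality."""


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions: n = 1629 admissions across
    three hospitals, 6% early mortality, 2% early live discharges, and
    the hospital-stratified missingness profile described above.
    """

    n: int = 1629
    seed: int = 0
    hospital_weights: dict = field(
        default_factory=lambda: {"a": 0.40, "b": 0.35, "c": 0.25}
    )
    target_mortality: float = 0.06
    early_discharge_rate: float = 0.02
    true_coefficients: dict = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_COEFFICIENTS.items()}
    )
    knots: dict = field(default_factory=lambda: dict(DEFAULT_KNOTS))
    #: fraction of patients in the physiologically deranged mixture
    #: component (low SBP, high HR, low GCS; SBP and HR negatively
    #: coupled there)
    shock_fraction: float = 0.10
    vital_distributions: dict = field(
        default_factory=lambda: {
            "sbp": {"normal": (118.0, 12.0), "shock": (95.0, 22.0), "bounds": (40.0, 220.0)},
            "hr": {"normal": (89.0, 13.0), "shock": (102.0, 26.0), "bounds": (30.0, 220.0)},
            "gcs_mass_at_15": 0.70,
        }
    )
    missingness: dict = field(default_factory=lambda: {
        "rates": {v: dict(r) for v, r in DEFAULT_MISSINGNESS.items()},
        # multiplicative MAR effects on the missingness rate; depend only
        # on always-observed fields (outcome, age) so MAR holds
        "died_multiplier": 1.3,
        "age_log_slope_per_decade": 0.0,
    })

    def __post_init__(self):
        w = sum(self.hospital_weights.values())
        if not np.isclose(w, 1.0):
            raise ValueError(f"hospital_weights sum to {w}, expected 1")
        for p in (self.target_mortality, self.early_discharge_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")

    def knot_sets(self) -> dict:
        return {v: KnotSet(v, tuple(k)) for v, k in self.knots.items()}

    def to_dict(self) -> dict:
        import dataclasses

        d = dataclasses.asdict(self)
        d["true_coefficients"] = {
            v: (list(c) if np.ndim(c) else float(c))
            for v, c in d["true_coefficients"].items()
        }
        d["knots"] = {v: list(k) for v, k in d["knots"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "true_coefficients" in d:
            d["true_coefficients"] = {
                v: (tuple(c) if isinstance(c, (list, tuple)) else float(c))
                for v, c in d["true_coefficients"].items()
            }
        if "knots" in d:
            d["knots"] = {v: tuple(k) for v, k in d["knots"].items()}
        return cls(**d)

    def save(self, path) -> None:
        """Write the spec as YAML (.yml/.yaml) or JSON (anything else)."""
        import json as _json
        from pathlib import Path as _Path

        path = _Path(path)
        if path.suffix in (".yml", ".yaml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(_json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "CohortSpec":
        import json as _json
        from pathlib import Path as _Path

        path = _Path(path)
        if path.suffix in (".yml", ".yaml"):
            import yaml

            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(_json.loads(path.read_text()))


def truth_of(spec: CohortSpec) -> dict:
    """The generator-side coefficient vector, keyed per basis column.

    Returned on the same parameterisation the fitting module uses:
    ``{"sbp_b1": ..., "sbp_b2": ..., "sbp_b3": ..., "hr_b1": ..., ...,
    "gcs": ...}``.  The intercept is cohort-specific (calibrated against
    the realised covariates) and reported by :func:`generate_cohort` in
    ``cohort.truth["intercept"]``.
    """
    out = {}
    for var, coefs in spec.true_coefficients.items():
        if np.ndim(coefs) == 0:
            out[var] = float(coefs)
        else:
            for i, c in enumerate(coefs, start=1):
                out[f"{var}_b{i}"] = float(c)
    return out


def _draw_vitals(spec: CohortSpec, n: int, rng: np.random.Generator):
    vd = spec.vital_distributions
    shock = rng.random(n) < spec.shock_fraction
    # shared latent severity couples SBP (down) and HR (up) in shock
    sev = np.abs(rng.normal(size=n))

    def trunc(x, lo, hi):
        return np.clip(x, lo, hi)

    mu_n, sd_n = vd["sbp"]["normal"]
    mu_s, sd_s = vd["sbp"]["shock"]
    sbp = np.where(
        shock,
        mu_s - 10.0 * sev + sd_s * rng.normal(size=n) * 0.7,
        mu_n + sd_n * rng.normal(size=n),
    )
    sbp = trunc(sbp, *vd["sbp"]["bounds"])

    mu_n, sd_n = vd["hr"]["normal"]
    mu_s, sd_s = vd["hr"]["shock"]
    hr = np.where(
        shock,
        mu_s + 12.0 * sev + sd_s * rng.normal(size=n) * 0.7,
        mu_n + sd_n * rng.normal(size=n),
    )
    hr = trunc(hr, *vd["hr"]["bounds"])

    # GCS: point mass at 15 plus a spread over 3-14; shock patients draw
    # from a low-weighted spread over 3-15
    gcs = np.empty(n)
    mass15 = vd["gcs_mass_at_15"]
    levels = np.arange(3, 15)  # 3..14
    w_rising = (levels - 2).astype(float)
    w_rising /= w_rising.sum()
    w_falling = (16.0 - levels)
    w_falling /= w_falling.sum()
    nrm = ~shock
    at15 = rng.random(n) < mass15
    gcs[nrm & at15] = 15
    idx = nrm & ~at15
    gcs[idx] = rng.choice(levels, size=int(idx.sum()), p=w_rising)
    low15 = rng.random(n) < 0.15
    gcs[shock & low15] = 15
    idx = shock & ~low15
    gcs[idx] = rng.choice(levels, size=int(idx.sum()), p=w_falling)
    return sbp.round(0), hr.round(0), gcs.astype(int)


def _linear_predictor_terms(spec: CohortSpec, df: pd.DataFrame) -> np.ndarray:
    """Non-intercept part of the true log-odds."""
    lp = np.zeros(len(df))
    ksets = spec.knot_sets()
    for var, coefs in spec.true_coefficients.items():
        if np.ndim(coefs) == 0:
            lp += float(coefs) * df[var].to_numpy(dtype=float)
        else:
            basis = rcs_basis(df[var].to_numpy(dtype=float), ksets[var]).values
            if basis.shape[1] != len(coefs):
                raise ValueError(
                    f"{var}: {len(coefs)} coefficients for {basis.shape[1]} basis columns"
                )
            lp += basis @ np.asarray(coefs, dtype=float)
    return lp


def calibrate_intercept(lp_terms: np.ndarray, target: float, tol: float = 1e-3) -> float:
    """Bisection for the intercept giving mean predicted risk = target.

    ``tol`` is on the probability scale (0.1 percentage points).
    """
    lo, hi = -40.0, 40.0
    f = lambda a: float(np.mean(expit(a + lp_terms))) - target  # noqa: E731
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"target mortality {target} unreachable for the given coefficients"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < tol * 0.1:
            return mid
        if fm < 0:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    if abs(f(alpha)) > tol:
        raise CalibrationError("intercept bisection did not converge")
    return alpha


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a complete (no-missingness) synthetic cohort.

    Outcomes are Bernoulli draws from the true logistic model; the
    intercept is found by bisection so that the expected mortality over
    the realised covariates equals ``spec.target_mortality`` to within
    0.1 percentage points.  Deterministic for fixed ``spec.seed``.
    """
    rng = np.random.default_rng([int(spec.seed), 0])
    n = int(spec.n)
    hospitals = list(spec.hospital_weights)
    weights = np.array([spec.hospital_weights[h] for h in hospitals])
    hosp = rng.choice(hospitals, size=n, p=weights / weights.sum())

    age = np.floor(15 + rng.gamma(2.0, 12.0, size=n)).astype(int)
    age = np.clip(age, 15, 100)
    sex = np.where(rng.random(n) < 0.80, "male", "female")
    mech = rng.choice(
        list(MECHANISM_PROBS),
        size=n,
        p=np.array(list(MECHANISM_PROBS.values())) / sum(MECHANISM_PROBS.values()),
    )
    transferred = rng.random(n) < 0.68
    sbp, hr, gcs = _draw_vitals(spec, n, rng)

    df = pd.DataFrame({
        "hospital_id": hosp,
        "age": age,
        "sex": sex,
        "transferred": transferred,
        "mechanism": mech,
        "sbp": sbp,
        "hr": hr,
        "gcs": gcs,
    })
    lp_terms = _linear_predictor_terms(spec, df)
    alpha = calibrate_intercept(lp_terms, spec.target_mortality)
    p = expit(alpha + lp_terms)
    died = rng.random(n) < p

    # arrival time: lognormal, sicker patients arrive sooner
    z = (lp_terms - lp_terms.mean()) / max(lp_terms.std(), 1e-9)
    tti = np.exp(np.log(7.0) - 0.35 * z + 1.05 * rng.normal(size=n))
    df["tti_hours"] = np.clip(tti, 0.25, 240.0).round(1)

    df["died_24h"] = died
    surv_rate = spec.early_discharge_rate / max(1.0 - spec.target_mortality, 1e-9)
    df["discharged_early"] = (~died) & (rng.random(n) < surv_rate)

    df = df[[
        "hospital_id", "age", "sex", "tti_hours", "transferred", "mechanism",
        "sbp", "hr", "gcs", "died_24h", "discharged_early",
    ]]
    truth = {
        "coefficients": truth_of(spec),
        "intercept": alpha,
        "knots": {v: tuple(k) for v, k in spec.knots.items()},
        "linear_predictor": alpha + lp_terms,
    }
    return Cohort(df, provenance="synthetic", truth=truth)


def impose_missingness(cohort: Cohort, spec: CohortSpec) -> Cohort:
    """Mask vital signs and arrival time missing-at-random, by hospital.

    A single uniform draw per patient is shared across the four maskable
    variables (missingness is strongly correlated within a patient, as
    when an unstable patient goes undocumented), so each hospital's
    incomplete-case proportion equals its largest per-variable rate.
    Rates may be multiplied up for non-survivors and by age; both are
    always observed, so the mechanism is MAR by construction.
    """
    rates = spec.missingness["rates"]
    for var, per_hosp in rates.items():
        for r in per_hosp.values():
            if r > 1.0 or r < 0.0:
                raise ValueError(f"{var}: missingness fraction {r} outside [0, 1]")
    rng = np.random.default_rng([int(spec.seed), 1])
    df = cohort.df.copy()
    n = len(df)
    u = rng.random(n)
    died = df["died_24h"].to_numpy(dtype=bool)
    age = df["age"].to_numpy(dtype=float)
    mult = np.where(died, float(spec.missingness.get("died_multiplier", 1.0)), 1.0)
    slope = float(spec.missingness.get("age_log_slope_per_decade", 0.0))
    if slope:
        mult = mult * np.exp(slope * (age - 35.0) / 10.0)
    for var, per_hosp in rates.items():
        base = df["hospital_id"].map(per_hosp).to_numpy(dtype=float)
        p_miss = np.clip(base * mult, 0.0, 1.0)
        mask = u < p_miss
        if mask.any():  # avoid dtype upcast when nothing is masked
            df[var] = df[var].astype(float)
            df.loc[mask, var] = np.nan
    return Cohort(df, provenance="synthetic", truth=cohort.truth)


def incomplete_case_proportions(cohort: Cohort, variables=None) -> pd.Series:
    """Per-hospital fraction of patients with >=1 missing modelled value."""
    variables = MODELLED_VARIABLES if variables is None else variables
    incomplete = cohort.df[variables].isna().any(axis=1)
    return incomplete.groupby(cohort.df["hospital_id"]).mean()
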