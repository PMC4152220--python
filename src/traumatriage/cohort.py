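"""Canonical cohort schema, CSV I/O, and outcome recoding rules.

One row per admitted trauma patient. The analysis variables are the three
vital signs recorded on arrival (systolic blood pressure, heart rate,
Glasgow coma scale), the descriptive variables (age, sex, time from injury
to arrival, transfer status, mechanism of injury), the hospital stratum,
and the 24-hour vital status with an early-live-discharge flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order
COLUMNS = [
    "hospital_id",
    "age",
    "sex",
    "tti_hours",
    "transferred",
    "mechanism",
    "sbp",
    "hr",
    "gcs",
    "died_24h",
    "discharged_early",
]

SEXES = ("male", "female")
MECHANISMS = ("fall", "railway", "road_traffic", "assault", "burn", "other", "unknown")

#: vital signs considered for the prediction model
VITALS = ["sbp", "hr", "gcs"]
#: variables that may be missing and enter the imputation model
MODELLED_VARIABLES = ["sbp", "hr", "gcs", "tti_hours"]
#: numeric columns (parse failures become missing)
NUMERIC_COLUMNS = ["age", "tti_hours", "sbp", "hr", "gcs"]
BOOLEAN_COLUMNS = ["transferred", "died_24h", "discharged_early"]

DEFAULT_NA_TOKENS = ["", "NA", "NaN", "nan", ".", "na"]


class SchemaError(ValueError):
    """A mandatory column is absent from the input file."""


class EmptyInputError(ValueError):
    """The input file parsed to zero patient rows."""


class CohortValidationError(ValueError):
    """A record violates a schema invariant; names the row and field."""


@dataclass
class Cohort:
    """An analysis dataset: patient records plus a provenance tag.

    ``df`` holds one row per patient in canonical columns; vital signs and
    time-to-arrival may be missing (NaN).  ``truth`` is populated only for
    synthetic cohorts and carries the generator-side coefficients.
    """

    df: pd.DataFrame
    provenance: str = "file"
    truth: dict | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_events(self) -> int:
        return int(self.df["died_24h"].sum())

    def hospitals(self) -> list:
        return sorted(self.df["hospital_id"].unique().tolist())

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), self.provenance, self.truth)

    def validate(self, for_fitting: bool = False) -> "Cohort":
        validate_frame(self.df)
        if for_fitting:
            n_ev = self.n_events
            if n_ev == 0 or n_ev == len(self.df):
                raise CohortValidationError(
                    "model fitting requires at least one event and one non-event"
                )
        return self


def validate_frame(df: pd.DataFrame) -> None:
    """Raise :class:`CohortValidationError` naming row and field on violation."""
    if len(df) == 0:
        raise EmptyInputError("cohort has zero rows")
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")

    gcs = df["gcs"].dropna()
    bad = gcs[(gcs < 3) | (gcs > 15) | (gcs != gcs.round())]
    if len(bad):
        row = bad.index[0]
        raise CohortValidationError(
            f"row {row}: field 'gcs' value {bad.iloc[0]} outside integer range [3, 15]"
        )
    age_bad = df["age"].dropna()
    age_bad = age_bad[age_bad < 15]
    if len(age_bad):
        raise CohortValidationError(
            f"row {age_bad.index[0]}: field 'age' value {age_bad.iloc[0]} below "
            "eligibility threshold of 15 years"
        )
    both = df["died_24h"].astype(bool) & df["discharged_early"].astype(bool)
    if both.any():
        raise CohortValidationError(
            f"row {both.idxmax()}: died_24h and discharged_early are both true"
        )
    bad_sex = set(df["sex"].dropna().unique()) - set(SEXES)
    if bad_sex:
        raise CohortValidationError(f"field 'sex' has unknown labels {sorted(bad_sex)}")
    bad_mech = set(df["mechanism"].dropna().unique()) - set(MECHANISMS)
    if bad_mech:
        raise CohortValidationError(
            f"field 'mechanism' has unknown labels {sorted(bad_mech)}"
        )


def read_cohort(
    path,
    schema_map: dict | None = None,
    na_tokens: list | None = None,
    provenance: str = "file",
) -> Cohort:
    """Read a patient-level CSV into a validated :class:`Cohort`.

    Parameters
    ----------
    path : str or file-like
        CSV file (RFC 4180, UTF-8, header row, one row per patient).
    schema_map : dict, optional
        Mapping from the file's column names to canonical names, for
        foreign dialects whose headers differ from :data:`COLUMNS`.
    na_tokens : list of str, optional
        Strings treated as missing (default empty cell, NA, NaN, ".").
    """
    na = DEFAULT_NA_TOKENS if na_tokens is None else na_tokens
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=na,
                     skipinitialspace=True)
    if schema_map:
        df = df.rename(columns=schema_map)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {missing_cols}")
    df = df[COLUMNS]
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no patient rows")

    n_warn = 0
    for col in NUMERIC_COLUMNS:
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna()
        n_warn += int(bad.sum())
        df[col] = parsed
    if n_warn:
        warnings.warn(f"{n_warn} unparseable numeric cells set to missing")
        logger.warning("%d unparseable numeric cells set to missing", n_warn)
    for col in BOOLEAN_COLUMNS:
        df[col] = _parse_bool(df[col], col)
    for col in ("sex", "mechanism", "hospital_id"):
        df[col] = df[col].astype(str).str.strip().str.lower()

    validate_frame(df)
    return Cohort(df.reset_index(drop=True), provenance=provenance)


def _parse_bool(series: pd.Series, name: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        row = out.index[out.isna()][0]
        raise CohortValidationError(
            f"row {row}: field '{name}' value {series.loc[row]!r} is not boolean"
        )
    return out.astype(bool)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the canonical CSV (empty cells for missing values)."""
    cohort.df.to_csv(path, index=False)


def primary_outcome(records) -> np.ndarray | bool:
    """24-hour mortality under the primary rule.

    A patient discharged alive before 24 hours is considered alive at
    24 hours, so the outcome is simply ``died_24h``.
    """
    if isinstance(records, (pd.DataFrame, dict)):
        died = records["died_24h"]
    else:
        died = records  # a bare outcome Series/scalar
    if isinstance(died, pd.Series):
        return died.astype(bool).to_numpy()
    return bool(died)


def worst_case_outcome(records) -> np.ndarray | bool:
    """24-hour mortality under the worst-case recoding.

    Patients discharged alive before 24 hours are recoded as dead at
    24 hours: returns ``died_24h OR discharged_early``.
    """
    died = records["died_24h"]
    disch = records["discharged_early"]
    if isinstance(died, pd.Series):
        return (died.astype(bool) | disch.astype(bool)).to_numpy()
    return bool(died) or bool(disch)


def required_events(n_free_parameters: int) -> int:
    """Minimum number of events under the ten-events-per-free-parameter rule."""
    if n_free_parameters < 1 or int(n_free_parameters) != n_free_parameters:
        raise ValueError("n_free_parameters must be a positive integer")
    return 10 * int(n_free_parameters)
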