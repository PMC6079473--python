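"""Cohort CSV schema, validated reading with exclusion accounting, and a
column-mapping adapter for externally extracted survey files.

The canonical cohort schema is one row per subject with the columns in
:data:`SCHEMA_COLUMNS` (units in the names where they matter).  Reading
applies the cohort inclusion rules in a fixed, documented order — adults
only, nonpregnant, complete anthropometrics, complete MS inputs,
mortality linkage present — and reports per-rule exclusion counts
rather than dropping rows silently.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

#: canonical column -> (dtype kind, required)
SCHEMA_COLUMNS: dict[str, tuple[str, bool]] = {
    "id": ("int", False),
    "age": ("float", True),
    "sex": ("str", True),
    "race_black": ("int", True),
    "height_cm": ("float", True),
    "weight_kg": ("float", True),
    "waist_cm": ("float", True),
    "hip_cm": ("float", True),
    "sbp_mmhg": ("float", True),
    "dbp_mmhg": ("float", True),
    "bp_meds": ("int", True),
    "tg_mg_dl": ("float", True),
    "hdl_mg_dl": ("float", True),
    "glu_mg_dl": ("float", True),
    "diabetes_pills": ("int", True),
    "followup_years": ("float", True),
    "died": ("int", True),
    "sample_weight": ("float", True),
    "training": ("int", False),
    "pregnant": ("int", False),
}

ANTHRO_COLUMNS = ["height_cm", "weight_kg", "waist_cm", "hip_cm"]
MS_INPUT_COLUMNS = [
    "sbp_mmhg", "dbp_mmhg", "bp_meds", "tg_mg_dl", "hdl_mg_dl",
    "glu_mg_dl", "diabetes_pills",
]


class CohortReadError(ValueError):
    """Raised for unreadable, empty or malformed cohort files."""


@dataclass
class FilterReport:
    """Per-rule exclusion counts, in application order."""

    n_input: int = 0
    under_18: int = 0
    pregnant: int = 0
    missing_anthro: int = 0
    missing_ms_inputs: int = 0
    missing_mortality: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "under_18": self.under_18,
            "pregnant": self.pregnant,
            "missing_anthro": self.missing_anthro,
            "missing_ms_inputs": self.missing_ms_inputs,
            "missing_mortality": self.missing_mortality,
            "retained": self.retained,
        }

    def check(self) -> None:
        excluded = (self.under_18 + self.pregnant + self.missing_anthro
                    + self.missing_ms_inputs + self.missing_mortality)
        assert excluded + self.retained == self.n_input


def apply_filters(df: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the cohort inclusion rules in fixed order; never mutates
    ``df``.  Rules: age >= 18; not pregnant; complete anthropometrics;
    complete MS inputs; mortality follow-up present."""
    report = FilterReport(n_input=len(df))
    keep = pd.Series(True, index=df.index)

    rule = df["age"].isna() | (df["age"] < 18)
    report.under_18 = int((rule & keep).sum())
    keep &= ~rule

    if "pregnant" in df.columns:
        rule = df["pregnant"].fillna(0).astype(float) > 0
        report.pregnant = int((rule & keep).sum())
        keep &= ~rule

    rule = df[ANTHRO_COLUMNS].isna().any(axis=1)
    report.missing_anthro = int((rule & keep).sum())
    keep &= ~rule

    bp_missing = (df["sbp_mmhg"].isna() & df["dbp_mmhg"].isna()
                  & df["bp_meds"].isna())
    glu_missing = df["glu_mg_dl"].isna() & (df["diabetes_pills"].fillna(0) == 0)
    rule = (bp_missing | df["tg_mg_dl"].isna() | df["hdl_mg_dl"].isna()
            | glu_missing)
    report.missing_ms_inputs = int((rule & keep).sum())
    keep &= ~rule

    rule = df["followup_years"].isna() | df["died"].isna()
    report.missing_mortality = int((rule & keep).sum())
    keep &= ~rule

    out = df.loc[keep].copy()
    report.retained = len(out)
    report.check()
    return out, report


def read_cohort(path, apply_cohort_filters: bool = True) -> tuple[pd.DataFrame, FilterReport]:
    """Read and validate a cohort CSV.

    Unknown columns are preserved but ignored (a notice is logged).
    Non-numeric values in numeric columns raise with the offending row
    numbers.  Returns the filtered frame and the exclusion report.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CohortReadError(f"cohort file is empty: {path}")
    if df.empty:
        raise CohortReadError(f"cohort file has no data rows: {path}")

    missing = [c for c, (_, req) in SCHEMA_COLUMNS.items()
               if req and c not in df.columns]
    if missing:
        raise CohortReadError(f"cohort file lacks required columns: {missing}")

    unknown = [c for c in df.columns
               if c not in SCHEMA_COLUMNS and not c.startswith(("z_true_", "true_"))]
    if unknown:
        log.info("ignoring unknown cohort columns: %s", unknown)

    for col, (kind, _) in SCHEMA_COLUMNS.items():
        if col not in df.columns or kind == "str":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:10]  # 1-based incl. header
            raise CohortReadError(
                f"non-numeric values in column {col!r} at file line(s) {rows}"
            )
        df[col] = coerced

    bad_sex = ~df["sex"].isin(["male", "female"]) & df["sex"].notna()
    if bad_sex.any():
        rows = (df.index[bad_sex] + 2).tolist()[:10]
        raise CohortReadError(
            f"sex must be 'male' or 'female'; bad values at line(s) {rows}"
        )

    if apply_cohort_filters:
        return apply_filters(df)
    report = FilterReport(n_input=len(df), retained=len(df))
    return df, report


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort frame in the canonical CSV schema (lossless
    round-trip: floats use shortest-repr formatting)."""
    df.to_csv(path, index=False)


@dataclass
class ColumnMap:
    """Mapping from an external file's columns to the cohort schema.

    ``columns`` maps source column name -> canonical name; ``sex_codes``
    maps source sex codes (e.g. 1/2) to 'male'/'female';
    ``missing_values`` lists sentinel values treated as missing.
    """

    columns: dict[str, str]
    sex_codes: dict = field(default_factory=dict)
    missing_values: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "ColumnMap":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls(
            columns=spec["columns"],
            sex_codes=spec.get("sex_codes", {}),
            missing_values=spec.get("missing_values", []),
        )

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.rename(columns=self.columns)[list(self.columns.values())].copy()
        if self.missing_values:
            out = out.replace(self.missing_values, np.nan)
        if self.sex_codes and "sex" in out.columns:
            out["sex"] = out["sex"].map(
                {k: v for k, v in self.sex_codes.items()}
            )
        return out


def read_external_cohort(path, column_map: ColumnMap) -> tuple[pd.DataFrame, FilterReport]:
    """Read an externally extracted CSV through a column map, then apply
    the standard validation and cohort filters."""
    raw = pd.read_csv(path)
    mapped = column_map.apply(raw)
    import io as _io

    buf = _io.StringIO()
    mapped.to_csv(buf, index=False)
    buf.seek(0)
    return read_cohort(buf)
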