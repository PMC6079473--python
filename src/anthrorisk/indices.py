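"""Anthropometric indices: BMI, ABSI and hip index (HI).

Raw inputs follow the NHANES convention (height, waist and hip
circumference in cm; weight in kg).  ABSI is reported in its customary
SI magnitude (~0.08), i.e. with height and waist in meters:

    BMI  = W / H^2                      [kg/m^2]
    ABSI = WC * H^(5/6) * W^(-2/3)      [m^(11/6) kg^(-2/3)]
    HI   = HC * (H/<H>)^0.310 * (W/<W>)^(-0.482)   [cm]

with the scaling constants <H> = 166 cm and <W> = 73 kg, so that a
subject at the reference height and weight has HI equal to their hip
circumference.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

# Scaling constants entering the HI definition.
H_REF_CM = 166.0
W_REF_KG = 73.0

# HI allometric exponents (fixed by definition, never re-fitted).
HI_HEIGHT_EXP = 0.310
HI_WEIGHT_EXP = -0.482

#: Default plausibility bounds for adult measurements, in ingest units.
#: Violations are *flagged*, not dropped; exclusion policy lives with the
#: cohort reader.
DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "height_cm": (100.0, 230.0),
    "weight_kg": (25.0, 350.0),
    "waist_cm": (40.0, 220.0),
    "hip_cm": (50.0, 220.0),
}


class InvalidMeasurementError(ValueError):
    """Raised when a raw anthropometric value is missing or nonpositive."""


@dataclass(frozen=True)
class RawAnthro:
    """One subject's raw anthropometrics (cm / kg)."""

    height_cm: float
    weight_kg: float
    waist_cm: float
    hip_cm: float

    def validate(self) -> None:
        for name in ("height_cm", "weight_kg", "waist_cm", "hip_cm"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise InvalidMeasurementError(f"missing measurement: {name}")
            if not np.isfinite(v) or v <= 0:
                raise InvalidMeasurementError(
                    f"nonpositive or non-finite measurement: {name}={v!r}"
                )

    def plausibility_flags(
        self, bounds: Mapping[str, tuple[float, float]] = DEFAULT_BOUNDS
    ) -> list[str]:
        """Names of fields outside their plausibility bounds (may be empty)."""
        flags = []
        for name, (lo, hi) in bounds.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                flags.append(name)
        return flags


@dataclass(frozen=True)
class AnthroIndexSet:
    """BMI, ABSI and HI for one subject (height carried for the H index)."""

    bmi: float
    absi: float
    hi: float
    height_cm: float


def _check_positive(**values: float) -> None:
    for name, v in values.items():
        arr = np.asarray(v, dtype=float)
        if np.any(np.isnan(arr)):
            raise InvalidMeasurementError(f"missing measurement: {name}")
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise InvalidMeasurementError(
                f"nonpositive or non-finite measurement: {name}"
            )


def compute_bmi(height_cm, weight_kg):
    """Body mass index, kg/m^2.  Accepts scalars or arrays."""
    _check_positive(height_cm=height_cm, weight_kg=weight_kg)
    h_m = np.asarray(height_cm, dtype=float) / 100.0
    return np.asarray(weight_kg, dtype=float) / h_m**2


def compute_absi(height_cm, weight_kg, waist_cm):
    """A body shape index, WC * H^(5/6) * W^(-2/3), with WC and H in meters."""
    _check_positive(height_cm=height_cm, weight_kg=weight_kg, waist_cm=waist_cm)
    h_m = np.asarray(height_cm, dtype=float) / 100.0
    wc_m = np.asarray(waist_cm, dtype=float) / 100.0
    w = np.asarray(weight_kg, dtype=float)
    return wc_m * h_m ** (5.0 / 6.0) * w ** (-2.0 / 3.0)


def compute_hi(height_cm, weight_kg, hip_cm):
    """Hip index, HC * (H/166 cm)^0.310 * (W/73 kg)^(-0.482), in cm."""
    _check_positive(height_cm=height_cm, weight_kg=weight_kg, hip_cm=hip_cm)
    h = np.asarray(height_cm, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    hc = np.asarray(hip_cm, dtype=float)
    return hc * (h / H_REF_CM) ** HI_HEIGHT_EXP * (w / W_REF_KG) ** HI_WEIGHT_EXP


def compute_all(raw: RawAnthro) -> AnthroIndexSet:
    """All three indices for one subject; height is passed through for H."""
    raw.validate()
    return AnthroIndexSet(
        bmi=float(compute_bmi(raw.height_cm, raw.weight_kg)),
        absi=float(compute_absi(raw.height_cm, raw.weight_kg, raw.waist_cm)),
        hi=float(compute_hi(raw.height_cm, raw.weight_kg, raw.hip_cm)),
        height_cm=raw.height_cm,
    )


def add_indices(df: pd.DataFrame) -> pd.DataFrame:
    """Append ``bmi``, ``absi`` and ``hi`` columns to a cohort frame.

    Expects ``height_cm``, ``weight_kg``, ``waist_cm``, ``hip_cm`` columns.
    Rows with missing anthropometrics yield NaN indices (they are flagged
    and excluded by the cohort reader, not here).
    """
    out = df.copy()
    h, w = df["height_cm"].to_numpy(float), df["weight_kg"].to_numpy(float)
    wc, hc = df["waist_cm"].to_numpy(float), df["hip_cm"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["bmi"] = w / (h / 100.0) ** 2
        out["absi"] = (wc / 100.0) * (h / 100.0) ** (5.0 / 6.0) * w ** (-2.0 / 3.0)
        out["hi"] = hc * (h / H_REF_CM) ** HI_HEIGHT_EXP * (w / W_REF_KG) ** HI_WEIGHT_EXP
    return out


def plausibility_table(
    df: pd.DataFrame, bounds: Mapping[str, tuple[float, float]] = DEFAULT_BOUNDS
) -> pd.DataFrame:
    """Boolean frame marking out-of-bounds raw measurements per subject."""
    flags = {}
    for name, (lo, hi) in bounds.items():
        v = df[name]
        flags[name] = ~v.between(lo, hi) & v.notna()
    return pd.DataFrame(flags, index=df.index)
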