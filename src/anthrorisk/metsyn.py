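"""ATP III metabolic syndrome (MS) component scoring.

Five components are each scored 0/1:

* Waist: waist circumference above 102 cm (men) / 88 cm (women)
* BP:    SBP >= 130 mmHg, or DBP >= 85 mmHg, or on BP medication
* TG:    fasting triglycerides >= 150 mg/dL
* HDL:   HDL under 40 mg/dL (men) / 50 mg/dL (women)
* Glu:   fasting glucose >= 110 mg/dL, or taking diabetes pills

The MS score is their 0-5 sum; a score of 3 or above defines MS.  The
"MSx" score (0-4) omits the Waist component, for use alongside ARI
whose inputs already include waist circumference.

Boundary semantics follow the criteria wording literally: "at or
above" is inclusive (>=), "above"/"under" are strict (>/<).  Missing
inputs raise (scalar API) or propagate as missing (frame API); they
are never imputed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WAIST_CUT_CM = {"male": 102.0, "female": 88.0}   # strict >
SBP_CUT = 130.0                                   # inclusive >=
DBP_CUT = 85.0                                    # inclusive >=
TG_CUT = 150.0                                    # inclusive >=
HDL_CUT = {"male": 40.0, "female": 50.0}          # strict <
GLU_CUT = 110.0                                   # inclusive >=

MS_COMPONENT_COLUMNS = ["ms_waist", "ms_bp", "ms_tg", "ms_hdl", "ms_glu"]


class MissingComponentError(ValueError):
    """Raised when an MS component cannot be scored for lack of inputs."""


def _require(name: str, value) -> None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise MissingComponentError(f"missing input for MS component: {name}")


def score_waist(waist_cm: float, sex: str) -> int:
    _require("waist_cm", waist_cm)
    if sex not in WAIST_CUT_CM:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return int(waist_cm > WAIST_CUT_CM[sex])


def score_bp(sbp_mmhg, dbp_mmhg, bp_meds) -> int:
    if all(
        v is None or (isinstance(v, float) and np.isnan(v))
        for v in (sbp_mmhg, dbp_mmhg, bp_meds)
    ):
        raise MissingComponentError(
            "missing input for MS component: sbp_mmhg/dbp_mmhg/bp_meds"
        )
    sbp_high = sbp_mmhg is not None and not _isnan(sbp_mmhg) and sbp_mmhg >= SBP_CUT
    dbp_high = dbp_mmhg is not None and not _isnan(dbp_mmhg) and dbp_mmhg >= DBP_CUT
    meds = bool(bp_meds) if bp_meds is not None and not _isnan(bp_meds) else False
    return int(sbp_high or dbp_high or meds)


def score_tg(tg_mg_dl: float) -> int:
    _require("tg_mg_dl", tg_mg_dl)
    return int(tg_mg_dl >= TG_CUT)


def score_hdl(hdl_mg_dl: float, sex: str) -> int:
    _require("hdl_mg_dl", hdl_mg_dl)
    if sex not in HDL_CUT:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return int(hdl_mg_dl < HDL_CUT[sex])


def score_glu(glu_mg_dl, diabetes_pills) -> int:
    pills = (
        bool(diabetes_pills)
        if diabetes_pills is not None and not _isnan(diabetes_pills)
        else False
    )
    if glu_mg_dl is None or _isnan(glu_mg_dl):
        if pills:
            return 1
        raise MissingComponentError("missing input for MS component: glu_mg_dl")
    return int(glu_mg_dl >= GLU_CUT or pills)


def _isnan(v) -> bool:
    return isinstance(v, float) and np.isnan(v)


@dataclass(frozen=True)
class MSResult:
    """Component scores, their sum, and the >= 3 MS indicator."""

    waist: int
    bp: int
    tg: int
    hdl: int
    glu: int

    @property
    def ms_score(self) -> int:
        return self.waist + self.bp + self.tg + self.hdl + self.glu

    @property
    def ms(self) -> int:
        return int(self.ms_score >= 3)

    @property
    def msx_score(self) -> int:
        """MS score excluding the Waist component (0-4)."""
        return self.ms_score - self.waist


def ms_total(
    *,
    waist_cm: float,
    sex: str,
    sbp_mmhg: float,
    dbp_mmhg: float,
    bp_meds,
    tg_mg_dl: float,
    hdl_mg_dl: float,
    glu_mg_dl: float,
    diabetes_pills,
) -> MSResult:
    """Score all five MS components for one subject.

    Raises :class:`MissingComponentError` listing the unscoreable
    components if any inputs are missing.
    """
    scores, missing = {}, []
    for name, fn in (
        ("waist", lambda: score_waist(waist_cm, sex)),
        ("bp", lambda: score_bp(sbp_mmhg, dbp_mmhg, bp_meds)),
        ("tg", lambda: score_tg(tg_mg_dl)),
        ("hdl", lambda: score_hdl(hdl_mg_dl, sex)),
        ("glu", lambda: score_glu(glu_mg_dl, diabetes_pills)),
    ):
        try:
            scores[name] = fn()
        except MissingComponentError:
            missing.append(name)
    if missing:
        raise MissingComponentError(f"unscoreable MS components: {missing}")
    return MSResult(**scores)


def score_dataframe(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized MS scoring of a cohort frame.

    Appends ``ms_waist .. ms_glu``, ``ms_score``, ``ms`` and
    ``msx_score``.  Rows with any missing component input get missing
    scores (complete-case analysis happens downstream, not here).
    """
    out = df.copy()
    male = df["sex"] == "male"
    waist_cut = np.where(male, WAIST_CUT_CM["male"], WAIST_CUT_CM["female"])
    hdl_cut = np.where(male, HDL_CUT["male"], HDL_CUT["female"])

    waist = (df["waist_cm"] > waist_cut).astype(float)
    waist[df["waist_cm"].isna()] = np.nan

    meds = df["bp_meds"].fillna(0).astype(bool)
    bp = ((df["sbp_mmhg"] >= SBP_CUT) | (df["dbp_mmhg"] >= DBP_CUT) | meds).astype(float)
    bp[df["sbp_mmhg"].isna() & df["dbp_mmhg"].isna() & df["bp_meds"].isna()] = np.nan

    tg = (df["tg_mg_dl"] >= TG_CUT).astype(float)
    tg[df["tg_mg_dl"].isna()] = np.nan

    hdl = (df["hdl_mg_dl"] < hdl_cut).astype(float)
    hdl[df["hdl_mg_dl"].isna()] = np.nan

    pills = df["diabetes_pills"].fillna(0).astype(bool)
    glu = ((df["glu_mg_dl"] >= GLU_CUT) | pills).astype(float)
    glu[df["glu_mg_dl"].isna() & ~pills] = np.nan

    out["ms_waist"], out["ms_bp"], out["ms_tg"] = waist, bp, tg
    out["ms_hdl"], out["ms_glu"] = hdl, glu
    comp = out[MS_COMPONENT_COLUMNS]
    out["ms_score"] = comp.sum(axis=1, skipna=False)
    out["ms"] = (out["ms_score"] >= 3).astype(float)
    out.loc[out["ms_score"].isna(), "ms"] = np.nan
    out["msx_score"] = out["ms_score"] - out["ms_waist"]
    return out
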