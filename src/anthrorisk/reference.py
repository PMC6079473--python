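"""Age- and sex-specific standardization of anthropometric indices.

Height, BMI, ABSI and HI all drift with age and differ between the
sexes (strongly so for ABSI and HI), so their raw values are converted
to Z scores against an age-sex stratified reference: for each index,

    z = (value - mean(sex, age bin)) / sd(sex, age bin).

The reference is a simple table of per-stratum sample moments, built
either from the cohort itself or loaded from CSV so that published
reference values can be substituted.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Index columns standardized by the reference table.
INDEX_COLUMNS = ("height_cm", "bmi", "absi", "hi")

#: Z-score column name per index.
Z_COLUMNS = {"height_cm": "z_height", "bmi": "z_bmi", "absi": "z_absi", "hi": "z_hi"}

OUTLIER_Z = 6.0  # |z| beyond this is flagged as a probable data problem


class ReferenceError(ValueError):
    """Raised when a reference table cannot be built or queried."""


def age_bin_edges(age_bin_width: float = 5.0, first_break: float = 20.0,
                  pool_above: float = 80.0) -> np.ndarray:
    """Bin edges for adult age strata.

    The first bin is [18, ``first_break``) (18-19 with the defaults),
    then bins of ``age_bin_width`` years up to ``pool_above``, with ages
    at or above ``pool_above`` pooled into one open-ended stratum.
    Returned edges end with +inf; with defaults this yields 14 bins.
    """
    edges = [18.0, first_break]
    e = first_break
    while e < pool_above:
        e = min(e + age_bin_width, pool_above)
        edges.append(e)
    edges.append(np.inf)
    return np.asarray(edges)


@dataclass
class ReferenceTable:
    """Per (sex, age-bin, index) means and SDs used for Z scoring.

    ``table`` has columns: sex, age_lo, age_hi, index, mean, sd, n.
    Age bins are [age_lo, age_hi); the last bin per sex is open-ended.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        if (t["sd"] <= 0).any():
            bad = t.loc[t["sd"] <= 0].iloc[0]
            raise ReferenceError(
                f"nonpositive SD in reference cell (sex={bad['sex']}, "
                f"age [{bad['age_lo']}, {bad['age_hi']}), index={bad['index']})"
            )

    @property
    def sexes(self) -> list[str]:
        return sorted(self.table["sex"].unique())

    def n_bins(self, sex: str) -> int:
        sub = self.table[self.table["sex"] == sex]
        return sub[["age_lo", "age_hi"]].drop_duplicates().shape[0]

    # -- construction ------------------------------------------------------

    @classmethod
    def build(
        cls,
        df: pd.DataFrame,
        age_bin_width: float = 5.0,
        min_cell_n: int = 25,
        weight_col: str | None = None,
        index_columns: tuple[str, ...] = INDEX_COLUMNS,
    ) -> "ReferenceTable":
        """Build a reference from a sample with sex, age and index columns.

        Cells with fewer than ``min_cell_n`` subjects are merged into the
        adjacent younger bin (the first bin merges upward).  Moments are
        unweighted by default; pass ``weight_col`` to use survey-weighted
        means and SDs instead.
        """
        if df.empty:
            raise ReferenceError("reference sample is empty")
        for sex in ("male", "female"):
            if not (df["sex"] == sex).any():
                raise ReferenceError(f"reference sample has no {sex} subjects")
        missing = [c for c in index_columns if c not in df.columns]
        if missing:
            raise ReferenceError(f"reference sample lacks columns: {missing}")

        edges = age_bin_edges(age_bin_width)
        rows = []
        for sex, sub in df.groupby("sex", observed=True):
            ages = sub["age"].to_numpy(float)
            if np.any(ages < 18):
                raise ReferenceError("reference sample contains ages under 18")
            bin_idx = np.searchsorted(edges, ages, side="right") - 1
            # Trim to bins actually populated, then merge small cells into
            # the adjacent younger bin so every retained stratum has
            # >= min_cell_n subjects.
            bins = _merge_small_bins(bin_idx, min_cell_n)
            for (lo_i, hi_i), members in bins:
                cell = sub.iloc[members]
                w = (
                    cell[weight_col].to_numpy(float)
                    if weight_col is not None
                    else np.ones(len(cell))
                )
                for col in index_columns:
                    x = cell[col].to_numpy(float)
                    mean, sd = _weighted_moments(x, w)
                    rows.append(
                        dict(
                            sex=sex,
                            age_lo=edges[lo_i],
                            age_hi=edges[hi_i + 1],
                            index=col,
                            mean=mean,
                            sd=sd,
                            n=len(cell),
                        )
                    )
        table = pd.DataFrame(rows)
        if table.empty:
            raise ReferenceError("no populated reference cells after merging")
        return cls(table)

    # -- queries -----------------------------------------------------------

    def lookup(self, sex: str, age: float, index: str) -> tuple[float, float]:
        """(mean, sd) for a subject's stratum; ages outside the covered
        range clamp to the nearest boundary bin with a logged warning."""
        sub = self.table[(self.table["sex"] == sex) & (self.table["index"] == index)]
        if sub.empty:
            raise ReferenceError(f"no reference cells for sex={sex!r}, index={index!r}")
        lo, hi = sub["age_lo"].min(), sub["age_hi"].max()
        if age < lo or age >= hi:
            log.warning(
                "age %.1f outside reference range [%s, %s); clamping", age, lo, hi
            )
            age = min(max(age, lo), sub["age_lo"].max())
        row = sub[(sub["age_lo"] <= age) & (age < sub["age_hi"])]
        if row.empty:  # pragma: no cover - bins partition the range
            raise ReferenceError(f"no reference cell covers age {age}")
        r = row.iloc[0]
        return float(r["mean"]), float(r["sd"])

    def zscores(self, df: pd.DataFrame) -> pd.DataFrame:
        """Z-score every index column of a cohort frame.

        Returns a copy with ``z_height``, ``z_bmi``, ``z_absi``, ``z_hi``
        appended.  |z| > 6 triggers a logged outlier warning.
        """
        out = df.copy()
        for index_col, z_col in Z_COLUMNS.items():
            z = np.full(len(df), np.nan)
            for sex in self.sexes:
                mask = (df["sex"] == sex).to_numpy()
                if not mask.any():
                    continue
                sub = self.table[
                    (self.table["sex"] == sex) & (self.table["index"] == index_col)
                ].sort_values("age_lo")
                edges = np.append(sub["age_lo"].to_numpy(), sub["age_hi"].iloc[-1])
                ages = df.loc[mask, "age"].to_numpy(float)
                if np.any(ages < edges[0]) or np.any(ages >= edges[-1]):
                    log.warning("ages outside reference range; clamping to boundary bins")
                idx = np.clip(
                    np.searchsorted(edges, ages, side="right") - 1, 0, len(sub) - 1
                )
                mean = sub["mean"].to_numpy()[idx]
                sd = sub["sd"].to_numpy()[idx]
                z[mask] = (df.loc[mask, index_col].to_numpy(float) - mean) / sd
            n_out = int(np.sum(np.abs(z[np.isfinite(z)]) > OUTLIER_Z))
            if n_out:
                log.warning("%d %s values with |z| > %g", n_out, z_col, OUTLIER_Z)
            out[z_col] = z
        return out

    def zscore_one(self, sex: str, age: float, values: dict[str, float]) -> dict[str, float]:
        """Z scores for a single subject; ``values`` maps index column -> value."""
        out = {}
        for index_col, v in values.items():
            mean, sd = self.lookup(sex, age, index_col)
            out[Z_COLUMNS.get(index_col, f"z_{index_col}")] = (v - mean) / sd
        return out

    # -- serialization -----------------------------------------------------

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        t = pd.read_csv(path)
        required = {"sex", "age_lo", "age_hi", "index", "mean", "sd", "n"}
        if not required.issubset(t.columns):
            raise ReferenceError(f"reference CSV must have columns {sorted(required)}")
        return cls(t)


def _merge_small_bins(bin_idx: np.ndarray, min_cell_n: int):
    """Group member positions by age bin, merging bins with fewer than
    ``min_cell_n`` members into the adjacent younger bin (first bin merges
    upward).  Returns [((lo_bin, hi_bin), member_positions), ...]."""
    present = sorted(set(bin_idx.tolist()))
    groups = [((b, b), np.flatnonzero(bin_idx == b)) for b in present]
    i = 0
    while len(groups) > 1 and i < len(groups):
        (span, members) = groups[i]
        if len(members) < min_cell_n:
            j = i - 1 if i > 0 else i + 1  # merge into younger neighbor
            other_span, other_members = groups[j]
            lo = min(span[0], other_span[0])
            hi = max(span[1], other_span[1])
            merged = ((lo, hi), np.concatenate([other_members, members]))
            groups[min(i, j)] = merged
            del groups[max(i, j)]
            i = 0  # restart: merging can leave earlier groups small
        else:
            i += 1
    if len(groups) == 1 and len(groups[0][1]) < min_cell_n:
        warnings.warn("single reference stratum smaller than min_cell_n", stacklevel=2)
    return groups


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted mean and (ddof=1-style) SD; plain sample moments when all
    weights are equal."""
    sw = w.sum()
    mean = float(np.sum(w * x) / sw)
    # unbiased analogue of ddof=1 under weights
    denom = sw - np.sum(w**2) / sw
    if denom <= 0:
        return mean, 0.0
    var = float(np.sum(w * (x - mean) ** 2) / denom)
    return mean, float(np.sqrt(var))
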