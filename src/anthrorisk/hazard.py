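"""Per-index log-hazard curves and the anthropometric risk index (ARI).

For each standardized anthropometric index (height, BMI, ABSI, HI), a
penalized-spline Cox proportional-hazards regression with attained age
as the timescale (left-truncated entry at baseline age) estimates the
log mortality-hazard ratio as a smooth function h(z) of the index Z
score.  Curves are fitted on a *training* subsample and applied to a
disjoint evaluation subsample.

Each curve is centered so that the training-sample (weighted) mean of
exp(h(z)) equals 1: a subject with h = 0 carries the population-average
hazard.  ARI is the sum of the four per-index log hazards, and exp(ARI)
is the subject's hazard as a fraction of the population average.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.interpolate import BSpline

from .loglik import efron_partial_loglik

log = logging.getLogger(__name__)

#: Index name -> (z-score column, log-hazard component column)
INDEX_Z_COLUMNS = {
    "height": ("z_height", "h_height"),
    "bmi": ("z_bmi", "h_bmi"),
    "absi": ("z_absi", "h_absi"),
    "hi": ("z_hi", "h_hi"),
}

H_COMPONENT_COLUMNS = [v[1] for v in INDEX_Z_COLUMNS.values()]


class HazardFitError(RuntimeError):
    """Raised when a hazard-curve fit is infeasible or fails to converge."""


@dataclass
class SplineConfig:
    """Configuration of the penalized-spline Cox fit.

    ``n_interior_knots`` cubic-spline knots are placed at evenly spaced
    quantiles of the training Z scores; boundary knots sit at the ends of
    ``z_range`` so the curve is evaluable over the whole range.  The
    ridge penalty is chosen from ``penalizer_grid`` by minimizing
    AIC = -2 loglik + 2 edf, where edf is the effective number of
    parameters of the penalized fit.
    """

    n_interior_knots: int = 4
    degree: int = 3
    z_range: tuple[float, float] = (-4.0, 4.0)
    penalizer_grid: tuple[float, ...] = (0.01, 0.03, 0.1, 0.3)
    min_events: int = 50


@dataclass
class HazardCurve:
    """A centered spline estimate of log hazard ratio vs index Z score."""

    index_name: str
    knots: np.ndarray
    degree: int
    coef: np.ndarray
    offset: float
    z_range: tuple[float, float]
    n: int
    n_events: int
    penalizer: float = 0.0
    edf: float = float("nan")

    def _basis(self, z: np.ndarray) -> np.ndarray:
        dm = BSpline.design_matrix(z, self.knots, self.degree).toarray()
        return dm[:, 1:]  # first column dropped for Cox identifiability

    def evaluate(self, z) -> np.ndarray:
        """Centered log hazard ratio at ``z``; out-of-range values are
        clamped to the evaluable range with a warning."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        lo, hi = self.z_range
        if np.any(z < lo) or np.any(z > hi):
            log.warning(
                "%s: %d z values outside [%g, %g]; clamped",
                self.index_name, int(np.sum((z < lo) | (z > hi))), lo, hi,
            )
            z = np.clip(z, lo, hi)
        return self._basis(z) @ self.coef - self.offset

    def __call__(self, z):
        out = self.evaluate(z)
        return float(out[0]) if np.isscalar(z) or np.ndim(z) == 0 else out

    # -- serialization -----------------------------------------------------

    def to_grid_frame(self, step: float = 0.01) -> pd.DataFrame:
        """Dense (z, log hazard) grid over the evaluable range, matching
        the online-calculator interchange convention."""
        lo, hi = self.z_range
        z = np.round(np.arange(lo, hi + step / 2, step), 10)
        return pd.DataFrame({"z": z, "log_hazard_ratio": self.evaluate(z)})

    def to_files(self, csv_path, json_path, step: float = 0.01) -> None:
        self.to_grid_frame(step).to_csv(csv_path, index=False)
        meta = {
            "index_name": self.index_name,
            "knots": self.knots.tolist(),
            "degree": self.degree,
            "coef": self.coef.tolist(),
            "offset": self.offset,
            "z_range": list(self.z_range),
            "n": self.n,
            "n_events": self.n_events,
            "penalizer": self.penalizer,
            "edf": self.edf,
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_json(cls, json_path) -> "HazardCurve":
        with open(json_path) as fh:
            meta = json.load(fh)
        return cls(
            index_name=meta["index_name"],
            knots=np.asarray(meta["knots"]),
            degree=meta["degree"],
            coef=np.asarray(meta["coef"]),
            offset=meta["offset"],
            z_range=tuple(meta["z_range"]),
            n=meta["n"],
            n_events=meta["n_events"],
            penalizer=meta.get("penalizer", 0.0),
            edf=meta.get("edf", float("nan")),
        )


def _spline_knots(z: np.ndarray, config: SplineConfig) -> np.ndarray:
    lo, hi = config.z_range
    qs = np.linspace(0, 1, config.n_interior_knots + 2)[1:-1]
    interior = np.quantile(z, qs)
    interior = np.clip(interior, lo + 1e-6, hi - 1e-6)
    # strictly increasing interior knots (degenerate quantiles are spread)
    interior = np.maximum.accumulate(interior + 1e-9 * np.arange(len(interior)))
    k = config.degree
    return np.concatenate([[lo] * (k + 1), interior, [hi] * (k + 1)])


def fit_hazard_curve(
    train: pd.DataFrame,
    z_col: str,
    index_name: str | None = None,
    config: SplineConfig | None = None,
    entry_col: str = "age",
    duration_col: str = "exit_age",
    event_col: str = "died",
    weight_col: str | None = None,
) -> HazardCurve:
    """Penalized-spline Cox fit of log mortality hazard against one Z score.

    Age is the timescale: subjects enter the risk set at baseline age
    (``entry_col``) and exit at death/censoring age (``duration_col``).
    The fit is unweighted unless ``weight_col`` is given.  The returned
    curve is centered so the training-sample (weighted) mean of
    exp(h(z)) is 1.
    """
    config = config or SplineConfig()
    index_name = index_name or z_col
    n_events = int(train[event_col].sum())
    if n_events < config.min_events:
        raise HazardFitError(
            f"{index_name}: {n_events} events < required minimum {config.min_events}"
        )
    z = train[z_col].to_numpy(float)
    if not np.all(np.isfinite(z)):
        raise HazardFitError(f"{index_name}: non-finite Z scores in training data")
    lo, hi = config.z_range
    n_clip = int(np.sum((z < lo) | (z > hi)))
    if n_clip:
        log.warning("%s: clamping %d training z values into [%g, %g]",
                    index_name, n_clip, lo, hi)
        z = np.clip(z, lo, hi)

    knots = _spline_knots(z, config)
    degree = config.degree
    basis = BSpline.design_matrix(z, knots, degree).toarray()[:, 1:]
    cols = [f"b{j}" for j in range(basis.shape[1])]
    df = pd.DataFrame(basis, columns=cols)
    df["_entry"] = train[entry_col].to_numpy(float)
    df["_exit"] = train[duration_col].to_numpy(float)
    df["_event"] = train[event_col].to_numpy(int)
    w = (train[weight_col].to_numpy(float) if weight_col is not None
         else np.ones(len(train)))
    df["_w"] = w

    entry, exit_, event = df["_entry"].to_numpy(), df["_exit"].to_numpy(), df["_event"].to_numpy()
    n = len(df)
    best = None
    for lam in config.penalizer_grid:
        cph = CoxPHFitter(penalizer=lam)
        try:
            cph.fit(
                df, duration_col="_exit", event_col="_event", entry_col="_entry",
                weights_col="_w", robust=False, show_progress=False,
            )
        except Exception as exc:  # convergence failures carry diagnostics
            raise HazardFitError(f"{index_name}: Cox fit failed at penalizer={lam}: {exc}")
        beta = cph.params_.to_numpy()
        eta = basis @ beta
        ll = efron_partial_loglik(entry, exit_, event, eta, w)
        # lifelines' L2 penalty is n*lam*0.5*||beta_norm||^2 on std-normalized
        # covariates, so the penalized information in normalized scale is
        # I_pen = I + n*lam*Id and edf = p - n*lam*tr(I_pen^{-1}) with
        # tr(I_pen^{-1}) = sum_j Var_jj * std_j^2 (Var in original scale).
        stds = df[cols].std(ddof=1).to_numpy()
        v_diag = np.diag(cph.variance_matrix_.to_numpy())
        edf = len(cols) - n * lam * float(np.sum(v_diag * stds**2))
        aic = -2.0 * ll + 2.0 * edf
        if best is None or aic < best[0]:
            best = (aic, lam, beta, edf)
    _, lam, beta, edf = best

    raw = basis @ beta
    offset = float(np.log(np.average(np.exp(raw), weights=w)))
    return HazardCurve(
        index_name=index_name, knots=knots, degree=degree, coef=beta,
        offset=offset, z_range=config.z_range, n=n, n_events=n_events,
        penalizer=lam, edf=float(edf),
    )


def fit_all_curves(
    train: pd.DataFrame,
    config: SplineConfig | None = None,
    weight_col: str | None = None,
    **fit_kwargs,
) -> dict[str, HazardCurve]:
    """Fit the four per-index curves (height, BMI, ABSI, HI) on the
    training subsample."""
    return {
        name: fit_hazard_curve(
            train, z_col, index_name=name, config=config,
            weight_col=weight_col, **fit_kwargs,
        )
        for name, (z_col, _) in INDEX_Z_COLUMNS.items()
    }


@dataclass(frozen=True)
class ARIComponents:
    """Per-index log hazard ratios, their sum, and exp(sum) for one subject."""

    h_height: float
    h_bmi: float
    h_absi: float
    h_hi: float

    @property
    def ari(self) -> float:
        return self.h_height + self.h_bmi + self.h_absi + self.h_hi

    @property
    def relative_hazard(self) -> float:
        return float(np.exp(self.ari))


def compute_ari(
    df: pd.DataFrame, curves: Mapping[str, HazardCurve]
) -> pd.DataFrame:
    """Evaluate the four curves at each subject's Z scores and sum into ARI.

    Appends ``h_height``, ``h_bmi``, ``h_absi``, ``h_hi``, ``ari`` and
    ``relative_hazard`` columns.  ``ari`` is the exact sum of the four
    components; exp(ari) is hazard relative to the population average.
    """
    missing = [name for name in INDEX_Z_COLUMNS if name not in curves]
    if missing:
        raise KeyError(f"missing hazard curves for indices: {missing}")
    out = df.copy()
    total = np.zeros(len(df))
    for name, (z_col, h_col) in INDEX_Z_COLUMNS.items():
        h = curves[name].evaluate(df[z_col].to_numpy(float))
        out[h_col] = h
        total = total + h
    out["ari"] = total
    out["relative_hazard"] = np.exp(total)
    return out


def ari_components_one(
    zscores: Mapping[str, float], curves: Mapping[str, HazardCurve]
) -> ARIComponents:
    """ARI components for a single subject given z_height .. z_hi."""
    vals = {}
    for name, (z_col, h_col) in INDEX_Z_COLUMNS.items():
        if name not in curves:
            raise KeyError(f"missing hazard curve for index: {name}")
        vals[h_col] = float(curves[name].evaluate(zscores[z_col])[0])
    return ARIComponents(**vals)
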