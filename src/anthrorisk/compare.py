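"""Cox model roster, AIC comparison, explained variation and concordance.

Ten proportional-hazards models for all-cause mortality are compared,
ranging from a covariate-only base model through ARI, MS occurrence,
MS score and MS components, to combined ARI + MS models.  Every model
additionally includes sex and black race as covariates; attained age is
the timescale (left-truncated entry at baseline age) and survey weights
enter the partial likelihood as case weights with robust (sandwich)
variance.

Relative performance is summarized by the AIC difference Delta_i
against the best model (Delta_i > 6 marks a model as significantly
worse; models within 6 are statistically tied), by a Royston-
Sauerbrei-type explained-variation R^2 on the log-hazard scale, and by
a weighted Harrell concordance C over pairs comparable under the age
timescale (ties count 1/2, so C = 0.5 means no discrimination).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import norm, rankdata

#: Threshold above which an AIC difference marks a model as significantly
#: worse than the best model in the comparison set.
DELTA_AIC_WORSE = 6.0

_KAPPA2 = 8.0 / np.pi          # rankit scaling constant of the D statistic
_SIGMA2_PH = np.pi**2 / 6.0    # log-hazard-scale variance constant

#: Predictors per model (sex and race are always added on top).
MODEL_SPECS: dict[str, list[str]] = {
    "Base": [],
    "ARI": ["ari"],
    "MS": ["ms"],
    "MS score": ["ms_score"],
    "ARI + MS": ["ari", "ms"],
    "ARI + MS score": ["ari", "ms_score"],
    "ARI + MSx score": ["ari", "msx_score"],
    "MS components": ["ms_waist", "ms_bp", "ms_tg", "ms_hdl", "ms_glu"],
    "ARI + MS components": ["ari", "ms_waist", "ms_bp", "ms_tg", "ms_hdl", "ms_glu"],
    "ARI + MSx components": ["ari", "ms_bp", "ms_tg", "ms_hdl", "ms_glu"],
}

#: Covariates included in every model.
ALWAYS_INCLUDED = ["male", "race_black"]


class CollinearityError(ValueError):
    """Raised when a model's design matrix is rank deficient."""


class CohortMismatchError(ValueError):
    """Raised when AIC differences are requested across different cohorts."""


@dataclass
class ModelFitResult:
    """One fitted Cox model with its performance measures."""

    name: str
    predictors: list[str]
    summary: pd.DataFrame = field(repr=False)  # coef, hr, ci_low, ci_high, se
    log_likelihood: float
    k: int
    aic: float
    n: int
    n_events: int
    r2: float
    c: float
    cohort_signature: tuple = field(repr=False, default=())
    delta_i: float = float("nan")
    significantly_worse: bool = False

    def hazard_ratio(self, predictor: str) -> tuple[float, float, float]:
        """(HR, CI low, CI high) for one predictor."""
        row = self.summary.loc[predictor]
        return float(row["hr"]), float(row["ci_low"]), float(row["ci_high"])


def add_exit_age(df: pd.DataFrame) -> pd.DataFrame:
    """Append the ``exit_age`` column (baseline age + follow-up years)."""
    out = df.copy()
    out["exit_age"] = out["age"] + out["followup_years"]
    return out


def _design_checks(X: pd.DataFrame) -> None:
    cols = list(X.columns)
    if len(set(cols)) != len(cols):
        dup = sorted({c for c in cols if cols.count(c) > 1})
        raise CollinearityError(f"duplicate predictors: {dup}")
    for c in cols:
        if np.isclose(X[c].std(ddof=0), 0.0):
            raise CollinearityError(f"zero-variance predictor: {c!r}")
    corr = np.corrcoef(X.to_numpy(float), rowvar=False)
    if X.shape[1] > 1:
        idx = np.triu_indices(X.shape[1], k=1)
        bad = np.flatnonzero(np.abs(corr[idx]) > 1 - 1e-10)
        if bad.size:
            i, j = idx[0][bad[0]], idx[1][bad[0]]
            raise CollinearityError(
                f"collinear predictors: {cols[i]!r} and {cols[j]!r}"
            )


def fit_cox(
    name: str,
    cohort: pd.DataFrame,
    predictors: list[str] | None = None,
    weight_col: str | None = "sample_weight",
    min_events: int = 50,
    compute_performance: bool = True,
) -> ModelFitResult:
    """Fit one roster model on the evaluation cohort.

    ``name`` is a Table-2-style roster name (or any label if explicit
    ``predictors`` are given).  Weights are normalized to sum to the
    sample size so AIC values are comparable across weighting schemes;
    confidence intervals are Wald intervals with robust variance when
    weights are in use.
    """
    if predictors is None:
        if name not in MODEL_SPECS:
            raise KeyError(f"unknown model {name!r}; known: {list(MODEL_SPECS)}")
        predictors = MODEL_SPECS[name]
    all_pred = list(predictors) + ALWAYS_INCLUDED

    df = cohort.copy()
    if "male" not in df.columns:
        df["male"] = (df["sex"] == "male").astype(float)
    if "exit_age" not in df.columns:
        df = add_exit_age(df)
    n_events = int(df["died"].sum())
    if n_events < min_events:
        raise ValueError(f"{n_events} events < required minimum {min_events}")

    X = df[all_pred].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in predictors: {bad}")
    _design_checks(X)

    if weight_col is not None:
        w_raw = df[weight_col].to_numpy(float)
        w = w_raw * len(df) / w_raw.sum()
        weighted = not np.allclose(w, 1.0)
    else:
        w = np.ones(len(df))
        weighted = False

    fit_df = X.copy()
    fit_df["_entry"] = df["age"].to_numpy(float)
    fit_df["_exit"] = df["exit_age"].to_numpy(float)
    fit_df["_event"] = df["died"].to_numpy(int)
    fit_df["_w"] = w

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            fit_df, duration_col="_exit", event_col="_event", entry_col="_entry",
            weights_col="_w", robust=weighted, show_progress=False,
        )
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
        }
    )
    ll = float(cph.log_likelihood_)
    k = len(all_pred)
    aic = -2.0 * ll + 2.0 * k

    entry = fit_df["_entry"].to_numpy()
    exit_ = fit_df["_exit"].to_numpy()
    event = fit_df["_event"].to_numpy(bool)
    pi = X.to_numpy(float) @ cph.params_.to_numpy()
    r2 = c = float("nan")
    if compute_performance:
        r2 = royston_r2(pi, entry, exit_, event, w)
        c = concordance_index(pi, entry, exit_, event, w)

    signature = (len(df), n_events, round(float(exit_.sum()), 6),
                 round(float(w.sum()), 6))
    return ModelFitResult(
        name=name, predictors=all_pred, summary=summary, log_likelihood=ll,
        k=k, aic=aic, n=len(df), n_events=n_events, r2=r2, c=c,
        cohort_signature=signature,
    )


def fit_all_models(
    cohort: pd.DataFrame,
    models: list[str] | None = None,
    weight_col: str | None = "sample_weight",
    compute_performance: bool = True,
) -> list[ModelFitResult]:
    """Fit the full roster (or a named subset) and assign AIC differences."""
    models = models or list(MODEL_SPECS)
    fits = [
        fit_cox(m, cohort, weight_col=weight_col,
                compute_performance=compute_performance)
        for m in models
    ]
    return aic_compare(fits)


def aic_compare(fits: list[ModelFitResult]) -> list[ModelFitResult]:
    """Assign Delta_i = AIC_i - min AIC and flag significantly worse models.

    All fits must come from the identical cohort and weighting.  Ties in
    AIC give Delta_i = 0 to each tied model; results are returned sorted
    by (Delta_i, name) for a deterministic order.
    """
    if not fits:
        raise ValueError("no fits to compare")
    sig = fits[0].cohort_signature
    for f in fits[1:]:
        if f.cohort_signature != sig:
            raise CohortMismatchError(
                f"fit {f.name!r} is on a different cohort/weighting than "
                f"{fits[0].name!r}; AIC differences are not meaningful"
            )
    best = min(f.aic for f in fits)
    for f in fits:
        f.delta_i = f.aic - best
        f.significantly_worse = f.delta_i > DELTA_AIC_WORSE
    return sorted(fits, key=lambda f: (f.delta_i, f.name))


def royston_r2(
    risk: np.ndarray,
    entry: np.ndarray,
    exit_: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Royston-Sauerbrei explained variation R^2_D of a prognostic index.

    The prognostic index is rank-transformed to scaled normal order
    statistics (rankits divided by kappa = sqrt(8/pi)); the Cox
    coefficient D of that transformed index measures prognostic
    separation, and R^2_D = (D^2/kappa^2) / (pi^2/6 + D^2/kappa^2)
    expresses it as a proportion of explained variation on the
    log-hazard scale.
    """
    risk = np.asarray(risk, float)
    if np.isclose(np.std(risk), 0.0):
        return 0.0
    n = len(risk)
    ranks = rankdata(risk, method="average")
    rankits = norm.ppf((ranks - 0.375) / (n + 0.25))
    x = rankits / np.sqrt(_KAPPA2)
    df = pd.DataFrame(
        {"_x": x, "_entry": entry, "_exit": exit_,
         "_event": np.asarray(event, int),
         "_w": np.ones(n) if weights is None else weights}
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_exit", event_col="_event",
                entry_col="_entry", weights_col="_w", robust=False)
    d = float(cph.params_.iloc[0])
    d2k2 = d**2 / _KAPPA2
    return d2k2 / (_SIGMA2_PH + d2k2)


def concordance_index(
    risk: np.ndarray,
    entry: np.ndarray,
    exit_: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted Harrell concordance under the age timescale.

    A pair is comparable when one subject dies at an age at which the
    other is under observation (entered earlier, exits later).  The pair
    is concordant when the dying subject carries the higher risk score;
    ties in risk count 1/2.  Pairs are weighted by the product of the
    two subjects' weights.  0.5 means no discrimination.
    """
    risk = np.asarray(risk, float)
    entry = np.asarray(entry, float)
    exit_ = np.asarray(exit_, float)
    event = np.asarray(event, bool)
    w = np.ones(len(risk)) if weights is None else np.asarray(weights, float)

    event_idx = np.flatnonzero(event)
    if event_idx.size == 0:
        raise ValueError("no events; concordance undefined")
    num = 0.0
    den = 0.0
    for i in event_idx:
        t = exit_[i]
        at_risk = (entry < t) & (exit_ > t)
        if not at_risk.any():
            continue
        pw = w[i] * w[at_risk]
        diff = risk[i] - risk[at_risk]
        num += float(pw[diff > 0].sum()) + 0.5 * float(pw[diff == 0].sum())
        den += float(pw.sum())
    if den == 0.0:
        raise ValueError("no comparable pairs; concordance undefined")
    return num / den


#: Paper-style labels for the correlation table.
CORRELATION_COLUMNS = {
    "h_height": "hH",
    "h_bmi": "hBMI",
    "h_absi": "hABSI",
    "h_hi": "hHI",
    "ari": "ARI",
    "ms_waist": "Waist",
    "ms_bp": "BP",
    "ms_tg": "TG",
    "ms_hdl": "HDL",
    "ms_glu": "Glu",
    "ms_score": "MS score",
    "ms": "MS",
}


def correlation_table(
    df: pd.DataFrame, columns: dict[str, str] | None = None
) -> pd.DataFrame:
    """Pearson correlation matrix of ARI components, ARI, MS components,
    MS score and MS (point-biserial/phi arise automatically for 0/1
    columns).  Zero-variance columns yield NaN rows/columns and a
    warning."""
    columns = columns or CORRELATION_COLUMNS
    present = {c: lbl for c, lbl in columns.items() if c in df.columns}
    sub = df[list(present)].astype(float)
    degenerate = [c for c in sub.columns if np.isclose(sub[c].std(ddof=0), 0.0)]
    if degenerate:
        warnings.warn(f"zero-variance columns in correlation table: {degenerate}")
    corr = sub.corr(method="pearson")
    for c in degenerate:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    corr.index = [present[c] for c in corr.index]
    corr.columns = [present[c] for c in corr.columns]
    return corr


def results_table(fits: list[ModelFitResult]) -> pd.DataFrame:
    """Long-format per-model, per-predictor report (Table-4-style CSV)."""
    rows = []
    for f in fits:
        pred_rows = [p for p in f.predictors if p not in ALWAYS_INCLUDED] or [None]
        for p in pred_rows:
            row = dict(
                model=f.name, delta_aic=f.delta_i, r2=f.r2, concordance=f.c,
                aic=f.aic, n=f.n, n_events=f.n_events,
                significantly_worse=f.significantly_worse,
                predictor=p if p is not None else "",
            )
            if p is not None:
                hr, lo, hi = f.hazard_ratio(p)
                row.update(hr=hr, hr_ci_low=lo, hr_ci_high=hi)
            else:
                row.update(hr=np.nan, hr_ci_low=np.nan, hr_ci_high=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
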