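"""Synthetic NHANES-like cohorts with known ground truth.

The generator emulates the statistical structure of the study cohort
this package analyzes, so that every pipeline stage can be exercised
and validated without any data download:

* sex- and age-dependent anthropometrics in which the four index Z
  scores (height, BMI, ABSI, HI) are mutually independent *by
  construction*: waist and hip circumference are derived by inverting
  the ABSI and HI definitions from independently drawn target Z scores;
* metabolic syndrome inputs driven by a correlated latent Gaussian
  (waist severity enters as the first latent dimension; the default
  latent correlation 0.33 puts the *observed* pairwise correlations of
  the 0/1 component scores near 0.2, since dichotomization attenuates
  the latent value), with marginal scales calibrated so the realized
  MS prevalence hits a target of 28%;
* survival on the age timescale from a Gompertz baseline hazard
  multiplied by exp(true log hazard), where the true log hazard is a
  configurable function of the index Z scores plus MS-component,
  MS-occurrence, sex and race effects; administrative censoring after
  20 years of follow-up;
* Gamma-distributed sampling weights (mean 1) and a 50/50
  training/evaluation subsample flag, mirroring the use of a disjoint
  subsample to fit the per-index hazard curves.

Identical configuration and seed reproduce the cohort exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import metsyn

# fixed internal stream for threshold calibration (a numerical
# procedure, deliberately independent of the cohort seed)
_CALIBRATION_SEED = 719_393
_CALIBRATION_N = 20_000


class CalibrationError(RuntimeError):
    """Raised when the MS prevalence target cannot be reached."""


#: Per-sex anthropometric location/scale parameters.  ``*_age`` entries are
#: linear drifts per year of age centered at 50 y.
DEFAULT_ANTHRO: dict[str, dict[str, float]] = {
    "male": dict(
        height_mean=176.0, height_sd=7.2, height_age=-0.04,
        bmi_mean=26.5, bmi_sd=4.3, bmi_age=0.02,
        absi_mean=0.0800, absi_sd=0.0042, absi_age=2.0e-5,
        hi_mean=96.0, hi_sd=4.5, hi_age=0.0,
    ),
    "female": dict(
        height_mean=162.5, height_sd=6.8, height_age=-0.05,
        bmi_mean=27.0, bmi_sd=5.8, bmi_age=0.03,
        absi_mean=0.0775, absi_sd=0.0048, absi_age=2.2e-5,
        hi_mean=104.0, hi_sd=5.5, hi_age=0.0,
    ),
}

#: Default linear log-hazard slopes per unit Z score.  The magnitudes are
#: chosen so the contributions of BMI, ABSI, HI and height to the summed
#: anthropometric risk mirror their observed relative importance (BMI
#: largest, height negligible) and give an ARI standard deviation near
#: 0.23.
DEFAULT_INDEX_SLOPES: dict[str, float] = {
    "height": 0.0, "bmi": 0.18, "absi": 0.14, "hi": 0.075,
}

#: Default true MS-component log hazard ratios (hazard ratios ~0.95,
#: 1.26, 0.93, 1.23, 1.25 for Waist, BP, TG, HDL, Glu).
DEFAULT_MS_COMPONENT_LOG_HR: dict[str, float] = {
    "ms_waist": math.log(0.95),
    "ms_bp": math.log(1.26),
    "ms_tg": math.log(0.93),
    "ms_hdl": math.log(1.23),
    "ms_glu": math.log(1.25),
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator."""

    n: int = 5221
    seed: int = 0
    female_frac: float = 0.52
    age_range: tuple[float, float] = (18.0, 85.0)
    race_black_frac: float = 0.12
    training_frac: float = 0.5
    anthro: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_ANTHRO.items()}
    )
    # true hazard specification -------------------------------------------
    index_slopes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEX_SLOPES)
    )
    #: optional per-index callables z -> log hazard, overriding the slopes
    index_effect_fns: Mapping[str, Callable[[np.ndarray], np.ndarray]] | None = None
    ms_component_log_hr: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MS_COMPONENT_LOG_HR)
    )
    ms_log_hr: float = 0.0  # extra effect of MS occurrence itself
    male_log_hr: float = 0.45
    race_black_log_hr: float = 0.20
    # baseline hazard (Gompertz on the age timescale) ----------------------
    gompertz_lambda0: float = 0.0023  # hazard/yr at the reference age
    gompertz_slope: float = 0.085     # log-hazard increase per year of age
    ref_age: float = 50.0
    censor_years: float = 20.0
    # MS input structure ---------------------------------------------------
    #: latent-Gaussian pairwise correlation of MS component severities;
    #: 0.33 here yields observed 0/1-score correlations near 0.2
    ms_latent_corr: float = 0.33
    ms_prevalence_target: float = 0.28
    #: cached calibration shift; computed on first use
    calibrated_shift: float | None = None
    # weights --------------------------------------------------------------
    weight_gamma_shape: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ms_prevalence_target < 1.0):
            raise ValueError("ms_prevalence_target must be in (0, 1)")
        if self.censor_years <= 0:
            raise ValueError("censor_years must be positive")
        # latent correlation matrix must be positive definite
        r = self.ms_latent_corr
        mat = np.full((5, 5), r)
        np.fill_diagonal(mat, 1.0)
        if np.linalg.eigvalsh(mat).min() <= 0:
            raise ValueError(f"latent correlation {r} is not positive definite")


def index_effect(config: GeneratorConfig, name: str, z: np.ndarray) -> np.ndarray:
    """True log-hazard contribution of one index at Z score ``z``.

    Linear effects are centered so that E[exp(effect)] = 1 under a
    standard-normal Z (subtracting slope^2/2); callable overrides are
    used exactly as supplied.
    """
    if config.index_effect_fns and name in config.index_effect_fns:
        return np.asarray(config.index_effect_fns[name](np.asarray(z, float)))
    b = config.index_slopes.get(name, 0.0)
    return b * np.asarray(z, float) - b**2 / 2.0


def _anthro_values(params, age, z):
    """(height_cm, bmi, absi_target, hi_target) for one sex block."""
    da = age - 50.0
    height = params["height_mean"] + params["height_age"] * da + params["height_sd"] * z[0]
    bmi = params["bmi_mean"] + params["bmi_age"] * da + params["bmi_sd"] * z[1]
    absi = params["absi_mean"] + params["absi_age"] * da + params["absi_sd"] * z[2]
    hi = params["hi_mean"] + params["hi_age"] * da + params["hi_sd"] * z[3]
    return height, bmi, absi, hi


def _ms_inputs_from_latents(sex, age, shift, latents, unif_bp_meds, unif_pills, dbp_noise):
    """Map latent severities to MS measurement columns.

    All maps are monotone in ``shift``, which the calibration step tunes
    to hit the MS prevalence target.
    """
    s_bp = latents[:, 0] + shift
    s_tg = latents[:, 1] + shift
    s_hdl = latents[:, 2] + shift
    s_glu = latents[:, 3] + shift
    da = age - 50.0
    male = sex == "male"

    sbp = 122.0 * np.exp(0.095 * s_bp + 0.004 * da)
    dbp = 74.0 + 0.22 * (sbp - 122.0) + 6.0 * dbp_noise
    p_bp_meds = _sigmoid(-2.6 + 0.9 * s_bp + 0.035 * da)
    bp_meds = (unif_bp_meds < p_bp_meds).astype(int)

    tg = 118.0 * np.exp(0.48 * s_tg)
    hdl = np.where(male, 46.0, 56.0) * np.exp(-0.22 * s_hdl)
    glu = 94.0 * np.exp(0.085 * s_glu + 0.0022 * da)
    p_pills = _sigmoid(-3.8 + 1.1 * s_glu + 0.03 * da)
    diabetes_pills = (unif_pills < p_pills).astype(int)

    return pd.DataFrame(
        dict(
            sbp_mmhg=sbp, dbp_mmhg=dbp, bp_meds=bp_meds,
            tg_mg_dl=tg, hdl_mg_dl=hdl, glu_mg_dl=glu,
            diabetes_pills=diabetes_pills,
        )
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_structural(config: GeneratorConfig, rng: np.random.Generator, n: int):
    """Draw everything up to (but not including) the calibration shift."""
    sex = np.where(rng.uniform(size=n) < config.female_frac, "female", "male")
    age = rng.uniform(*config.age_range, size=n)
    race_black = (rng.uniform(size=n) < config.race_black_frac).astype(int)

    # independent target Z scores, truncated at +-4 SD (values beyond are
    # anthropometrically implausible and would be flagged as data errors)
    z = np.clip(rng.standard_normal((4, n)), -4.0, 4.0)
    height = np.empty(n); bmi = np.empty(n); absi = np.empty(n); hi = np.empty(n)
    for s in ("male", "female"):
        m = sex == s
        height[m], bmi[m], absi[m], hi[m] = _anthro_values(
            config.anthro[s], age[m], z[:, m]
        )
    weight = bmi * (height / 100.0) ** 2
    # invert the index definitions: WC from the ABSI target, HC from HI
    waist = 100.0 * absi * (height / 100.0) ** (-5.0 / 6.0) * weight ** (2.0 / 3.0)
    hip = hi / ((height / 166.0) ** 0.310 * (weight / 73.0) ** (-0.482))

    # waist severity = standardized log WC within sex; it seeds the
    # correlated latent structure of the MS components
    u_waist = np.empty(n)
    logwc = np.log(waist)
    for s in ("male", "female"):
        m = sex == s
        u_waist[m] = (logwc[m] - logwc[m].mean()) / logwc[m].std()

    r = config.ms_latent_corr
    cov = np.full((4, 4), r) - r**2
    np.fill_diagonal(cov, 1.0 - r**2)
    chol = np.linalg.cholesky(cov)
    latents = r * u_waist[:, None] + rng.standard_normal((n, 4)) @ chol.T

    aux = dict(
        unif_bp_meds=rng.uniform(size=n),
        unif_pills=rng.uniform(size=n),
        dbp_noise=rng.standard_normal(n),
    )
    return dict(
        sex=sex, age=age, race_black=race_black, z=z,
        height=height, weight=weight, waist=waist, hip=hip,
        latents=latents, aux=aux,
    )


def _ms_prevalence(structural, shift) -> float:
    ms_df = _ms_inputs_from_latents(
        structural["sex"], structural["age"], shift,
        structural["latents"], **structural["aux"],
    )
    ms_df["sex"] = structural["sex"]
    ms_df["waist_cm"] = structural["waist"]
    scored = metsyn.score_dataframe(ms_df)
    return float(scored["ms"].mean())


def calibrate(config: GeneratorConfig) -> GeneratorConfig:
    """Return a config whose marginal-scale shift hits the MS prevalence
    target (bisection on a fixed large calibration sample).

    The calibration draw uses a fixed internal stream so the shift
    depends only on the configuration, not on the cohort seed.
    """
    if config.calibrated_shift is not None:
        return config
    rng = np.random.default_rng(np.random.SeedSequence([_CALIBRATION_SEED]))
    structural = _draw_structural(config, rng, _CALIBRATION_N)
    lo, hi = -3.0, 3.0
    p_lo, p_hi = _ms_prevalence(structural, lo), _ms_prevalence(structural, hi)
    target = config.ms_prevalence_target
    if not (p_lo <= target <= p_hi):
        raise CalibrationError(
            f"MS prevalence target {target} outside achievable range "
            f"[{p_lo:.3f}, {p_hi:.3f}]"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _ms_prevalence(structural, mid) < target:
            lo = mid
        else:
            hi = mid
    return replace(config, calibrated_shift=0.5 * (lo + hi))


def true_log_hazard_parts(
    config: GeneratorConfig,
    z: np.ndarray,
    scored: pd.DataFrame,
    sex: np.ndarray,
    race_black: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(anthropometric part, full log hazard) used by the generator."""
    names = ("height", "bmi", "absi", "hi")
    eta_anthro = np.zeros(z.shape[1])
    for i, name in enumerate(names):
        eta_anthro = eta_anthro + index_effect(config, name, z[i])
    eta = eta_anthro.copy()
    for comp, b in config.ms_component_log_hr.items():
        eta = eta + b * scored[comp].to_numpy(float)
    eta = eta + config.ms_log_hr * scored["ms"].to_numpy(float)
    eta = eta + config.male_log_hr * (sex == "male")
    eta = eta + config.race_black_log_hr * race_black
    return eta_anthro, eta


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one cohort; reproducible given (config, seed).

    Besides the cohort schema columns, the frame carries generator-only
    ground-truth columns ``z_true_*``, ``true_anthro_log_hazard`` and
    ``true_log_hazard`` for oracle comparisons.
    """
    config = calibrate(config)
    rng = np.random.default_rng(config.seed)
    n = config.n
    st = _draw_structural(config, rng, n)

    ms_df = _ms_inputs_from_latents(
        st["sex"], st["age"], config.calibrated_shift, st["latents"], **st["aux"]
    )
    df = pd.DataFrame(
        dict(
            id=np.arange(1, n + 1),
            age=st["age"],
            sex=st["sex"],
            race_black=st["race_black"],
            height_cm=st["height"],
            weight_kg=st["weight"],
            waist_cm=st["waist"],
            hip_cm=st["hip"],
        )
    )
    df = pd.concat([df, ms_df], axis=1)
    scored = metsyn.score_dataframe(df)

    eta_anthro, eta = true_log_hazard_parts(
        config, st["z"], scored, st["sex"], st["race_black"]
    )

    # survival: Gompertz baseline on the age timescale, left-truncated
    # entry at baseline age, administrative censoring after censor_years
    lam0, k, a_ref = config.gompertz_lambda0, config.gompertz_slope, config.ref_age
    u = rng.uniform(size=n)
    cum0_entry = lam0 / k * np.exp(k * (st["age"] - a_ref))
    cum_at_death = cum0_entry - np.log(u) / np.exp(eta)
    death_age = a_ref + np.log(k * cum_at_death / lam0) / k
    time_to_death = death_age - st["age"]
    died = (time_to_death < config.censor_years).astype(int)
    followup = np.minimum(time_to_death, config.censor_years)

    df["followup_years"] = followup
    df["died"] = died
    df["sample_weight"] = rng.gamma(
        config.weight_gamma_shape, 1.0 / config.weight_gamma_shape, size=n
    )
    df["training"] = (rng.uniform(size=n) < config.training_frac).astype(int)

    for i, name in enumerate(("height", "bmi", "absi", "hi")):
        df[f"z_true_{name}"] = st["z"][i]
    df["true_anthro_log_hazard"] = eta_anthro
    df["true_log_hazard"] = eta
    return df


def true_hazard(df: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Recompute the exact log hazard the generator used for ``df``.

    Only works on generator output (requires the ``z_true_*`` ground
    truth columns); raises on other records.
    """
    z_cols = [f"z_true_{n}" for n in ("height", "bmi", "absi", "hi")]
    missing = [c for c in z_cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"not a generator cohort: missing ground-truth columns {missing}"
        )
    scored = metsyn.score_dataframe(df)
    z = df[z_cols].to_numpy(float).T
    _, eta = true_log_hazard_parts(
        config, z, scored, df["sex"].to_numpy(), df["race_black"].to_numpy(float)
    )
    return eta
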