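# Methods

## Model and procedure

The package estimates how anthropometric risk and the metabolic
syndrome (MS) jointly predict all-cause mortality in a survey cohort.

**Indices.** BMI, ABSI and HI are computed from height, weight, waist
and hip circumference (cm/kg ingest; ABSI uses meters internally so
its magnitude is the customary ~0.08).  The HI exponents (0.310,
−0.482) and scaling constants (166 cm, 73 kg) are fixed by definition
and never re-fitted.  Raw values outside configurable plausibility
bounds are flagged, not dropped; exclusion policy lives in the cohort
reader, which applies the inclusion rules (adults, nonpregnant,
complete anthropometrics, complete MS inputs, mortality linkage) in a
fixed order with per-rule exclusion counts.

**Standardization.** Each index is converted to a Z score against
age–sex stratum means and SDs.  Strata are 5-year age bins with 18–19
first and 80+ pooled (14 bins per sex); cells under 25 subjects merge
into the adjacent younger bin.  Reference moments are unweighted by
default (survey-weighted optionally); the table round-trips through
CSV so published reference values can be substituted.  Ages outside
the table clamp to the boundary bin with a logged warning, and |z| > 6
is flagged.

**Hazard curves and ARI.** For each index, log mortality hazard as a
function of the Z score is estimated by Cox regression with a cubic
B-spline basis (boundary knots at ±4, 4 interior knots at training
quantiles, first basis column dropped for identifiability) and an L2
roughness penalty.  Attained age is the timescale: subjects enter the
risk set at baseline age and exit at death or censoring age, which
makes age adjustment implicit and exact.  The penalty weight is chosen
from a small grid by AIC = −2·loglik + 2·edf, where the unpenalized
Efron partial likelihood is evaluated by an in-house routine (verified
against the fitting library to 1e−10) and edf is the effective number
of parameters of the penalized fit, p − nλ·tr(I_pen⁻¹).  Each curve is
centered by subtracting log of the training-sample (weighted) mean of
exp(h), so exp(h) averages exactly 1: h = 0 is population-average
risk.  Curves are fitted on a disjoint training subsample (flag
column) and applied to the evaluation subsample, preventing leakage;
training fits are unweighted by default (configurable).  ARI is the
exact sum of the four evaluated components.  Evaluation outside
z ∈ [−4, 4] clamps with a warning.  Curves serialize to a dense z-grid
CSV (−4…4, step 0.01) plus a JSON sidecar that reconstructs them
exactly.

**MS scoring.** ATP III criteria, read literally: "at or above" is
inclusive (SBP ≥ 130, DBP ≥ 85, TG ≥ 150, glucose ≥ 110), "above" and
"under" are strict (waist > 102/88 cm, HDL < 40/50 mg/dL), plus the
medication clauses.  The score is the 0–5 sum, MS is score ≥ 3, and
MSx (0–4) omits waist for use alongside ARI.  Missing inputs are never
imputed: the scalar API raises naming the unscoreable components, the
frame API propagates missingness for complete-case analysis
downstream.  One deliberate reading: a subject on diabetes pills with
missing fasting glucose still scores the glucose point, since the
medication clause alone satisfies the criterion.

**Model comparison.** The ten-model roster (Base; ARI; MS; MS score;
ARI + MS; ARI + MS score; ARI + MSx score; MS components; ARI + MS
components; ARI + MSx components) always includes sex and black race.
Fits use Efron tie handling, survey weights as case weights normalized
to sum to the sample size (so AIC is scale-free), and Wald CIs from
robust (sandwich) variance whenever weights are in use.  Δᵢ = AICᵢ −
min AIC; Δᵢ > 6 flags a model as significantly worse, ties order
deterministically by name, and comparing fits from different cohorts
or weightings is an error.  R² is the Royston–Sauerbrei D-based
explained variation: the prognostic index is rank-transformed to
rankits scaled by κ = √(8/π); its Cox coefficient D gives
R² = (D²/κ²)/(π²/6 + D²/κ²).  (The rank transform is unweighted; the
D regression itself is weighted.)  Concordance is a weighted Harrell C
under the age timescale — a pair is comparable when one subject dies
at an age the other is under observation; risk ties count 1/2, so the
no-skill value is exactly 0.5, and pairs weight by the product of the
subjects' weights.  The correlation table reports Pearson correlations
of the four hazard components, ARI, the five 0/1 MS components, MS
score and MS (point-biserial/phi automatically for binaries), with
zero-variance columns reported as undefined.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated:

* **Population**: 52% female, ages uniform on 18–85, 12% black race
  indicator, n defaulting to 5221 (the complete-measurement cohort
  size).
* **Anthropometrics**: per-sex height/BMI/ABSI/HI means, SDs and mild
  linear age drifts typical of survey adults.  Four independent
  standard-normal Z scores (truncated at ±4; beyond that is
  anthropometrically implausible) generate the index values; waist and
  hip circumference are then obtained by *inverting* the ABSI and HI
  definitions, so the index Z scores are mutually independent by
  construction — realized |r| < 0.05 at n = 20,000.
* **MS inputs**: waist severity (standardized log WC within sex) is
  the first dimension of an equicorrelated latent Gaussian; BP, TG,
  HDL and glucose severities are drawn conditionally.  The latent
  correlation defaults to 0.33, which yields observed correlations
  among the dichotomized component scores near 0.2 (dichotomization
  attenuates the latent value).  Latents map to measurements through
  lognormal/linear marginals with age trends on blood pressure and
  glucose, plus Bernoulli medication flags monotone in severity.  A
  single scale shift on the four non-waist severities is calibrated by
  bisection (fixed internal stream, 20,000 draws, independent of the
  cohort seed) so realized MS prevalence hits the 28% target;
  infeasible targets raise.
* **Survival**: Gompertz baseline on the age timescale (0.0023/yr at
  age 50, slope 0.085/yr — ~30% deaths over the 20-year administrative
  censoring horizon) times exp(true log hazard).  The true log hazard
  sums linear index effects (slopes 0, 0.18, 0.14, 0.075 for height,
  BMI, ABSI, HI — centered by β²/2 so E[exp] = 1 — giving
  anthropometric log-hazard SD ≈ 0.24, the observed ARI dispersion,
  and mirroring the observed ordering BMI > ABSI > HI ≫ height),
  per-component MS log hazard ratios defaulting to (0.95, 1.26, 0.93,
  1.23, 1.25) for waist/BP/TG/HDL/glucose, an optional MS-occurrence
  effect, and sex (HR e^0.45) and race (e^0.20) effects.  Index
  effects can be replaced by arbitrary callables (used for U-shape
  recovery tests).  Ground-truth columns (`z_true_*`,
  `true_log_hazard`) ride along for oracle comparisons.
* **Weights**: Gamma(4, 1/4), mean 1 — they exercise weighted fitting
  without replicating cluster-sample design.  Training/evaluation
  split is a 50/50 flag.

What the generator does **not** emulate: cluster sampling and
oversampling (weights are independent of covariates, so weighted and
unweighted estimands coincide), measurement error, non-proportional or
time-varying effects, competing risks, and item nonresponse.  Passing
tests therefore demonstrate correctness of the machinery under the
stated structure, not robustness to those real-data features.

## Numerical choices

* Spline: cubic, 4 interior knots (~7 free coefficients before
  penalization), penalty grid {0.01, 0.03, 0.1, 0.3} (heavier ridge
  penalties bias the curve amplitude toward zero); degenerate quantile
  knots are spread by 1e−9 to stay strictly increasing.
* Centering anchor holds to 1e−6 by construction and is asserted.
* Cox minimum events: 50 per fit (curves and models).
* Collinearity: duplicate predictors, zero-variance predictors, and
  pairwise |r| > 1 − 1e−10 are rejected naming the offending pair.
* AIC ties: Δᵢ = 0 for every tied model; result ordering breaks ties
  by model name.
* Concordance ties (risk or age): 1/2 credit; two deaths at the same
  age are incomparable.
* Weighted SDs use the frequency-weight analogue of ddof = 1, which
  reduces to the plain sample SD under equal weights.
* Likelihood evaluation shifts the linear predictor by its maximum
  before exponentiation (shift-invariant, overflow-safe).

## Validation problem sizes

Curve-shape recovery (linear within ±0.1 on z ∈ [−2, 2]; null flat;
U-shape argmin within ±0.3) runs at n = 20,000.  Confidence-interval
coverage of generating hazard ratios (MS occurrence 1.37; the five
component HRs) uses 200 replicates of n = 5,000 with ≥ 90% nominal
coverage.  Model-selection recovery (the generating roster entry
attains Δᵢ = 0) uses five full-pipeline replicates at n = 5,000.
Structural fidelity (prevalence, correlation structure, ARI
dispersion) is checked on one n = 20,000 run.  These sizes are the
package's validation design; all are configurable.

## Known limitations

* The explained-variation measure is one defensible reading of a
  generically named "R²"; O'Quigley's ρ² or similar could be swapped
  in via the same interface.
* Penalty selection by edf-based AIC depends on the fitting library's
  penalty scaling (n·λ·‖β‖²/2 on std-normalized covariates); the
  in-house likelihood cross-check pins this down, but a different
  backend would need the edf formula revisited.
* The reference table is piecewise-constant in age; no smooth
  (LMS-type) standardization.
* Whether the original analysis weighted the curve-fitting subsample
  or read the waist cut as strict is not documented; both choices are
  explicit switches here (default: unweighted training, strict cut).
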