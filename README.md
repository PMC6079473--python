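# anthrorisk

Anthropometric risk and the metabolic syndrome as joint predictors of
all-cause mortality, as a tested, reusable Python pipeline.

## The problem

Body mass index correlates ~0.9 with waist circumference, so the two
mostly repeat each other as risk factors.  A complementary set of
indices fixes this: height H, BMI, **ABSI** (a body shape index, waist
normalized for height and weight) and **HI** (hip index, hip
circumference normalized the same way) are statistically
near-independent,

```
BMI  = W · H⁻²
ABSI = WC · H^(5/6) · W^(−2/3)          (WC, H in m; W in kg)
HI   = HC · (H/166 cm)^0.310 · (W/73 kg)^(−0.482)
```

Each index is converted to an age- and sex-specific Z score, and a
penalized-spline Cox regression (attained age as timescale, delayed
entry at baseline age) estimates the log mortality-hazard ratio h(z)
attributable to each index alone, on a training subsample.  Their sum
is the **anthropometric risk index**

```
ARI = hH(zH) + hBMI(zBMI) + hABSI(zABSI) + hHI(zHI),
```

with exp(ARI) the subject's hazard relative to the population average
(curves are centered so the training-sample mean of exp(h) is 1).

The **metabolic syndrome** (MS) is scored per ATP III: one point each
for elevated waist, blood pressure, triglycerides, low HDL and
elevated fasting glucose; 3+ points define MS.  The package fits the
ten-model Cox roster (Base, ARI, MS, MS score, combinations, and the
MSx variants that drop the waist component), all with sex and black
race as covariates, survey weights with robust variance, and reports
hazard ratios with 95% CIs, AIC differences Δᵢ (Δᵢ > 6 = significantly
worse), Royston–Sauerbrei explained variation R², and a weighted
Harrell concordance C, plus the full correlation table of ARI and MS
components.

Because the underlying survey data require a download, the package
ships a synthetic cohort generator that reproduces the structure the
analysis relies on — independent index Z scores by construction,
correlated MS components calibrated to 28% prevalence, ~30% mortality
over 20 years — with known ground-truth hazards, so every stage is
validated end to end.

## Worked example

```python
from anthrorisk import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(simulate_n=5221, seed=1))
for f in res.model_results[:3]:
    print(f"{f.name:<22} dAIC={f.delta_i:5.1f}  R2={f.r2:.4f}  C={f.c:.3f}")
```

prints

```
ARI + MSx components     dAIC=  0.0  R2=0.0759  C=0.599
ARI + MS components      dAIC=  0.8  R2=0.0766  C=0.600
ARI + MS score           dAIC=  2.4  R2=0.0651  C=0.595
```

ARI combined with the non-waist MS components wins the AIC comparison:
anthropometrics and the clinical/laboratory MS criteria carry
complementary mortality information.  In the same run the best model's
ARI hazard ratio is 2.04 (1.40–2.95) per unit ARI and the MS blood
pressure component's is 1.38 (1.15–1.65); the evaluation-half MS
prevalence is 29.7% and the ARI standard deviation 0.21.

The `examples/` scripts walk through each capability (indices, MS
scoring, cohort generation, hazard curves and ARI, model comparison);
each prints what it computes and what the numbers mean.  A shell entry
point exists for whole runs:

```sh
python -m anthrorisk.pipeline --simulate 5221 --seed 1 --outdir out/
```

which writes the reference table, hazard-curve grids (CSV + JSON
metadata), correlation and model-comparison CSVs, and a run log with
seed, config hash and software versions.  Real survey extracts enter
through `ColumnMap` / `read_external_cohort` (a documented
column-mapping YAML; see `anthrorisk/cohort.py` for the canonical
schema and the fixed-order cohort filters with per-rule exclusion
counts).

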