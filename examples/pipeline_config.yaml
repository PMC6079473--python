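# Example pipeline configuration for `python -m anthrorisk.pipeline --config ...`
# Every key is optional; shown values are the defaults unless noted.

# Either read a cohort CSV in the canonical schema ...
# input_path: cohort.csv
# ... or simulate one (set exactly one of the two):
simulate_n: 5221

seed: 1
outdir: pipeline_out

# subset of the model roster to fit (default: all ten)
# models: [Base, ARI, MS, "ARI + MSx components"]

weight_col: sample_weight     # null -> unweighted fits
training_col: training        # 0/1 column marking the curve-fitting subsample
age_bin_width: 5.0            # reference-table age strata (years)
min_cell_n: 25                # merge smaller reference cells

# substitute a published reference table instead of building one:
# reference_table_path: reference_table.csv

spline:
  n_interior_knots: 4
  degree: 3
  penalizer_grid: [0.01, 0.03, 0.1, 0.3]

# generator overrides (only used when simulating); keys mirror GeneratorConfig
# generator:
#   ms_prevalence_target: 0.28
#   censor_years: 20.0
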