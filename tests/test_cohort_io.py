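import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

import anthrorisk as ar
from anthrorisk.cohort import (CohortReadError, ColumnMap, apply_filters,
                               read_cohort, read_external_cohort,
                               write_cohort)
from anthrorisk.pipeline import PipelineConfig, PipelineError, run_pipeline


@pytest.fixture(scope="module")
def cohort_file(tmp_path_factory, default_cohort):
    p = tmp_path_factory.mktemp("io") / "cohort.csv"
    write_cohort(default_cohort, p)
    return p


def test_round_trip_identity(cohort_file, tmp_path, default_cohort):
    df1, rep1 = read_cohort(cohort_file)
    p2 = tmp_path / "again.csv"
    write_cohort(df1, p2)
    df2, rep2 = read_cohort(p2)
    pd.testing.assert_frame_equal(df1.reset_index(drop=True),
                                  df2.reset_index(drop=True))
    assert rep1.as_dict() == rep2.as_dict()
    assert rep1.retained == len(default_cohort)  # generator output is complete


def test_filter_counts_and_order(default_cohort):
    df = default_cohort.head(10).copy().reset_index(drop=True)
    df.loc[0, "age"] = 15.0
    df.loc[1, "age"] = 17.9
    df.loc[2, "waist_cm"] = np.nan
    kept, report = apply_filters(df)
    assert report.under_18 == 2
    assert report.missing_anthro == 1
    assert report.retained == 7
    assert len(kept) == 7
    report.check()


def test_filters_count_each_row_once(default_cohort):
    # a row failing two rules is charged to the first rule in order
    df = default_cohort.head(5).copy().reset_index(drop=True)
    df.loc[0, "age"] = 12.0
    df.loc[0, "waist_cm"] = np.nan
    _, report = apply_filters(df)
    assert report.under_18 == 1 and report.missing_anthro == 0


def test_pregnancy_and_mortality_filters(default_cohort):
    df = default_cohort.head(8).copy().reset_index(drop=True)
    df["pregnant"] = 0
    df.loc[1, "pregnant"] = 1
    df.loc[2, "followup_years"] = np.nan
    df.loc[3, "tg_mg_dl"] = np.nan
    _, report = apply_filters(df)
    assert report.pregnant == 1
    assert report.missing_mortality == 1
    assert report.missing_ms_inputs == 1
    assert report.retained == 5


def test_empty_file_rejected(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("")
    with pytest.raises(CohortReadError, match="empty"):
        read_cohort(p)


def test_malformed_value_reports_line(tmp_path, default_cohort):
    p = tmp_path / "bad.csv"
    df = default_cohort.head(4).copy()
    df = df.astype({"tg_mg_dl": object})
    df.iloc[2, df.columns.get_loc("tg_mg_dl")] = "oops"
    df.to_csv(p, index=False)
    with pytest.raises(CohortReadError, match="tg_mg_dl.*4"):
        read_cohort(p)


def test_missing_required_column_rejected(tmp_path, default_cohort):
    p = tmp_path / "short.csv"
    default_cohort.drop(columns=["hip_cm"]).to_csv(p, index=False)
    with pytest.raises(CohortReadError, match="hip_cm"):
        read_cohort(p)


def test_unknown_columns_preserved(tmp_path, default_cohort):
    p = tmp_path / "extra.csv"
    df = default_cohort.head(20).copy()
    df["mystery"] = 7
    df.to_csv(p, index=False)
    out, _ = read_cohort(p)
    assert "mystery" in out.columns


def test_column_map_adapter(tmp_path, default_cohort):
    """An externally named extract maps onto the canonical schema."""
    src = default_cohort.head(200).copy()
    renames = {
        "age": "HSAGEIR", "sex": "HSSEX", "race_black": "DMARACER",
        "height_cm": "BMPHT", "weight_kg": "BMPWT", "waist_cm": "BMPWAIST",
        "hip_cm": "BMPBUTTO", "sbp_mmhg": "PEPMNK1R", "dbp_mmhg": "PEPMNK5R",
        "bp_meds": "HAE5A", "tg_mg_dl": "TGP", "hdl_mg_dl": "HDP",
        "glu_mg_dl": "GHP", "diabetes_pills": "HAD6",
        "followup_years": "PERMTH_Y", "died": "MORTSTAT",
        "sample_weight": "WTPFSD6", "training": "SDPPHASE",
    }
    ext = src.rename(columns=renames)
    ext["HSSEX"] = np.where(src["sex"] == "male", 1, 2)
    ext.loc[ext.index[0], "TGP"] = 8888  # sentinel for missing
    p = tmp_path / "external.csv"
    ext.to_csv(p, index=False)

    cmap = ColumnMap(
        columns={v: k for k, v in renames.items()},
        sex_codes={1: "male", 2: "female"},
        missing_values=[8888],
    )
    out, report = read_external_cohort(p, cmap)
    assert report.missing_ms_inputs == 1
    assert report.retained == 199
    assert set(out["sex"].unique()) <= {"male", "female"}
    pd.testing.assert_series_equal(
        out["waist_cm"].reset_index(drop=True),
        src["waist_cm"].iloc[1:].reset_index(drop=True),
        check_names=False,
    )


def test_column_map_yaml_round_trip(tmp_path):
    yml = tmp_path / "map.yaml"
    yml.write_text(
        "columns:\n  A: age\n  S: sex\nsex_codes:\n  1: male\n  2: female\n"
        "missing_values: [9999]\n"
    )
    cmap = ColumnMap.from_yaml(yml)
    df = pd.DataFrame({"A": [44.0, 9999], "S": [1, 2]})
    out = cmap.apply(df)
    assert list(out.columns) == ["age", "sex"]
    assert out["sex"].tolist() == ["male", "female"]
    assert np.isnan(out["age"].iloc[1])


@pytest.fixture(scope="module")
def result(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe")
    cfg = PipelineConfig(simulate_n=1500, seed=7, outdir=str(out / "run1"))
    return run_pipeline(cfg), out, cfg


class TestPipeline:
    def test_all_roster_models_fitted(self, result):
        res, _, _ = result
        assert len(res.model_results) == 10
        assert set(f.name for f in res.model_results) == set(ar.MODEL_SPECS)
        # exactly one best model
        assert sum(f.delta_i == 0.0 for f in res.model_results) >= 1
        assert min(f.delta_i for f in res.model_results) == 0.0

    def test_outputs_written(self, result):
        res, out, cfg = result
        run1 = out / "run1"
        for f in ("reference_table.csv", "correlations.csv",
                  "model_comparison.csv", "run_log.json", "curve_bmi.csv",
                  "curve_bmi.json"):
            assert (run1 / f).exists()
        log = json.loads((run1 / "run_log.json").read_text())
        assert log["seed"] == 7
        assert "lifelines" in log["versions"]
        assert log["filter_report"]["retained"] == 1500

    def test_rerun_is_byte_identical(self, result, tmp_path):
        res, out, cfg = result
        cfg2 = dataclasses.replace(cfg, outdir=str(tmp_path / "run2"))
        run_pipeline(cfg2)
        a = (out / "run1" / "model_comparison.csv").read_bytes()
        b = (tmp_path / "run2" / "model_comparison.csv").read_bytes()
        assert a == b

    def test_training_and_evaluation_are_disjoint(self, result):
        res, _, _ = result
        assert (res.evaluation["training"] == 0).all()
        assert len(res.evaluation) + res.run_log["n_training"] == len(res.cohort)

    def test_missing_training_column_is_instructive(self, tmp_path,
                                                    default_cohort):
        p = tmp_path / "no_train.csv"
        write_cohort(default_cohort.drop(columns=["training"]), p)
        with pytest.raises(PipelineError, match="training"):
            run_pipeline(PipelineConfig(input_path=str(p)))

    def test_config_needs_some_input(self):
        with pytest.raises(PipelineError, match="input_path or simulate_n"):
            run_pipeline(PipelineConfig())

    def test_yaml_config_round_trip(self, tmp_path):
        yml = tmp_path / "cfg.yaml"
        yml.write_text(
            "simulate_n: 1234\nseed: 3\nmodels: [Base, ARI]\n"
            "spline:\n  n_interior_knots: 3\n  penalizer_grid: [0.1]\n"
            "generator:\n  ms_prevalence_target: 0.25\n"
        )
        cfg = PipelineConfig.from_yaml(yml)
        assert cfg.simulate_n == 1234 and cfg.seed == 3
        assert cfg.models == ["Base", "ARI"]
        assert cfg.spline.n_interior_knots == 3
        assert tuple(cfg.spline.penalizer_grid) == (0.1,)
        assert cfg.generator.ms_prevalence_target == 0.25
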