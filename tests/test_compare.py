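import numpy as np
import pandas as pd
import pytest

import anthrorisk as ar
from anthrorisk.compare import (CohortMismatchError, CollinearityError,
                                ModelFitResult, aic_compare,
                                concordance_index, correlation_table,
                                fit_cox, royston_r2)


def _stub(name, aic, sig=(100, 40, 1.0, 100.0)):
    return ModelFitResult(
        name=name, predictors=[], summary=pd.DataFrame(), log_likelihood=0.0,
        k=1, aic=aic, n=100, n_events=40, r2=0.0, c=0.5, cohort_signature=sig,
    )


class TestAicCompare:
    def test_delta_arithmetic_and_worse_flag(self):
        fits = aic_compare([_stub("a", 100.0), _stub("b", 103.0), _stub("c", 110.0)])
        assert [f.delta_i for f in fits] == [0.0, 3.0, 10.0]
        assert [f.significantly_worse for f in fits] == [False, False, True]

    def test_single_fit_is_best(self):
        (f,) = aic_compare([_stub("only", 57.0)])
        assert f.delta_i == 0.0 and not f.significantly_worse

    def test_equal_aics_tie_with_name_order(self):
        fits = aic_compare([_stub("zeta", 90.0), _stub("alpha", 90.0)])
        assert [f.name for f in fits] == ["alpha", "zeta"]
        assert all(f.delta_i == 0.0 for f in fits)

    def test_different_cohorts_rejected(self):
        with pytest.raises(CohortMismatchError):
            aic_compare([_stub("a", 100.0), _stub("b", 101.0, sig=(99, 40, 1.0, 99.0))])


@pytest.fixture(scope="module")
def scored_cohort(default_cohort):
    return ar.score_dataframe(default_cohort)


class TestFitCox:
    def test_duplicate_predictor_rejected(self, scored_cohort):
        with pytest.raises(CollinearityError, match="duplicate"):
            fit_cox("dup", scored_cohort, predictors=["ms", "ms"],
                    compute_performance=False)

    def test_collinear_pair_named(self, scored_cohort):
        df = scored_cohort.copy()
        df["ms_twice"] = 2.0 * df["ms"]
        with pytest.raises(CollinearityError, match="ms.*ms_twice|ms_twice.*ms"):
            fit_cox("col", df, predictors=["ms", "ms_twice"],
                    compute_performance=False)

    def test_equal_weights_match_unweighted_exactly(self, scored_cohort):
        df = scored_cohort.copy()
        df["flat"] = 1.0
        a = fit_cox("MS", df, weight_col="flat", compute_performance=False)
        b = fit_cox("MS", df, weight_col=None, compute_performance=False)
        pd.testing.assert_frame_equal(a.summary, b.summary)
        assert a.aic == pytest.approx(b.aic, rel=1e-12)

    def test_null_covariates_cover_one(self):
        """Sex/race unrelated to survival: base-model CIs straddle HR=1."""
        cfg = ar.GeneratorConfig(
            n=4000, seed=77, index_slopes={"height": 0, "bmi": 0, "absi": 0, "hi": 0},
            ms_component_log_hr={}, male_log_hr=0.0, race_black_log_hr=0.0,
        )
        df = ar.score_dataframe(ar.generate_cohort(ar.calibrate(cfg)))
        fit = fit_cox("Base", df, compute_performance=False)
        for pred in ("male", "race_black"):
            hr, lo, hi = fit.hazard_ratio(pred)
            assert lo < 1.0 < hi

    def test_hazard_ratio_cis_bracket_points(self, scored_cohort):
        fit = fit_cox("MS components", scored_cohort, compute_performance=False)
        s = fit.summary
        assert ((s["ci_low"] < s["hr"]) & (s["hr"] < s["ci_high"])).all()


class TestNesting:
    def test_nested_model_never_has_lower_partial_likelihood(self, scored_cohort):
        base = fit_cox("Base", scored_cohort, compute_performance=False)
        bigger = fit_cox("MS components", scored_cohort, compute_performance=False)
        assert bigger.log_likelihood >= base.log_likelihood - 1e-8


class TestConcordance:
    def test_random_scores_have_no_skill(self):
        rng = np.random.default_rng(4)
        n = 4000
        entry = rng.uniform(30, 70, n)
        exit_ = entry + rng.exponential(10, n)
        event = rng.uniform(size=n) < 0.5
        c = concordance_index(rng.normal(size=n), entry, exit_, event)
        assert c == pytest.approx(0.5, abs=0.02)

    def test_identical_scores_give_exactly_half(self):
        rng = np.random.default_rng(5)
        n = 500
        entry = rng.uniform(30, 70, n)
        exit_ = entry + rng.exponential(10, n)
        event = rng.uniform(size=n) < 0.5
        c = concordance_index(np.zeros(n), entry, exit_, event)
        assert c == 0.5

    def test_true_log_hazard_dominates_noisy_scores(self, default_cohort):
        df = ar.add_exit_age(default_cohort)
        entry = df["age"].to_numpy()
        exit_ = df["exit_age"].to_numpy()
        event = df["died"].to_numpy(bool)
        truth = df["true_log_hazard"].to_numpy()
        c_true = concordance_index(truth, entry, exit_, event)
        rng = np.random.default_rng(6)
        for noise_sd in (0.5, 2.0):
            c_noisy = concordance_index(
                truth + rng.normal(0, noise_sd, len(df)), entry, exit_, event
            )
            assert c_true > c_noisy
        assert c_true > 0.5

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            concordance_index(np.ones(3), np.zeros(3), np.ones(3),
                              np.zeros(3, bool))


class TestExplainedVariation:
    def test_null_predictor_near_zero(self):
        rng = np.random.default_rng(7)
        n = 3000
        entry = rng.uniform(30, 70, n)
        exit_ = entry + rng.exponential(10, n)
        event = rng.uniform(size=n) < 0.5
        r2 = royston_r2(rng.normal(size=n), entry, exit_, event)
        assert r2 < 0.01

    def test_constant_risk_is_zero(self):
        r2 = royston_r2(np.ones(100), np.zeros(100), np.ones(100),
                        np.ones(100, bool))
        assert r2 == 0.0

    def test_strong_predictor_beats_weak(self):
        def cohort(beta, seed):
            rng = np.random.default_rng(seed)
            n = 4000
            x = rng.normal(size=n)
            entry = rng.uniform(30, 70, n)
            lam = 0.01 * np.exp(beta * x)
            t = rng.exponential(1 / lam)
            exit_ = entry + np.minimum(t, 20)
            event = t < 20
            return x, entry, exit_, event

        x, entry, exit_, event = cohort(1.0, 8)
        strong = royston_r2(x, entry, exit_, event)
        x, entry, exit_, event = cohort(0.1, 8)
        weak = royston_r2(x, entry, exit_, event)
        assert strong > weak

    def test_r2_in_unit_interval(self, scored_cohort):
        fit = fit_cox("MS score", scored_cohort)
        assert 0.0 <= fit.r2 < 1.0
        assert 0.0 <= fit.c <= 1.0


class TestCorrelationTable:
    def test_diagonal_is_one_and_symmetric(self, scored_cohort):
        corr = correlation_table(scored_cohort)
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)
        assert "MS score" in corr.columns and "Waist" in corr.columns

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(9)
        n = 5000
        df = pd.DataFrame(dict(ari=rng.normal(size=n), ms=rng.integers(0, 2, n)))
        corr = correlation_table(df, {"ari": "ARI", "ms": "MS"})
        assert abs(corr.loc["ARI", "MS"]) < 3 / np.sqrt(n)

    def test_zero_variance_column_flagged(self):
        df = pd.DataFrame(dict(ari=np.random.default_rng(0).normal(size=50),
                               ms=np.zeros(50)))
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = correlation_table(df, {"ari": "ARI", "ms": "MS"})
        assert np.isnan(corr.loc["MS", "ARI"])
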