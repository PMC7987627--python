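"""Tests of feature derivation, robust fitting, cutoffs, and FP1 selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dosegain.cohort import GeneratorConfig, generate_cohort
from dosegain.errors import (
    CodingError,
    InsufficientDataError,
    RankDeficiencyError,
)
from dosegain.predictors import (
    RegressionResult,
    cutoff_from_fit,
    derive_features,
    dummy_code,
    fp_select,
    robust_fit,
    round_printed,
    screen_all,
)


class TestDeriveFeatures:
    def test_ratio_and_difference(self):
        rec = pd.DataFrame(
            {"breast_depth_prone": [80.0], "breast_depth_supine": [40.0],
             "breast_volume_left": [490.0], "weight": [70.0]}
        )
        out = derive_features(rec)
        assert out.depth_ratio.iloc[0] == pytest.approx(2.0)
        assert out.depth_diff.iloc[0] == pytest.approx(40.0)
        assert out.breast_volume_per_weight.iloc[0] == pytest.approx(7.0)

    def test_missing_weight_propagates_only_to_volume_ratio(self):
        rec = pd.DataFrame(
            {"breast_depth_prone": [80.0], "breast_depth_supine": [40.0],
             "breast_volume_left": [490.0], "weight": [np.nan]}
        )
        out = derive_features(rec)
        assert np.isnan(out.breast_volume_per_weight.iloc[0])
        assert out.depth_ratio.iloc[0] == pytest.approx(2.0)

    def test_zero_supine_depth_gives_missing_ratio(self):
        rec = pd.DataFrame(
            {"breast_depth_prone": [80.0], "breast_depth_supine": [0.0]}
        )
        assert np.isnan(derive_features(rec).depth_ratio.iloc[0])


class TestDummyCode:
    def test_reference_maps_to_zero(self):
        coded = dummy_code(["bionix", "varian", "bionix"], "bionix")
        assert coded.tolist() == [0.0, 1.0, 0.0]

    def test_all_reference_gives_all_zero(self):
        assert dummy_code(["a", "a"], "a").tolist() == [0.0, 0.0]

    def test_unseen_level_rejected(self):
        with pytest.raises(CodingError):
            dummy_code(["a", "b", "c"], "a", levels={"a", "b"})


class TestRobustFit:
    def test_exact_on_noiseless_line(self):
        x = np.linspace(0, 10, 30)
        res = robust_fit(x, 2.0 - 0.5 * x)
        assert res.intercept == pytest.approx(2.0, abs=1e-8)
        assert res.coefficient == pytest.approx(-0.5, abs=1e-9)

    def test_agrees_with_ols_on_clean_noiseless_data(self):
        x = np.linspace(1, 5, 20)
        y = 0.3 + 1.7 * x
        res = robust_fit(x, y)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.coefficient == pytest.approx(ols.params[1], abs=1e-9)

    def test_resists_planted_outliers_where_ols_fails(self, rng):
        x = rng.uniform(0, 10, 100)
        y = 1.0 - x + rng.normal(0, 0.1, 100)
        xo = np.concatenate([x, rng.uniform(0, 2, 10)])
        yo = np.concatenate([y, np.full(10, 8.0)])
        res = robust_fit(xo, yo)
        assert abs(res.coefficient - (-1.0)) < 3 * res.coefficient_sd
        ols = sm.OLS(yo, sm.add_constant(xo)).fit()
        assert abs(ols.params[1] - (-1.0)) > 3 * ols.bse[1]

    def test_stable_under_outlier_removal(self, rng):
        x = rng.uniform(0, 10, 100)
        y = 1.0 - x + rng.normal(0, 0.1, 100)
        xo = np.concatenate([x, rng.uniform(0, 2, 3)])
        yo = np.concatenate([y, np.full(3, 8.0)])
        with_out = robust_fit(xo, yo)
        without = robust_fit(x, y)
        assert abs(with_out.coefficient - without.coefficient) < with_out.coefficient_sd

    def test_constant_predictor_rejected(self):
        with pytest.raises(RankDeficiencyError):
            robust_fit(np.ones(20), np.arange(20.0))

    def test_too_few_complete_cases_rejected(self):
        x = np.array([1.0, 2, 3, np.nan, np.nan, np.nan, np.nan, np.nan, 4, 5, 6, 7])
        with pytest.raises(InsufficientDataError):
            robust_fit(x, np.arange(12.0))

    def test_significance_flag_matches_z_rule(self, rng):
        x = rng.uniform(0, 10, 50)
        y = -0.5 * x + rng.normal(0, 0.5, 50)
        res = robust_fit(x, y)
        assert res.significant == (abs(res.coefficient / res.coefficient_sd) > 1.96)


class TestCutoff:
    def test_reported_supine_depth_cutoff(self):
        res = RegressionResult("depth supine", 0.278, -0.0073, 0.0038, 116, True)
        res = cutoff_from_fit(res)
        assert round_printed(res.cutoff) == 38
        assert res.direction == "greater_better"

    def test_reported_total_lung_cutoff(self):
        res = RegressionResult("total lung", -0.640, 0.0970, 0.0766, 116, False)
        res = cutoff_from_fit(res)
        assert round_printed(res.cutoff, 1) == 6.6
        assert res.direction == "less_better"

    def test_zero_intercept_gives_zero_cutoff(self):
        res = cutoff_from_fit(RegressionResult("x", 0.0, -0.5, 0.1, 30, True))
        assert res.cutoff == 0.0

    def test_flat_slope_not_identifiable(self):
        res = cutoff_from_fit(RegressionResult("x", 0.1, 0.01, 0.1, 30, False))
        assert res.cutoff is None

    def test_cutoff_outside_data_range_not_identifiable(self):
        res = RegressionResult("x", 10.0, -0.1, 0.01, 30, True)
        assert cutoff_from_fit(res, x_range=(0.0, 50.0)).cutoff is None

    def test_prediction_is_zero_at_cutoff_and_negative_on_better_side(self):
        res = cutoff_from_fit(RegressionResult("x", 1.244, -0.795, 0.2493, 116, True))
        at_cut = res.intercept + res.coefficient * res.cutoff
        assert at_cut == pytest.approx(0.0, abs=1e-9)
        beyond = res.intercept + res.coefficient * (res.cutoff + 1.0)
        assert beyond < 0  # prone strictly better past the cutoff


class TestFPSelect:
    def test_linear_data_selects_linear(self, rng):
        x = rng.uniform(1, 10, 200)
        y = 0.5 + 0.8 * x + rng.normal(0, 0.3, 200)
        assert fp_select(x, y).form == "linear"

    def test_log_data_selects_log_power(self, rng):
        x = rng.lognormal(1.0, 0.8, 200)
        y = np.log(x) + rng.normal(0, 0.3, 200)
        res = fp_select(x, y)
        assert res.form == "fp1"
        assert res.power == 0

    def test_independent_response_usually_null(self):
        r = np.random.default_rng(99)
        rejections = sum(
            fp_select(r.lognormal(3.5, 0.5, 116), r.normal(0, 1, 116)).form != "null"
            for _ in range(100)
        )
        assert rejections <= 15

    def test_non_positive_x_is_shifted(self, rng):
        x = rng.uniform(-5, 5, 150)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.3, 150)
        res = fp_select(x, y)
        assert res.shift > 0
        assert res.form in ("linear", "fp1")


@pytest.fixture(scope="module")
def direct_records():
    config = GeneratorConfig(n_patients=200, seed=42, mode="direct", n_outliers=0)
    return generate_cohort(config).characteristics


class TestScreenAll:
    def test_planted_depth_ratio_signal_is_recovered(self, direct_records):
        table = screen_all(direct_records)
        by_name = table.set_index("characteristic")
        ratio = by_name.loc["Breast depth ratio prone/supine"]
        assert ratio.significant
        assert ratio.coefficient < 0
        couch = by_name.loc["Couch type Varian vs Bionix"]
        assert not couch.significant

    def test_post_dosimetry_supine_score_has_negative_slope(self, direct_records):
        table = screen_all(direct_records).set_index("characteristic")
        assert table.loc["Supine penalty score"].coefficient < 0
        assert table.loc["Prone penalty score"].coefficient > 0

    def test_deterministic_ordering(self, direct_records):
        t1 = screen_all(direct_records, run_fp=False)
        t2 = screen_all(direct_records, run_fp=False)
        pd.testing.assert_frame_equal(t1, t2)

    def test_exclusion_drops_patients(self, direct_records):
        drop = list(direct_records.patient_id.iloc[:5])
        table = screen_all(direct_records, run_fp=False, exclude=drop)
        assert table.set_index("characteristic").loc[
            "Breast depth ratio prone/supine", "n"
        ] == len(direct_records) - 5
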