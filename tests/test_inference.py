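"""Inference: imputation, Park test, GLM/OLS fits, SUR, bootstrap, BCa."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from trialcea.cohort import CohortParams, generate_cohort
from trialcea.inference import (
    RegressionSpec,
    bca_ci,
    bootstrap_sur,
    fit_cost_model,
    fit_effect_model,
    jackknife_sur,
    modified_park_test,
    regression_impute,
    sur_fit,
)
from trialcea.scenarios import add_outcome_columns, build_analysis_frame

from conftest import TRUE_DELTA_QALY


class TestRegressionImpute:
    def test_no_missingness_returns_frame_unchanged(self):
        frame = pd.DataFrame(
            {"arm": [0, 1, 0, 1], "utility_t0": [0.5, 0.6, 0.7, 0.8],
             "isi_t0": [15, 16, 17, 18], "baseline_depression": [10, 11, 12, 13],
             "age": [40, 45, 50, 55], "cost_total": [100.0, 200.0, 300.0, 400.0]}
        )
        out = regression_impute(frame)
        pd.testing.assert_frame_equal(out.drop(columns="imputed"), frame)
        assert not out["imputed"].any()

    def test_single_missing_value_equals_fitted_line(self):
        rng = np.random.default_rng(4)
        n = 40
        x = rng.normal(0, 1, n)
        arm = np.repeat([0.0, 1.0], n // 2)
        y = 10 + 5 * x + 2 * arm + rng.normal(0, 0.5, n)
        y_missing = y.copy()
        y_missing[7] = np.nan
        frame = pd.DataFrame(
            {"arm": arm, "x": x, "cost_total": y_missing,
             "utility_t0": np.zeros(n), "isi_t0": np.zeros(n),
             "baseline_depression": np.zeros(n), "age": np.zeros(n)}
        )
        out = regression_impute(frame, outcome_predictors=("x",), dropout_predictors=())
        obs = ~np.isnan(y_missing)
        X = np.column_stack([np.ones(n), arm, x])
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        assert out.loc[7, "cost_total"] == pytest.approx(X[7] @ beta)

    def test_mar_dropout_arm_means_recovered(self):
        """Under missingness at random on a baseline covariate, the imputed
        arm-mean QALY matches the pre-dropout truth on the same participants."""
        params = CohortParams(n_per_arm=2000, seed=31, dropout_rate=0.4)
        truth = build_analysis_frame(generate_cohort(CohortParams(**{**params.__dict__, "dropout_rate": 0.0})))
        frame = regression_impute(build_analysis_frame(generate_cohort(params)))
        truth = add_outcome_columns(truth, "societal")
        frame = add_outcome_columns(frame, "societal")
        for arm_val in (0, 1):
            t = truth.loc[truth["arm"] == arm_val, "qaly"]
            f = frame.loc[frame["arm"] == arm_val, "qaly"]
            assert abs(f.mean() - t.mean()) < 2 * t.std() / np.sqrt(len(t))

    def test_all_missing_predictor_named(self):
        frame = pd.DataFrame(
            {"arm": [0, 1], "utility_t0": [np.nan, np.nan], "isi_t0": [1.0, 2.0],
             "baseline_depression": [1.0, 2.0], "age": [40.0, 50.0],
             "cost_total": [1.0, np.nan]}
        )
        with pytest.raises(ValueError, match="utility_t0"):
            regression_impute(frame)


class TestModifiedParkTest:
    def test_variance_proportional_to_mean_squared_recommends_gamma(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(1, 10, 5000)
        y = rng.gamma(2.0, mu / 2.0)  # var = mu^2 / 2
        fit = sm.OLS(y, sm.add_constant(mu)).fit()
        result = modified_park_test(y - fit.fittedvalues, fit.fittedvalues)
        assert result.family == "gamma"
        assert abs(result.slope - 2.0) < 3 * result.slope_se

    def test_homoskedastic_data_recommends_gaussian(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 10, 5000)
        y = 2 + 3 * x + rng.normal(0, 1, 5000)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        result = modified_park_test(y - fit.fittedvalues, fit.fittedvalues)
        assert result.family == "gaussian"
        assert abs(result.slope) < 0.3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            modified_park_test([1.0, -1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            modified_park_test([1.0, -1.0], [1.0, -1.0])


class TestSingleEquationModels:
    def test_gamma_identity_recovers_arm_effect(self):
        """Parameter recovery on data simulated from the gamma-identity model
        itself (variance proportional to the squared mean)."""
        rng = np.random.default_rng(2)
        n = 10_000
        arm = np.repeat([0.0, 1.0], n // 2)
        age = rng.normal(48, 10, n)
        mu = 5000 - 900 * arm + 10 * (age - 48)
        y = rng.gamma(2.0, mu / 2.0)
        frame = pd.DataFrame({"arm": arm, "age": age, "cost": y})
        res = fit_cost_model(frame, RegressionSpec("cost", ("age",), family="gamma"))
        assert abs(res.arm_effect - (-900)) < 2 * res.bse[1]

    def test_gaussian_no_covariates_equals_mean_difference(self):
        frame = pd.DataFrame(
            {"arm": [0, 0, 0, 1, 1, 1], "cost": [10.0, 20.0, 30.0, 50.0, 60.0, 70.0]}
        )
        res = fit_cost_model(frame, RegressionSpec("cost", (), family="gaussian"))
        assert res.arm_effect == pytest.approx(40.0)

    def test_adjusted_societal_cost_negative_on_calibrated_cohort(self, recovery_frame):
        spec = RegressionSpec("cost_total", ("age", "baseline_depression"), family="gamma")
        res = fit_cost_model(recovery_frame, spec)
        assert res.arm_effect < 0

    def test_gamma_zero_fraction_falls_back_to_gaussian(self):
        frame = pd.DataFrame(
            {"arm": np.repeat([0.0, 1.0], 20),
             "cost": np.concatenate([np.zeros(15), np.full(25, 100.0)])}
        )
        with pytest.warns(UserWarning, match="zero"):
            fit_cost_model(frame, RegressionSpec("cost", (), family="gamma"))

    def test_effect_risk_difference_closed_form(self):
        frame = pd.DataFrame(
            {"arm": [0] * 10 + [1] * 10,
             "symptom_free": [1, 0, 0, 0, 0, 0, 0, 0, 0, 0] + [1] * 6 + [0] * 4}
        )
        res = fit_effect_model(frame, RegressionSpec("symptom_free", ()))
        assert res.arm_effect == pytest.approx(0.6 - 0.1)

    def test_qaly_gain_recovery(self, recovery_frame):
        res = fit_effect_model(recovery_frame, RegressionSpec("qaly", ("utility_t0",)))
        assert abs(res.arm_effect - TRUE_DELTA_QALY) < 2 * res.bse[1]

    def test_unadjusted_remission_difference_near_configured_gap(self, recovery_frame):
        # restricted to completers: thresholding deterministically imputed ISI
        # scores attenuates the ITT risk difference, which is a property of
        # regression imputation rather than of the generator
        completers = recovery_frame.loc[recovery_frame["completed_followup"]]
        res = fit_effect_model(completers, RegressionSpec("symptom_free", ()))
        assert abs(res.arm_effect - 0.36) < 0.02

    def test_collinear_covariates_rejected(self):
        frame = pd.DataFrame(
            {"arm": [0, 0, 1, 1], "qaly": [0.3, 0.4, 0.5, 0.6],
             "a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]}
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_effect_model(frame, RegressionSpec("qaly", ("a", "b")))


def _sur_sim_frame(n, rho, seed, sd1=2.0, sd2=1.0):
    rng = np.random.default_rng(seed)
    arm = np.repeat([0.0, 1.0], n // 2)
    c1 = rng.normal(0, 1, n)
    c2 = rng.normal(0, 1, n)
    cov = [[sd1**2, rho * sd1 * sd2], [rho * sd1 * sd2, sd2**2]]
    e = rng.multivariate_normal([0, 0], cov, size=n)
    y1 = 1.0 + 2.0 * arm + 0.5 * c1 + e[:, 0]
    y2 = -1.0 + 0.3 * arm + 0.2 * c2 + e[:, 1]
    return pd.DataFrame({"arm": arm, "c1": c1, "c2": c2, "y1": y1, "y2": y2})


class TestSUR:
    def test_identical_regressors_equal_per_equation_ols(self, recovery_frame):
        cost_spec = RegressionSpec("cost_total", ("age", "baseline_depression"))
        effect_spec = RegressionSpec("qaly", ("age", "baseline_depression"))
        fit = sur_fit(recovery_frame, cost_spec, effect_spec)
        X, y1, _ = cost_spec.design(recovery_frame)
        _, y2, _ = effect_spec.design(recovery_frame)
        ols1 = np.linalg.lstsq(X, y1, rcond=None)[0]
        ols2 = np.linalg.lstsq(X, y2, rcond=None)[0]
        assert np.allclose(fit.params_cost.to_numpy(), ols1, rtol=1e-8, atol=1e-10)
        assert np.allclose(fit.params_effect.to_numpy(), ols2, rtol=1e-8, atol=1e-10)

    def test_residual_correlation_recovery(self):
        frame = _sur_sim_frame(5000, rho=0.5, seed=6)
        fit = sur_fit(frame, RegressionSpec("y1", ("c1",)), RegressionSpec("y2", ("c2",)))
        se = (1 - 0.5**2) / np.sqrt(5000)
        assert abs(fit.resid_corr - 0.5) < 3 * se
        assert abs(fit.params_cost["arm"] - 2.0) < 3 * fit.delta_cost_se
        assert abs(fit.params_effect["arm"] - 0.3) < 3 * fit.delta_effect_se

    def test_zero_correlation_matches_ols_closely(self):
        frame = _sur_sim_frame(5000, rho=0.0, seed=7)
        cost_spec = RegressionSpec("y1", ("c1",))
        effect_spec = RegressionSpec("y2", ("c2",))
        fit = sur_fit(frame, cost_spec, effect_spec)
        X1, y1, _ = cost_spec.design(frame)
        X2, y2, _ = effect_spec.design(frame)
        ols1 = np.linalg.lstsq(X1, y1, rcond=None)[0]
        ols2 = np.linalg.lstsq(X2, y2, rcond=None)[0]
        assert abs(fit.params_cost["arm"] - ols1[1]) < 0.2 * fit.delta_cost_se
        assert abs(fit.params_effect["arm"] - ols2[1]) < 0.2 * fit.delta_effect_se


class TestBootstrapSUR:
    def test_cloud_size_and_reproducibility(self, recovery_frame):
        sub = recovery_frame.iloc[::100].reset_index(drop=True)  # n=200 for speed
        cost_spec = RegressionSpec("cost_total", ("age", "baseline_depression"))
        effect_spec = RegressionSpec("qaly", ("utility_t0",))
        a = bootstrap_sur(sub, cost_spec, effect_spec, B=300, seed=5)
        b = bootstrap_sur(sub, cost_spec, effect_spec, B=300, seed=5)
        c = bootstrap_sur(sub, cost_spec, effect_spec, B=300, seed=6)
        assert a.pairs.shape == (300, 2)
        assert np.array_equal(a.pairs, b.pairs)
        assert not np.array_equal(a.pairs, c.pairs)

    def test_cloud_mean_near_point_estimate(self, recovery_frame):
        sub = recovery_frame.iloc[::50].reset_index(drop=True)
        cost_spec = RegressionSpec("cost_total", ("age", "baseline_depression"))
        effect_spec = RegressionSpec("qaly", ("utility_t0",))
        cloud = bootstrap_sur(sub, cost_spec, effect_spec, B=2000, seed=5)
        for j in range(2):
            sd = cloud.pairs[:, j].std()
            assert abs(cloud.pairs[:, j].mean() - cloud.point[j]) < 0.2 * sd

    def test_dispersion_shrinks_with_sqrt_k_duplication(self):
        frame = _sur_sim_frame(100, rho=0.3, seed=8)
        big = pd.concat([frame] * 4, ignore_index=True)
        cost_spec = RegressionSpec("y1", ("c1",))
        effect_spec = RegressionSpec("y2", ("c2",))
        small_cloud = bootstrap_sur(frame, cost_spec, effect_spec, B=2000, seed=9)
        big_cloud = bootstrap_sur(big, cost_spec, effect_spec, B=2000, seed=9)
        ratio = big_cloud.pairs[:, 0].std() / small_cloud.pairs[:, 0].std()
        assert 0.4 < ratio < 0.6

    def test_degenerate_cohort_gives_constant_cloud(self):
        frame = pd.DataFrame(
            {"arm": [0.0] * 10 + [1.0] * 10,
             "y1": [100.0] * 10 + [80.0] * 10,
             "y2": [0.3] * 10 + [0.5] * 10}
        )
        cloud = bootstrap_sur(frame, RegressionSpec("y1", ()), RegressionSpec("y2", ()),
                              B=200, seed=3)
        assert np.allclose(cloud.pairs[:, 0], -20.0)
        assert np.allclose(cloud.pairs[:, 1], 0.2)
        assert cloud.point == pytest.approx((-20.0, 0.2))

    def test_b_floor_enforced(self, recovery_frame):
        with pytest.raises(ValueError):
            bootstrap_sur(recovery_frame, RegressionSpec("cost_total", ()),
                          RegressionSpec("qaly", ()), B=50)


class TestBCa:
    def test_reduces_to_percentile_under_zero_bias_and_acceleration(self, rng):
        reps = rng.standard_normal(2500)
        lo, hi = bca_ci(reps, float(np.median(reps)), None, level=0.95)
        assert lo == pytest.approx(np.quantile(reps, 0.025), abs=1e-9)
        assert hi == pytest.approx(np.quantile(reps, 0.975), abs=1e-9)

    def test_normal_quantiles(self, rng):
        reps = rng.standard_normal(2500)
        lo, hi = bca_ci(reps, float(np.median(reps)), None)
        assert lo == pytest.approx(-1.96, abs=0.15)
        assert hi == pytest.approx(1.96, abs=0.15)

    def test_matches_scipy_bca_on_skewed_statistic(self):
        """Independent oracle: scipy's BCa interval for the mean of skewed data."""
        rng = np.random.default_rng(17)
        data = rng.exponential(1.0, 80)
        B = 6000
        idx = rng.integers(0, 80, size=(B, 80))
        reps = data[idx].mean(axis=1)
        jack = np.array([np.delete(data, i).mean() for i in range(80)])
        lo, hi = bca_ci(reps, float(data.mean()), jack)
        oracle = scipy.stats.bootstrap(
            (data,), np.mean, n_resamples=B, confidence_level=0.95,
            method="BCa", random_state=np.random.default_rng(99),
        ).confidence_interval
        assert lo == pytest.approx(oracle.low, abs=0.02)
        assert hi == pytest.approx(oracle.high, abs=0.02)

    def test_degenerate_replicates_warn_and_collapse(self):
        with pytest.warns(UserWarning, match="identical"):
            lo, hi = bca_ci(np.full(500, 3.0), 3.0)
        assert lo == hi == 3.0

    def test_minimum_replicates(self):
        with pytest.raises(ValueError):
            bca_ci(np.arange(50), 25.0)


class TestJackknife:
    def test_shape_and_leave_one_out_effect(self):
        frame = _sur_sim_frame(60, rho=0.2, seed=10)
        jk = jackknife_sur(frame, RegressionSpec("y1", ("c1",)), RegressionSpec("y2", ("c2",)))
        assert jk.shape == (60, 2)
        assert jk[:, 0].std() > 0
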