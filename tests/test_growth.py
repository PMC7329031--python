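"""Ricker model primitives, NLS fitting, AICc selection and uncertainty bands."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleodyn.growth import (
    GrowthModelFit,
    GrowthModelParams,
    GrowthModelSpec,
    InvalidCapacityError,
    aicc,
    akaike_weights,
    carrying_capacity,
    fit_growth_model,
    fit_model_set,
    per_capita_growth,
    prediction_r2,
    ratio_regression,
    ricker_step,
    simulate_trajectory,
    trajectory_ci,
)
from paleodyn.series import CovariateSeries, DemographicSeries
from paleodyn.synthetic import SyntheticScenario, gen_covariates, gen_population


class TestPerCapitaGrowth:
    def test_constant_population_zero_growth(self):
        s = DemographicSeries(np.arange(0, 90, 30), np.full(3, 7.0))
        np.testing.assert_allclose(per_capita_growth(s), 0.0)

    def test_doubling_gives_log_two(self):
        s = DemographicSeries(np.arange(0, 120, 30), 100.0 * 2.0 ** np.arange(4))
        np.testing.assert_allclose(per_capita_growth(s), np.log(2.0))

    def test_halving_gives_minus_log_two(self):
        s = DemographicSeries([0.0, 30.0], [100.0, 50.0])
        np.testing.assert_allclose(per_capita_growth(s), -np.log(2.0))

    def test_nonpositive_population_rejected(self):
        s = DemographicSeries([0.0, 30.0], [100.0, 0.0])
        with pytest.raises(ValueError):
            per_capita_growth(s)


class TestCapacityAndRicker:
    def test_constant_form_ignores_covariates(self):
        p = GrowthModelParams(0.4, 500.0)
        assert carrying_capacity(p, f=30.0, c=0.5) == 500.0

    def test_linear_palm_effect(self):
        p = GrowthModelParams(0.4, 0.0, k_f=10.0)
        assert carrying_capacity(p, f=40.0, check=False) == pytest.approx(400.0)

    def test_nonpositive_capacity_signalled(self):
        p = GrowthModelParams(0.4, 100.0, k_c=-200.0)
        with pytest.raises(InvalidCapacityError):
            carrying_capacity(p, c=0.6)

    def test_equilibrium_is_fixed_point(self):
        p = GrowthModelParams(0.7, 900.0)
        assert ricker_step(p, 900.0, 900.0) == pytest.approx(900.0)

    def test_zero_rate_is_identity(self):
        p = GrowthModelParams(0.0, 900.0)
        assert ricker_step(p, 123.0, 900.0) == pytest.approx(123.0)

    def test_closed_form_value(self):
        # 500 * exp(0.5 * (1 - 500/1000)) = 500 * e^0.25
        p = GrowthModelParams(0.5, 1000.0)
        assert ricker_step(p, 500.0, 1000.0) == pytest.approx(500.0 * np.exp(0.25))


class TestAicc:
    def test_hand_computed_value(self):
        # 22*ln(0.22/22) + 2*2 + 2*2*3/19
        assert aicc(22, 2, 0.22) == pytest.approx(22 * np.log(0.01) + 4 + 12 / 19)
        assert aicc(22, 2, 0.22) == pytest.approx(-96.6822, abs=1e-4)

    def test_smaller_rss_smaller_aicc(self):
        assert aicc(22, 3, 0.11) < aicc(22, 3, 0.22)

    def test_more_params_larger_aicc_at_same_rss(self):
        assert aicc(22, 4, 0.22) > aicc(22, 3, 0.22)

    def test_insufficient_observations_rejected(self):
        with pytest.raises(ValueError):
            aicc(4, 3, 0.1)


class TestAkaikeWeights:
    def test_equal_values_equal_weights(self):
        np.testing.assert_allclose(akaike_weights([-100.0, -100.0, -100.0]), 1 / 3)

    def test_delta_two_weight_split(self):
        w = akaike_weights([0.0, 2.0])
        np.testing.assert_allclose(w, [1 / (1 + np.e**-1), np.e**-1 / (1 + np.e**-1)])
        np.testing.assert_allclose(w, [0.7311, 0.2689], atol=1e-4)

    def test_infinite_delta_gives_zero_weight(self):
        np.testing.assert_allclose(akaike_weights([0.0, np.inf]), [1.0, 0.0])

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([1.0])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=-500, max_value=500), min_size=2, max_size=6))
    def test_weights_sum_to_one(self, values):
        assert akaike_weights(values).sum() == pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def scenario_covariates():
    sc = SyntheticScenario(seed=7, obs_noise_sd=0.0)
    return sc, gen_covariates(sc)


_TRUE = {
    "constant": GrowthModelParams(0.4, 800.0),
    "palm": GrowthModelParams(0.45, 1.0, k_f=0.15),
    "soi": GrowthModelParams(0.45, 3.0, k_c=-2.0),
    "palm_soi": GrowthModelParams(0.45, 1.0, k_f=0.15, k_c=-0.8),
}


class TestFitGrowthModel:
    @pytest.mark.parametrize("k_form", list(_TRUE))
    def test_noise_free_recovery_all_forms(self, k_form, scenario_covariates):
        sc, cov = scenario_covariates
        true_p = _TRUE[k_form]
        from dataclasses import replace

        sc2 = replace(
            sc, k_form=k_form, true_params=true_p,
            n0=400.0 if k_form == "constant" else 0.5,
        )
        true, _ = gen_population(sc2, cov)
        fit = fit_growth_model(true.window(1100, 1760), cov, GrowthModelSpec(k_form))
        spec = GrowthModelSpec(k_form)
        rel = np.abs(fit.params.to_vector(spec) - true_p.to_vector(spec)) / np.abs(
            true_p.to_vector(spec)
        )
        assert np.max(rel) <= 1e-6

    def test_too_short_series_rejected(self, scenario_covariates):
        _, cov = scenario_covariates
        s = DemographicSeries(np.arange(0, 120, 30.0), [1.0, 1.2, 1.3, 1.1])
        with pytest.raises(ValueError, match="growth-rate observations"):
            fit_growth_model(s, cov, GrowthModelSpec("palm_soi"))

    def test_model_set_weights_sum_to_one(self, scenario_covariates):
        sc, cov = scenario_covariates
        true, _ = gen_population(sc, cov)
        fits = fit_model_set(true.window(1100, 1760), cov)
        assert sum(f.akaike_weight for f in fits) == pytest.approx(1.0, abs=1e-12)


class TestSimulation:
    def test_fixed_point_stays_flat(self):
        p = GrowthModelParams(0.5, 2.0)
        fitlike = GrowthModelParams(0.5, 2.0)
        traj = simulate_trajectory(fitlike, 2.0, None, np.arange(0, 300, 30.0))
        np.testing.assert_allclose(traj, 2.0)

    def test_zero_rate_stays_flat(self):
        p = GrowthModelParams(0.0, 2.0)
        traj = simulate_trajectory(p, 1.3, None, np.arange(0, 300, 30.0))
        np.testing.assert_allclose(traj, 1.3)

    def test_simulator_matches_generator_exactly(self, scenario_covariates):
        sc, cov = scenario_covariates
        true, _ = gen_population(sc, cov)
        traj = simulate_trajectory(
            sc.true_params, sc.n0, cov, true.time_ce, GrowthModelSpec(sc.k_form)
        )
        np.testing.assert_allclose(traj, true.n, rtol=1e-12)

    def test_model_equations_closure(self, scenario_covariates):
        # R_t computed from the simulated series equals the model RHS exactly
        sc, cov = scenario_covariates
        true, _ = gen_population(sc, cov)
        r = per_capita_growth(true)
        grid = cov.on_step_grid(true.time_ce, 30.0)
        k = carrying_capacity(sc.true_params, grid.palm, 0.0)
        rhs = sc.true_params.r_max * (1.0 - true.n[:-1] / k[:-1])
        np.testing.assert_allclose(r, rhs, atol=1e-12)


class TestPredictionR2:
    def test_perfect_prediction(self):
        x = np.array([1.0, 2.0, 4.0])
        assert prediction_r2(x, x) == 1.0

    def test_mean_predictor_scores_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert prediction_r2(x, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_anti_correlated_hand_value(self):
        assert prediction_r2([1, 2, 3], [3, 2, 1]) == pytest.approx(-3.0)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            prediction_r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_invariant_under_common_rescaling(self, scale):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        y = np.array([1.2, 1.8, 4.5, 3.3])
        assert prediction_r2(scale * x, scale * y) == pytest.approx(prediction_r2(x, y))


@pytest.fixture(scope="module")
def fitted():
    sc = SyntheticScenario(seed=13, obs_noise_sd=0.0)
    cov = gen_covariates(sc)
    true, _ = gen_population(sc, cov)
    fit = fit_growth_model(true.window(1100, 1760), cov, GrowthModelSpec("palm"))
    return sc, cov, true.window(1100, 1760), fit


class TestTrajectoryCI:
    def test_zero_covariance_band_collapses(self, fitted):
        sc, cov, demo, fit = fitted
        degenerate = GrowthModelFit(
            spec=fit.spec, params=fit.params, covariance=np.zeros_like(fit.covariance),
            rss=fit.rss, n_obs=fit.n_obs, aicc=fit.aicc,
        )
        band = trajectory_ci(degenerate, float(demo.n[0]), cov, demo.time_ce, n_iter=200, rng=0)
        np.testing.assert_allclose(band.lo, band.point, rtol=1e-12)
        np.testing.assert_allclose(band.hi, band.point, rtol=1e-12)

    def test_percentile_nesting(self, fitted):
        sc, cov, demo, fit = fitted
        kw = dict(n_iter=500, rng=4)
        wide = trajectory_ci(fit, float(demo.n[0]), cov, demo.time_ce, level=0.95, **kw)
        narrow = trajectory_ci(fit, float(demo.n[0]), cov, demo.time_ce, level=0.50, **kw)
        assert np.all(wide.lo <= narrow.lo + 1e-12)
        assert np.all(wide.hi >= narrow.hi - 1e-12)

    def test_same_seed_reproducible(self, fitted):
        sc, cov, demo, fit = fitted
        a = trajectory_ci(fit, float(demo.n[0]), cov, demo.time_ce, n_iter=300, rng=8)
        b = trajectory_ci(fit, float(demo.n[0]), cov, demo.time_ce, n_iter=300, rng=8)
        np.testing.assert_array_equal(a.lo, b.lo)
        np.testing.assert_array_equal(a.hi, b.hi)


class TestRatioRegression:
    def test_noiseless_line_recovered(self):
        rng = np.random.default_rng(0)
        ratio = rng.uniform(0.0, 0.2, 20)
        r = 0.4 - 2.0 * ratio
        fit = ratio_regression(r, ratio)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.intercept == pytest.approx(0.4)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.df == (1, 18)

    def test_symmetric_points_give_zero_slope(self):
        fit = ratio_regression([0.0, 1.0, 0.0], [0.0, 1.0, 2.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_ratio_rejected(self):
        with pytest.raises(ValueError):
            ratio_regression([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])
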