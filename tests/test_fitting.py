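"""Objective function, goodness of fit, and the annealed-simplex fitter."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from microloop import (
    FitConfig,
    ObservationSet,
    SyntheticDesign,
    fit_parameters,
    generate_observations,
    goodness_of_fit,
    predict_at_times,
    squared_deviation,
)
from microloop.fitting import (
    FitConfigurationError,
    anneal_simplex,
    series_ratio,
)
from tests.conftest import light_fit_config


def obs_from_rows(rows):
    return ObservationSet(
        pd.DataFrame(rows, columns=["time_days", "species", "replicate", "value"])
    )


def single_series_obs(values_by_time, species="B"):
    rows = []
    for t, values in values_by_time.items():
        for rep, v in enumerate(values, start=1):
            rows.append((t, species, rep, v))
    # pad the other species so the table is valid but contributes nothing
    return rows


class TestPredict:
    def test_time_zero_returns_init(self, truth):
        pred = predict_at_times(truth.params, truth.init, [0.0])
        assert pred["B"][0] == pytest.approx(truth.init.B)
        assert pred["D"][0] == pytest.approx(truth.init.D)

    def test_matches_verhulst_closed_form(self, truth):
        params = truth.params.replace(lam=0.0, nu_delta_D=0.0)
        init = truth.init.replace(B=0.0)
        times = np.array([7.0, 14.0, 21.0, 28.0])
        pred = predict_at_times(params, init, times)["D"]
        cc, d0, r = params.CC_D, init.D, params.nu_mu_D
        expected = cc / (1.0 + (cc / d0 - 1.0) * np.exp(-r * times))
        assert np.allclose(pred, expected, rtol=1e-6)

    def test_unsorted_times_preserve_order(self, truth):
        shuffled = predict_at_times(truth.params, truth.init, [14.0, 0.0, 7.0])
        ordered = predict_at_times(truth.params, truth.init, [0.0, 7.0, 14.0])
        assert shuffled["B"][1] == ordered["B"][0]
        assert shuffled["D"][0] == ordered["D"][2]

    def test_ratio_guard_on_zero_denominator(self):
        with pytest.warns(UserWarning):
            ratio = series_ratio(np.array([1.0, 2.0]), np.array([0.0, 4.0]))
        assert math.isnan(ratio[0])
        assert ratio[1] == pytest.approx(0.5)


class TestSquaredDeviation:
    def test_zero_on_exact_data(self, truth, noiseless_obs):
        obs, _ = noiseless_obs
        config = FitConfig(free_parameters=("lam",))
        value = squared_deviation(obs, truth.params, truth.init, config, truth.options)
        assert value == pytest.approx(0.0, abs=1e-8)

    def test_single_observation_linear_scale(self, truth):
        rows = [(0.0, "B", 1, 5.0), (7.0, "B", 1, 0.0), (14.0, "B", 1, 0.0)]
        obs = obs_from_rows(rows)
        config = FitConfig(free_parameters=("lam",), objective_scale="linear")
        # pick a model whose B-prediction at t=0 is exactly 3
        init = truth.init.replace(B=3.0)
        params = truth.params.replace(nu_mu_B=0.0, nu_delta_B=0.0, lam=0.0, nu_delta_D=0.0)
        value = squared_deviation(obs, params, init, config, truth.options)
        # B stays at 3: contributions (5-3)^2 + 3^2 + 3^2
        assert value == pytest.approx(4.0 + 9.0 + 9.0, rel=1e-9)

    def test_log_scale_replicates_hand_computed(self, truth):
        rows = [
            (0.0, "B", 1, 10.0),
            (0.0, "B", 2, 1000.0),
            (7.0, "B", 1, 100.0),
            (14.0, "B", 1, 100.0),
        ]
        obs = obs_from_rows(rows)
        config = FitConfig(free_parameters=("lam",), objective_scale="log10")
        init = truth.init.replace(B=100.0, D=0.0, DOM_E=0.0, DOM_B=0.0)
        params = truth.params.replace(nu_delta_B=0.0)
        # B is constant at 100; with g(x) = log10(x + 1) only the two
        # replicates at t=0 deviate: (g(10)-g(100))^2 + (g(1000)-g(100))^2
        g = lambda x: math.log10(x + 1.0)
        expected = (g(10) - g(100)) ** 2 + (g(1000) - g(100)) ** 2
        value = squared_deviation(obs, params, init, config, truth.options)
        assert value == pytest.approx(expected, rel=1e-6)

    def test_record_order_invariance(self, truth):
        obs, _ = generate_observations(truth, SyntheticDesign(noise_cv=0.1, rng_seed=5))
        config = FitConfig(free_parameters=("lam",))
        base = squared_deviation(obs, truth.params, truth.init, config, truth.options)
        shuffled = ObservationSet(
            obs.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        relabeled = ObservationSet(
            obs.data.assign(replicate=obs.data["replicate"].map({1: 3, 2: 1, 3: 2}))
        )
        for variant in (shuffled, relabeled):
            value = squared_deviation(variant, truth.params, truth.init, config, truth.options)
            assert value == pytest.approx(base, rel=1e-12)

    def test_mean_fitting_flag(self, truth):
        obs, _ = generate_observations(truth, SyntheticDesign(noise_cv=0.2, rng_seed=5))
        rep = FitConfig(free_parameters=("lam",), fit_to_replicates=True)
        mean = FitConfig(free_parameters=("lam",), fit_to_replicates=False)
        v_rep = squared_deviation(obs, truth.params, truth.init, rep, truth.options)
        v_mean = squared_deviation(obs, truth.params, truth.init, mean, truth.options)
        # replicate scatter adds deviation that the mean fit does not see
        assert v_rep > v_mean


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        r2, p = goodness_of_fit([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r2 == pytest.approx(1.0)
        assert p < 1e-6

    def test_scale_invariance_of_correlation(self):
        r2, _ = goodness_of_fit([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r2 == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # r = 3 / sqrt(2 * 14/3)  =>  r^2 = 27/28
        r2, p = goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert r2 == pytest.approx(27.0 / 28.0, rel=1e-12)
        r = math.sqrt(r2)
        t_stat = r * math.sqrt(1.0) / math.sqrt(1.0 - r2)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(t_stat, df=1), rel=1e-6)

    def test_ss_definition_can_be_negative(self):
        r2, _ = goodness_of_fit([1.0, 2.0, 3.0], [10.0, 12.0, 20.0], method="ss")
        assert r2 < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAnnealSimplex:
    def test_zero_temperature_matches_plain_nelder_mead(self):
        """At T0 = 0 the hybrid is the plain downhill simplex."""
        target = np.array([0.7, -1.3, 2.1])

        def quadratic(x):
            return float(np.sum((x - target) ** 2))

        lo = np.full(3, -5.0)
        hi = np.full(3, 5.0)
        rng = np.random.default_rng(0)
        x_best, f_best, _, converged, _ = anneal_simplex(
            quadratic, np.zeros(3), lo, hi, rng, T0=0.0, restarts=1, n_temps=1,
            steps_per_temp=0,
        )
        reference = minimize(
            quadratic, np.zeros(3), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        assert converged
        assert np.allclose(x_best, reference.x, atol=1e-6)
        assert f_best <= reference.fun + 1e-10

    def test_annealing_escapes_local_minimum(self):
        """A double well where the start sits in the shallow basin."""

        def double_well(x):
            v = x[0]
            return float(min((v - 3.0) ** 2, 0.5 + 5.0 * (v + 2.0) ** 2))

        lo, hi = np.array([-5.0]), np.array([5.0])
        rng = np.random.default_rng(3)
        # T0 on the scale of the barrier between the wells
        x_best, f_best, _, _, _ = anneal_simplex(
            double_well, np.array([-2.0]), lo, hi, rng,
            T0=8.0, cooling=0.85, steps_per_temp=25, n_temps=30, restarts=3,
        )
        assert f_best == pytest.approx(0.0, abs=1e-8)
        assert x_best[0] == pytest.approx(3.0, abs=1e-3)


BOUNDS_3 = {"nu_mu_B": (1e-3, 1e2), "lam": (1e-3, 1e2), "K_DOME": (1e3, 1e10)}


class TestFitParameters:
    def test_noiseless_recovery_within_5pct(self, truth, noiseless_obs):
        obs, _ = noiseless_obs
        config = light_fit_config(
            ("nu_mu_B", "lam", "K_DOME"), BOUNDS_3, n_temps=30, steps_per_temp=25
        )
        result = fit_parameters(obs, config, truth.init, truth.params, truth.options)
        assert result.objective_value < 1e-6
        for name, estimate in result.free_values(config.free_parameters).items():
            true_value = getattr(truth.params, name)
            assert abs(estimate - true_value) / true_value < 0.05, name

    def test_seeded_determinism(self, truth):
        obs, _ = generate_observations(truth, SyntheticDesign(noise_cv=0.1, rng_seed=9))
        config = light_fit_config(("nu_mu_B", "lam"), BOUNDS_3, seed=21, n_temps=8,
                                  steps_per_temp=10)
        a = fit_parameters(obs, config, truth.init, truth.params, truth.options)
        b = fit_parameters(obs, config, truth.init, truth.params, truth.options)
        assert a.params_hat == b.params_hat
        assert a.objective_value == b.objective_value
        assert a.n_evaluations == b.n_evaluations

    def test_bounds_are_respected(self, truth):
        # truth nu_mu_B is 2.0; force the search into [3, 5]
        obs, _ = generate_observations(truth, SyntheticDesign(noise_cv=0.0, rng_seed=2))
        config = light_fit_config(
            ("nu_mu_B",), {"nu_mu_B": (3.0, 5.0)}, n_temps=8, steps_per_temp=10
        )
        result = fit_parameters(obs, config, truth.init, truth.params, truth.options)
        assert 3.0 <= result.params_hat.nu_mu_B <= 5.0
        assert "nu_mu_B" in result.at_bounds

    def test_too_many_free_parameters_rejected(self, truth):
        rows = [(t, "B", 1, 1e5) for t in (0.0, 7.0, 14.0)]
        obs = obs_from_rows(rows)
        config = FitConfig()  # 12 free parameters, 3 points
        with pytest.raises(FitConfigurationError):
            fit_parameters(obs, config, truth.init, truth.params, truth.options)

    def test_invalid_config_rejected(self):
        with pytest.raises(FitConfigurationError):
            FitConfig(cooling=1.5)
        with pytest.raises(FitConfigurationError):
            FitConfig(free_parameters=("not_a_parameter",))
        with pytest.raises(FitConfigurationError):
            FitConfig(bounds={"lam": (2.0, 1.0)})

    def test_gof_reported_per_series(self, truth, noiseless_obs):
        obs, _ = noiseless_obs
        config = light_fit_config(("lam",), {"lam": (1e-3, 1.0)}, n_temps=5,
                                  steps_per_temp=8)
        result = fit_parameters(obs, config, truth.init, truth.params, truth.options)
        assert set(result.gof) == {"B", "D", "ratio"}
        for r2, _p in result.gof.values():
            assert r2 > 0.99


class TestMoreDataHelps:
    def test_nine_time_points_not_worse_than_five(self, truth):
        """Median recovery error does not grow when sampling is denser.

        A Monte-Carlo comparison over 60 paired datasets (noise draws are
        shared at the five common sampling times); fits use the cheap
        zero-temperature simplex path since the objective is unimodal in
        this one-parameter problem.
        """
        from microloop import parameter_recovery_experiment

        config = light_fit_config(
            ("nu_mu_B",),
            {"nu_mu_B": (1e-2, 1e2)},
            n_temps=0,
            steps_per_temp=0,
            polish_xatol=1e-4,
            polish_fatol=1e-8,
        )
        design5 = SyntheticDesign(noise_cv=0.2, rng_seed=0)
        design9 = SyntheticDesign(
            sample_times=tuple(np.linspace(0.0, 28.0, 9)), noise_cv=0.2, rng_seed=0
        )
        report5 = parameter_recovery_experiment(truth, design5, config, n_datasets=60, seed=1)
        report9 = parameter_recovery_experiment(truth, design9, config, n_datasets=60, seed=1)
        err5 = report5.median_abs_rel_error()["nu_mu_B"]
        err9 = report9.median_abs_rel_error()["nu_mu_B"]
        assert err9 <= err5 + 1e-12
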