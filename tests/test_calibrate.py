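import numpy as np
import pytest

from pisaster_deb import (
    FixtureSpec,
    ObservationTable,
    arrhenius_scaled,
    fit_arrhenius_TA,
    fit_functional_response,
    fit_p_M_starv,
    fit_shape_coefficient,
    generate,
    grid_search_tpc,
)

T_12C = 285.15


class TestFunctionalResponseFit:
    def test_noiseless_recovery(self):
        X = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 80.0])
        obs = ObservationTable("feeding", X, X / (X + 10.0))
        fit = fit_functional_response(obs)
        assert fit.estimate == pytest.approx(10.0, abs=1e-6)
        assert fit.rmse < 1e-9

    def test_saturated_responses_error_path(self):
        X = np.array([5.0, 11.0, 21.0, 32.0, 48.0])
        obs = ObservationTable("feeding", X, np.ones_like(X))
        with pytest.raises(RuntimeError):
            fit_functional_response(obs)

    def test_closed_loop_recovery_within_2se(self, params):
        spec = FixtureSpec(role="feeding", seed=1, truth={"X_K": 13.9},
                           noise_sd=0.05, n_rep=4)
        obs = generate(spec, params)
        fit = fit_functional_response(obs)
        assert abs(fit.estimate - 13.9) <= 2 * fit.se

    def test_needs_enough_densities(self):
        X = np.array([5.0, 5.0, 11.0, 11.0, 21.0])
        obs = ObservationTable("feeding", X, X / (X + 10.0))
        with pytest.raises(ValueError):
            fit_functional_response(obs)


class TestArrheniusFit:
    def test_noiseless_pure_arrhenius(self):
        T = np.array([283.15, 287.15, 291.15, 293.15])
        rate = np.exp(-6000.0 / T) / np.exp(-6000.0 / T).max()
        fit = fit_arrhenius_TA(ObservationTable("tpc", T, rate))
        assert fit.estimate == pytest.approx(6000.0, rel=1e-9)

    def test_constant_rates_give_zero_slope(self):
        T = np.array([283.15, 287.15, 291.15, 293.15])
        fit = fit_arrhenius_TA(ObservationTable("tpc", T, np.full(4, 0.5)))
        assert fit.estimate == pytest.approx(0.0, abs=1e-9)

    def test_window_must_contain_data(self):
        T = np.array([283.15, 287.15, 291.15])
        obs = ObservationTable("tpc", T, np.array([0.3, 0.5, 0.8]))
        with pytest.raises(ValueError):
            fit_arrhenius_TA(obs, T_window=(300.0, 310.0))

    def test_closed_loop_recovery_within_2se(self, params):
        spec = FixtureSpec(role="tpc", seed=2, truth={"T_A": 6000.0,
                                                      "tpc_form": "arrhenius"},
                           noise_sd=0.05, n_rep=4)
        obs = generate(spec, params)
        fit = fit_arrhenius_TA(obs)
        assert abs(fit.estimate - 6000.0) <= 2 * fit.se


class TestTPCGridSearch:
    def test_in_grid_truth_recovered_exactly(self, params):
        T = np.array([283.15, 287.15, 291.15, 293.15, 297.15, 299.15])
        rate = np.asarray(arrhenius_scaled(T, params))
        obs = ObservationTable("tpc", T, rate)
        bounds = {
            "T_L": (278.0, 282.0), "T_H": (295.0, 299.0),
            "T_AL": (21000.0, 41000.0), "T_AH": (180000.0, 200000.0),
        }
        res = grid_search_tpc(obs, T_A=params.T_A, bounds=bounds, resolution=3,
                              params=params)
        assert res.rmse == pytest.approx(0.0, abs=1e-12)
        assert (res.T_L, res.T_H) == (280.0, 297.0)
        assert (res.T_AL, res.T_AH) == (31000.0, 190000.0)

    def test_objective_invariant_to_rate_rescaling(self, params):
        T = np.array([283.15, 287.15, 291.15, 293.15, 297.15, 299.15])
        rate = np.asarray(arrhenius_scaled(T, params)) * 0.9
        bounds = {"T_L": (278.0, 282.0), "T_H": (295.0, 299.0),
                  "T_AL": (21000.0, 41000.0), "T_AH": (180000.0, 200000.0)}
        a = grid_search_tpc(ObservationTable("tpc", T, rate), params.T_A,
                            bounds, 3, params)
        b = grid_search_tpc(ObservationTable("tpc", T, rate / 3.0), params.T_A,
                            bounds, 3, params)
        assert a.rmse == pytest.approx(b.rmse, rel=1e-12)
        assert (a.T_L, a.T_H, a.T_AL, a.T_AH) == (b.T_L, b.T_H, b.T_AL, b.T_AH)

    def test_single_temperature_warns_flat_objective(self, params):
        obs = ObservationTable("tpc", np.full(3, 287.15), np.array([0.5, 0.52, 0.48]))
        bounds = {"T_L": (278.0, 282.0), "T_H": (295.0, 299.0),
                  "T_AL": (21000.0, 41000.0), "T_AH": (180000.0, 200000.0)}
        with pytest.warns(RuntimeWarning):
            grid_search_tpc(obs, params.T_A, bounds, 2, params)

    def test_cell_cap_enforced(self, params):
        T = np.array([283.15, 287.15, 291.15])
        obs = ObservationTable("tpc", T, np.array([0.3, 0.5, 0.8]))
        with pytest.raises(ValueError, match="cap"):
            grid_search_tpc(obs, params.T_A, resolution=50, params=params)

    def test_noisy_recovery_of_curve_shape(self, params):
        spec = FixtureSpec(role="tpc", seed=3, noise_sd=0.1, n_rep=4)
        obs = generate(spec, params)
        bounds = {"T_L": (276.0, 286.0), "T_H": (292.0, 302.0),
                  "T_AL": (11000.0, 51000.0), "T_AH": (100000.0, 280000.0)}
        res = grid_search_tpc(obs, T_A=params.T_A, bounds=bounds, resolution=6,
                              params=params)
        grid = np.linspace(276.0, 302.0, 80)
        fitted = params.replace(T_L=res.T_L, T_H=res.T_H, T_AL=res.T_AL,
                                T_AH=res.T_AH)
        curve_err = np.sqrt(np.mean(
            (np.asarray(arrhenius_scaled(grid, fitted))
             - np.asarray(arrhenius_scaled(grid, params))) ** 2
        ))
        assert curve_err < 0.1


class TestStarvationFit:
    def test_noiseless_recovery(self, params, marks):
        spec = FixtureSpec(role="starvation", seed=10,
                           truth={"p_M_starv": 11.5}, noise_sd=0.0, n_rep=1)
        obs = generate(spec, params)
        fit = fit_p_M_starv(obs, params, T=T_12C, marks=marks)
        assert fit.mean == pytest.approx(11.5, rel=0.01)

    def test_multi_individual_recovery(self, params, marks):
        """Truths drawn in [8, 15]; estimates stay in band, mean within 15%."""
        spec = FixtureSpec(role="starvation", seed=11,
                           truth={"p_M_starv_range": (8.0, 15.0)},
                           noise_sd=2.0, n_rep=6)
        obs = generate(spec, params)
        fit = fit_p_M_starv(obs, params, T=T_12C, marks=marks)
        truths = np.array(obs.meta["truth"]["p_M_starv"])
        ests = np.array(list(fit.estimates.values()))
        assert np.all((ests > 7.0) & (ests < 16.0))
        assert abs(fit.mean - truths.mean()) < 0.15 * truths.mean()

    def test_increasing_weights_hit_bracket_edge(self, params, marks):
        days = np.array([0.0, 30.0, 60.0, 90.0])
        W = np.array([100.0, 101.0, 102.0, 103.0])
        obs = ObservationTable("starvation", days, W,
                               individual=np.array(["a"] * 4))
        with pytest.warns(RuntimeWarning, match="bracket"):
            fit_p_M_starv(obs, params, T=T_12C, marks=marks)

    def test_monotone_in_loss_rate(self, params, marks):
        """Faster observed weight loss yields a larger maintenance estimate."""
        days = np.array([0.0, 60.0, 120.0, 200.0, 300.0])
        results = []
        for slope in (0.06, 0.15):
            W = 100.0 - slope * days
            obs = ObservationTable("starvation", days, W,
                                   individual=np.array(["x"] * days.size))
            fit = fit_p_M_starv(obs, params, T=T_12C, marks=marks)
            results.append(fit.mean)
        assert results[1] > results[0]


class TestShapeCoefficientFit:
    def test_noiseless_recovery(self, rng):
        L = rng.uniform(2.0, 18.0, 40)
        obs = ObservationTable("shape", L, (0.59 * L) ** 3)
        fit = fit_shape_coefficient(obs)
        assert fit.estimate == pytest.approx(0.59, abs=1e-9)

    def test_single_repeated_point_rejected(self):
        L = np.full(12, 5.0)
        with pytest.raises(ValueError):
            fit_shape_coefficient(ObservationTable("shape", L, (0.59 * L) ** 3))

    def test_nonpositive_data_rejected(self, rng):
        L = rng.uniform(2.0, 18.0, 12)
        W = (0.59 * L) ** 3
        L[0] = -1.0
        with pytest.raises(ValueError):
            fit_shape_coefficient(ObservationTable("shape", L, W))

    def test_closed_loop_recovery_within_2se(self, params):
        spec = FixtureSpec(role="shape", seed=4, truth={"delta_post": 0.59},
                           noise_sd=0.10, n_rep=457)
        obs = generate(spec, params)
        fit = fit_shape_coefficient(obs)
        assert abs(fit.estimate - 0.59) <= 2 * fit.se


class TestObservationTable:
    def test_role_checked(self):
        with pytest.raises(ValueError):
            ObservationTable("unknown", np.arange(3.0), np.arange(3.0))

    def test_minimum_rows(self):
        with pytest.raises(ValueError):
            ObservationTable("feeding", np.array([1.0]), np.array([0.5]))

    def test_scaled_response_band(self):
        with pytest.raises(ValueError):
            ObservationTable("feeding", np.arange(4.0) + 1, np.array([0.1, 0.5, 0.9, 1.5]))

    def test_wrong_role_passed_to_fit(self, params):
        obs = ObservationTable("tpc", np.array([283.0, 287.0, 291.0, 295.0]),
                               np.array([0.2, 0.4, 0.7, 1.0]))
        with pytest.raises(ValueError):
            fit_functional_response(obs)
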