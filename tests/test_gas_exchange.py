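"""Optimal-stomata model components."""

import math

import numpy as np
import pandas as pd
import pytest

from cambiosim.env_soil import MINERAL_SOIL, PEAT_SOIL, swc_from_wtd
from cambiosim.gas_exchange import (OSMConstants, OSMParams, acclim_update,
                                    assimilation, krl_from_sapflow, ksr,
                                    lag_shift, leaf_temperature, light_response,
                                    mwue, optimal_conductance, respiration,
                                    season_onset, transpiration)

C = OSMConstants()
P = OSMParams()


class TestLeafTemperature:
    @pytest.mark.parametrize("t, i, expected", [(10, 0, 10), (10, 1500, 11), (20, 750, 20.5)])
    def test_linear_radiative_load(self, t, i, expected):
        assert leaf_temperature(t, i) == pytest.approx(expected)

    def test_never_below_air_temperature(self):
        i = np.linspace(0, 2000, 50)
        assert np.all(leaf_temperature(5.0, i) >= 5.0)


class TestRespiration:
    def test_reference_value_at_zero(self):
        assert respiration(0.0, C) == pytest.approx(C.R0)

    def test_q10_doubling_rule(self):
        for t in (-5.0, 3.0, 17.0):
            assert respiration(t + 10, C) / respiration(t, C) == pytest.approx(C.Q10)

    def test_closed_form_at_25(self):
        assert respiration(25.0, C) == pytest.approx(7.30064082002395e-07, rel=1e-12)


class TestAcclimation:
    def test_fixed_point(self):
        s = acclim_update(10.0, 10.0, 0.0, 1800.0, C)
        assert s == pytest.approx(10.0)

    def test_exponential_relaxation(self):
        # constant forcing: |S - T_l| must decay with e-folding tau_S
        s, t_l = -5.0, 12.0
        n_steps = int(C.tau_S_seconds / 1800)
        for _ in range(n_steps):
            s = acclim_update(s, t_l, 0.0, 1800.0, C)
        assert abs(s - t_l) == pytest.approx(abs(-5.0 - t_l) / math.e, rel=1e-9)

    def test_matches_rk4_oracle_on_sinusoid(self):
        # fine-step RK4 of dS/dt = (T_l - S)/tau on a sinusoidal T_l
        dt, n = 1800.0, 400
        t_air = 10 + 8 * np.sin(2 * np.pi * np.arange(n) / 48)
        s_model = np.empty(n)
        s_model[0] = t_air[0]
        for i in range(1, n):
            s_model[i] = acclim_update(s_model[i - 1], t_air[i - 1], 0.0, dt, C)
        tau = C.tau_S_seconds
        s_ref = t_air[0]
        h = dt / 100
        refs = [s_ref]
        for i in range(n - 1):
            for _ in range(100):
                k1 = (t_air[i] - s_ref) / tau
                k2 = (t_air[i] - (s_ref + 0.5 * h * k1)) / tau
                k3 = (t_air[i] - (s_ref + 0.5 * h * k2)) / tau
                k4 = (t_air[i] - (s_ref + h * k3)) / tau
                s_ref += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            refs.append(s_ref)
        assert np.allclose(s_model, refs, atol=1e-9)


class TestLightResponse:
    def test_zero_at_threshold_and_darkness(self):
        assert light_response(800.0, C.S0, P, C) == 0.0
        assert light_response(0.0, 15.0, P, C) == 0.0

    def test_saturates_at_gamma(self):
        f = light_response(1e12, 15.0, P, C)
        assert f == pytest.approx(P.gamma, rel=1e-3)
        assert f < P.gamma

    def test_hand_arithmetic(self):
        # iota = 0.1 requires S - S0 = 0.1/c
        p = OSMParams(c=0.1, gamma=2e-3)
        f = light_response(100.0, C.S0 + 1.0, p, C)
        i, g, ppfd = 0.1, 2e-3, 100e-6
        assert f == pytest.approx(i * g * ppfd / (i * ppfd + g), rel=1e-12)


class TestKsr:
    def test_mineral_saturation_returns_multiplier(self):
        assert ksr(MINERAL_SOIL.theta_sat, "mineral", P, MINERAL_SOIL) == pytest.approx(P.xi_m)

    def test_mineral_increasing_in_theta(self):
        theta = np.linspace(0.05, MINERAL_SOIL.theta_sat, 100)
        k = ksr(theta, "mineral", P, MINERAL_SOIL)
        assert np.all(np.diff(k) > 0)

    def test_peat_plateau_value_at_optimum(self):
        th_lo = swc_from_wtd(P.sigma_star - 15.0, PEAT_SOIL)
        th_hi = swc_from_wtd(P.sigma_star + 15.0, PEAT_SOIL)
        th_star = swc_from_wtd(P.sigma_star, PEAT_SOIL)
        k_minus = P.eta_m * ((2 * th_star - th_lo) / PEAT_SOIL.theta_sat) ** P.eta_p
        k_plus = P.xi_m * (th_hi / PEAT_SOIL.theta_sat) ** P.xi_p
        expected = 0.5 * (k_minus + k_plus)
        assert ksr(P.sigma_star, "peat", P, PEAT_SOIL) == pytest.approx(expected)

    def test_peat_branchwise_against_grid_oracle(self):
        sigma = np.linspace(4.0, 75.0, 200)
        k = np.asarray(ksr(sigma, "peat", P, PEAT_SOIL))
        theta = swc_from_wtd(sigma, PEAT_SOIL)
        th_star = swc_from_wtd(P.sigma_star, PEAT_SOIL)
        for s, th, kv in zip(sigma, theta, k):
            if s < P.sigma_star - 15:
                expect = P.eta_m * ((2 * th_star - th) / PEAT_SOIL.theta_sat) ** P.eta_p
            elif s > P.sigma_star + 15:
                expect = P.xi_m * (th / PEAT_SOIL.theta_sat) ** P.xi_p
            else:
                expect = ksr(P.sigma_star, "peat", P, PEAT_SOIL)
            assert kv == pytest.approx(expect)

    def test_peat_unimodal_shape(self):
        # rising on the waterlogged flank, flat plateau, falling on the dry flank
        wet = np.asarray(ksr(np.linspace(0.0, P.sigma_star - 16, 50), "peat", P, PEAT_SOIL))
        dry = np.asarray(ksr(np.linspace(P.sigma_star + 16, 100, 50), "peat", P, PEAT_SOIL))
        assert np.all(np.diff(wet) >= 0)
        assert np.all(np.diff(dry) <= 0)

    def test_total_waterlogging_floor(self):
        # an (extreme) optimum deep enough that saturation means 2 theta* < theta
        p = OSMParams(sigma_star=150.0)
        th_star = swc_from_wtd(p.sigma_star, PEAT_SOIL)
        assert 2 * th_star < PEAT_SOIL.theta_sat  # sigma=0 saturates the peat
        k = ksr(0.0, "peat", p, PEAT_SOIL)
        assert 0 < k <= 1e-9


class TestKrl:
    def test_constant_series(self):
        j = np.full(100, 2.5)
        expected = 2.5 / (3.0 * C.dpsi_sl_max) / C.k0
        assert krl_from_sapflow(j, 3.0, C) == pytest.approx(expected)

    def test_rho_scaling(self):
        j = np.array([1.0, 4.0, 2.0])
        assert krl_from_sapflow(j, 2.0, C) == pytest.approx(krl_from_sapflow(j, 1.0, C) / 2)

    def test_ignores_missing_values(self):
        rng = np.random.default_rng(1)
        j = rng.uniform(0.1, 5.0, 200)
        j[::7] = np.nan
        expected = np.nanmax(j) / (2.0 * C.dpsi_sl_max) / C.k0
        assert krl_from_sapflow(j, 2.0, C) == pytest.approx(expected)

    def test_rejects_all_missing(self):
        with pytest.raises(ValueError):
            krl_from_sapflow(np.full(10, np.nan), 1.0, C)


class TestMwue:
    def test_reference_point(self):
        assert mwue(1.0, P) == pytest.approx(10.0 ** P.z0)

    def test_decade_step(self):
        assert mwue(10.0, P) == pytest.approx(10.0 ** (P.z0 + P.z1))

    def test_decreasing_in_conductance(self):
        k = np.logspace(-3, 1, 100)
        lam = mwue(k, P)
        assert np.all(np.diff(lam) < 0)


class TestOptimalConductance:
    def test_darkness_floor(self):
        assert optimal_conductance(0.0, 1e-7, 1e-3, 0.3, C) == C.g0

    def test_large_vpd_floor(self):
        assert optimal_conductance(1e-3, 0.0, 1e-2, 1e9, C) == C.g0

    def test_marginal_condition_at_interior_optimum(self):
        # with R = 0 the optimum g* satisfies dA/dg = 1.6 lambda D for
        # A = g f C_a / (g + f); checked by numerical optimisation
        f, lam, d = 8e-4, 8e-4, 0.3
        g_star = optimal_conductance(f, 0.0, lam, d, C)
        assert g_star > C.g0

        def objective(g):
            return g * f * C.C_a / (g + f) - lam * 1.6 * g * d

        grid = np.linspace(1e-6, 20 * g_star, 300001)
        best = grid[np.argmax(objective(grid))]
        assert g_star == pytest.approx(best, abs=grid[1] - grid[0])

    def test_respiration_above_supply_floors(self):
        # C_a - R/f <= 0: no positive-assimilation solution
        g = optimal_conductance(1e-6, 1.0, 1e-3, 0.3, C)
        assert g == C.g0


class TestFluxes:
    def test_transpiration_bilinear(self):
        assert transpiration(2e-3, 0.0) == 0.0
        assert transpiration(C.g0, 0.5) == pytest.approx(1.6 * C.g0 * 0.5)
        assert transpiration(4e-3, 0.6) == pytest.approx(4 * transpiration(2e-3, 0.3))

    def test_night_respiration(self):
        r = 2e-7
        assert assimilation(C.g0, 0.0, r, C) == pytest.approx(-r)

    def test_demand_limited_limit(self):
        f = 1e-3
        a = assimilation(1e3, f, 0.0, C)
        assert a == pytest.approx(f * C.C_a, rel=1e-5)

    def test_matches_internal_co2_balance_oracle(self):
        # solve supply g(C_a - C_i) = demand f C_i - R for C_i directly
        g, f, r = 2e-3, 7e-4, 3e-7
        c_i = (g * C.C_a + r) / (g + f)
        expected = g * (C.C_a - c_i)
        assert assimilation(g, f, r, C) == pytest.approx(expected, rel=1e-12)

    def test_gross_form_without_respiration(self):
        g, f = 2e-3, 7e-4
        a = assimilation(g, f, 5e-7, C, include_respiration=False)
        assert a == pytest.approx(g * f * C.C_a / (g + f))


class TestLagShift:
    def test_zero_lag_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(lag_shift(x, 0.0, 15.0), x)

    def test_one_step_shift_oracle(self):
        x = np.arange(10.0)
        # beta*height = 30 min = one step
        out = lag_shift(x, 2.0, 15.0)
        assert np.array_equal(out[:-1], x[1:])
        assert np.isnan(out[-1])

    def test_shift_rounding_to_whole_steps(self):
        x = np.arange(20.0)
        out = lag_shift(x, 5.25, 15.4)  # 80.85 min -> 3 steps
        assert np.array_equal(out[:-3], x[3:])

    def test_rejects_lag_beyond_series(self):
        with pytest.raises(ValueError):
            lag_shift(np.arange(3.0), 60.0, 10.0)


class TestSeasonOnset:
    def test_linear_ramp_crossing(self):
        idx = pd.date_range("2021-03-01", periods=10 * 48, freq="1800s")
        s = np.linspace(-5, 5, len(idx))
        doy = season_onset(s, idx)
        first = idx[np.argmax(s >= 0)].dayofyear
        assert doy == first

    def test_no_crossing_sentinel(self):
        idx = pd.date_range("2021-03-01", periods=48, freq="1800s")
        assert season_onset(np.full(48, -3.0), idx) is None

    def test_noisy_series_matches_scan(self):
        rng = np.random.default_rng(11)
        idx = pd.date_range("2021-04-01", periods=20 * 48, freq="1800s")
        s = np.linspace(-3, 3, len(idx)) + rng.normal(0, 0.5, len(idx))
        expected = None
        for i, v in enumerate(s):
            if v >= 0:
                expected = idx[i].dayofyear
                break
        assert season_onset(s, idx) == expected
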