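"""Irreversible cambial growth and the whole-tree simulator.

Growth of one radial file is the product of three factors:

* a Lockhart expansion rate p = phi(T) (psi_cam - psi_0), zero below
  the turgor threshold psi_0;
* an enzyme-kinetic extensibility phi(T) with activation enthalpy and a
  high-temperature deactivation described by an enthalpy/entropy pair
  (Johnson-Eyring-Williams form), zero below the temperature threshold
  T_0;
* a Gompertz-derivative phenology envelope N_c(t) for the number of
  actively dividing cambial cells, clocked in hours from the seasonal
  start day.

Cell number converts to radial increment through the mature tracheid
diameter; cells double their volume before dividing, so the division
rate is g_f * p / ln 2 with a geometry factor g_f (3 for isotropic
linear expansion, configurable).

Three model variants are supported: the full model (FM), AM1 with the
phenology envelope frozen at its cell-number ceiling, and AM2 with the
biophysical rate frozen at phi_max * 1 MPa (pure phenology).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import env_soil, gas_exchange, stem_water
from .env_soil import STEP_SECONDS, SoilConstants
from .gas_exchange import OSMConstants, OSMParams
from .stem_water import StemConstants, TreeAttributes

R_GAS = 8.3145  # J mol-1 K-1

MODES = ("fm", "am1", "am2")


@dataclass(frozen=True)
class GrowthParams:
    """Estimated growth parameters (mid-prior defaults).

    ``psi_0`` (MPa, < 0) and ``t_0`` (degC) are the turgor and
    temperature thresholds of growth; ``dh_a`` (J mol-1, < 0), ``dh_d``
    (J mol-1) and ``ds_d`` (J mol-1 K-1) the enzyme-kinetic enthalpies/
    entropy; ``phi_max`` (MPa-1 h-1) the extensibility scale; ``b``
    (unitless displacement) and ``tau_g`` (h, inverse rate) the Gompertz
    phenology coefficients.
    """

    psi_0: float = -0.7
    t_0: float = 7.0
    dh_a: float = -7.3e4
    dh_d: float = 3.525e5
    ds_d: float = 1050.0
    phi_max: float = 1.05e-2
    b: float = 6.75
    tau_g: float = 400.0

    def __post_init__(self) -> None:
        if self.phi_max <= 0 or self.tau_g <= 0 or self.b <= 0:
            raise ValueError("phi_max, tau_g and b must be positive")


@dataclass(frozen=True)
class GrowthConstants:
    """Fixed growth constants."""

    a: float = 5.3544e12        # extensibility scaling, K-1
    d_c_bar: float = 0.035      # mature tracheid radial diameter, mm
    n_c_max: float = 8.85       # maximum active cambial cells
    time_unity: float = 1.0     # h, unit-carrier of the phenology curve
    g_f: float = 3.0            # division geometry factor (3 or 1)
    start_doy: int = 132        # seasonal clock start for the growth model


def extensibility(t_kelvin, params: GrowthParams, consts: GrowthConstants = GrowthConstants()):
    """Cell-wall extensibility phi(T) (MPa-1 h-1).

    phi = phi_max * a * T * exp(dH_A/(R T))
          / (1 + exp(dS_D/R - dH_D/(R T)))           for T >= T_0,
    and 0 below the threshold.  With dH_A < 0 the numerator is
    Arrhenius-increasing; the denominator switches on deactivation
    around T = dH_D/dS_D, making phi unimodal above T_0.
    """
    t = np.asarray(t_kelvin, dtype=float)
    t0_k = params.t_0 + 273.15
    safe_t = np.where(t > 0, t, 1.0)
    numer = consts.a * safe_t * np.exp(params.dh_a / (R_GAS * safe_t))
    denom = 1.0 + np.exp(params.ds_d / R_GAS - params.dh_d / (R_GAS * safe_t))
    phi = np.where(t >= t0_k, params.phi_max * numer / denom, 0.0)
    return phi if phi.shape else float(phi)


def expansion_rate(psi_cam_mpa, t_kelvin, params: GrowthParams,
                   consts: GrowthConstants = GrowthConstants()):
    """Lockhart relative expansion rate p (h-1).

    p = phi(T) * (psi_cam - psi_0) above the turgor threshold, else 0.
    Growth therefore requires jointly T >= T_0 and psi_cam >= psi_0.
    """
    phi = np.asarray(extensibility(t_kelvin, params, consts), dtype=float)
    surplus = np.maximum(np.asarray(psi_cam_mpa, dtype=float) - params.psi_0, 0.0)
    p = phi * surplus
    return p if p.shape else float(p)


def active_cells(t_hours, params: GrowthParams, consts: GrowthConstants = GrowthConstants()):
    """Phenology envelope N_c(t): derivative-of-Gompertz cell number.

    N_c(t) = N_c_max (b T_u / tau_G) exp(-b e^(-t/tau_G) - t/tau_G),
    with the time unity T_u = 1 h.  Peaks at t* = tau_G ln b; its
    integral over [0, inf) is N_c_max T_u (1 - e^(-b)) cell-hours.
    Zero for t < 0 (before the seasonal clock starts).
    """
    t = np.asarray(t_hours, dtype=float)
    x = t / params.tau_g
    n = consts.n_c_max * params.b * consts.time_unity / params.tau_g \
        * np.exp(-params.b * np.exp(-x) - x)
    n = np.where(t >= 0.0, n, 0.0)
    return n if n.shape else float(n)


def growth_rate(t_hours, psi_cam_mpa, t_kelvin, params: GrowthParams,
                consts: GrowthConstants = GrowthConstants(), mode: str = "fm"):
    """Instantaneous radial growth rate (mm h-1) under a model variant."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    conv = consts.g_f * consts.d_c_bar / math.log(2.0)
    if mode == "fm":
        n_c = active_cells(t_hours, params, consts)
        p = expansion_rate(psi_cam_mpa, t_kelvin, params, consts)
    elif mode == "am1":
        n_c = np.where(np.asarray(t_hours, dtype=float) >= 0, consts.n_c_max, 0.0)
        p = expansion_rate(psi_cam_mpa, t_kelvin, params, consts)
    else:  # am2: pure phenology, rate frozen at phi_max * 1 MPa
        n_c = active_cells(t_hours, params, consts)
        p = params.phi_max * 1.0
    out = conv * np.asarray(n_c, dtype=float) * np.asarray(p, dtype=float)
    return out if np.asarray(out).shape else float(out)


def growth_increment(t_hours, psi_cam_mpa, t_kelvin, dt_seconds: float,
                     params: GrowthParams, consts: GrowthConstants = GrowthConstants(),
                     mode: str = "fm"):
    """Growth over one step (mm), rectangle rule at the step start."""
    rate = growth_rate(t_hours, psi_cam_mpa, t_kelvin, params, consts, mode)
    out = np.asarray(rate, dtype=float) * dt_seconds / 3600.0
    return out if np.asarray(out).shape else float(out)


def season_hours(timestamps, start_doy: int) -> np.ndarray:
    """Hours since 00:00 of the seasonal start day of each record's year.

    Negative before the start day; the growth model treats those times
    as dormant (N_c = 0).
    """
    ts = pd.DatetimeIndex(timestamps)
    years = ts.year.to_numpy()
    t_ns = ts.asi8.astype(np.int64)
    out = np.empty(len(ts), dtype=float)
    for year in np.unique(years):
        origin = (pd.Timestamp(int(year), 1, 1).value
                  + (start_doy - 1) * 86400 * 10 ** 9)
        m = years == year
        out[m] = (t_ns[m] - origin) / 3.6e12
    return out


def simulate_arrays(drivers: pd.DataFrame, tree: TreeAttributes,
                    osm_params: OSMParams, growth_params: GrowthParams,
                    soil: SoilConstants,
                    osm_consts: OSMConstants = OSMConstants(),
                    stem_consts: StemConstants = StemConstants(),
                    growth_consts: GrowthConstants = GrowthConstants(),
                    j_obs=None, k_rl: float | None = None, mode: str = "fm",
                    s_init: float | None = None) -> tuple[dict, pd.DatetimeIndex]:
    """Array-valued core of :func:`simulate_srd` (no DataFrame overhead).

    Returns ``(columns, timestamps)``; used directly by the likelihood
    evaluation, where the trace is rebuilt tens of thousands of times.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    ts = pd.DatetimeIndex(drivers.index)
    if len(ts) < 2:
        raise ValueError("driver series too short")
    steps = np.unique(np.diff(ts.asi8)) / 1e9
    if steps.size != 1 or steps[0] != STEP_SECONDS:
        bad = ts[1 + int(np.argmax(np.diff(ts.asi8) / 1e9 != STEP_SECONDS))]
        raise ValueError(f"driver grid is not a regular 30-min grid (first offence at {bad})")
    dt = float(STEP_SECONDS)

    t_air = drivers["T_degC"].to_numpy(dtype=float)
    ppfd = drivers["ppfd_umol_m2_s"].to_numpy(dtype=float)
    vpd = drivers["vpd_mol_m3"].to_numpy(dtype=float)
    rain = drivers["rain_mm"].to_numpy(dtype=float)
    n = t_air.size

    # --- soil water state -------------------------------------------------
    if soil.site_kind == "peat":
        sigma = drivers["wtd_cm"].to_numpy(dtype=float)
        theta = np.asarray(env_soil.swc_from_wtd(sigma, soil), dtype=float)
        k_sr = np.asarray(gas_exchange.ksr(sigma, "peat", osm_params, soil), dtype=float)
    else:
        theta = drivers["swc_m3_m3"].to_numpy(dtype=float)
        k_sr = np.asarray(gas_exchange.ksr(theta, "mineral", osm_params, soil), dtype=float)
    psi_s = np.asarray(env_soil.psi_soil(theta, soil, osm_params.xi_p), dtype=float)

    # --- acclimation state: exact exponential filter ----------------------
    t_leaf = np.asarray(gas_exchange.leaf_temperature(t_air, ppfd, osm_consts), dtype=float)
    decay = math.exp(-dt / osm_consts.tau_S_seconds)
    s0 = t_leaf[0] if s_init is None else float(s_init)
    s = np.empty(n)
    s[0] = s0
    if n > 1:
        # S[i+1] = decay*S[i] + (1-decay)*T_l[i]
        s[1:] = lfilter([1.0 - decay], [1.0, -decay], t_leaf[:-1], zi=[decay * s0])[0]

    # --- stomatal optimum, fluxes ----------------------------------------
    f = np.asarray(gas_exchange.light_response(ppfd, s, osm_params, osm_consts), dtype=float)
    resp = np.asarray(gas_exchange.respiration(t_leaf, osm_consts), dtype=float)
    if j_obs is not None:
        j_obs = np.asarray(j_obs, dtype=float)
        if j_obs.size != n:
            raise ValueError("sap-flow series is not aligned with the drivers")
        k_rl = gas_exchange.krl_from_sapflow(j_obs, tree.rho, osm_consts)
    elif k_rl is None:
        raise ValueError("closed-loop runs need an explicit k_rl (multiples of k0)")
    d_safe = np.maximum(vpd, 1e-9)

    k_sl = 1.0 / (1.0 / k_sr + 1.0 / k_rl)
    lam = np.asarray(gas_exchange.mwue(k_sl, osm_params), dtype=float)
    g_sigma = np.asarray(gas_exchange.optimal_conductance(f, resp, lam, d_safe, osm_consts),
                         dtype=float)
    e_mod = np.asarray(gas_exchange.transpiration(g_sigma, vpd), dtype=float)
    a_mod = np.asarray(gas_exchange.assimilation(g_sigma, f, resp, osm_consts), dtype=float)

    # --- breast-height flow per leaf area ---------------------------------
    if j_obs is not None:
        j_leaf = j_obs / tree.rho
        j_leaf = pd.Series(j_leaf).ffill().fillna(0.0).to_numpy()
    else:
        shift = gas_exchange.lag_steps(osm_params.beta, tree.height, dt)
        j_leaf = np.empty(n)
        if shift > 0:
            j_leaf[:shift] = e_mod[0]
            j_leaf[shift:] = e_mod[:n - shift]
        else:
            j_leaf[:] = e_mod

    # --- bark capacitor and cambial potential ------------------------------
    q_b = stem_water.bark_series(rain, dt, stem_consts, tree.bark_thickness)
    k_sb_abs = np.asarray(
        stem_water.ksb(k_sr * osm_consts.k0, k_rl * osm_consts.k0, tree, stem_consts),
        dtype=float)
    psi_cam = np.asarray(
        stem_water.cambium_potential(psi_s, j_leaf, k_sb_abs, q_b, stem_consts,
                                     tree.bark_thickness), dtype=float)

    # --- reversible and irreversible radius --------------------------------
    d_ela = (psi_cam - psi_cam[0]) * tree.d0 / tree.E_moe
    t_season = season_hours(ts, growth_consts.start_doy)
    t_kelvin = t_air + 273.15
    inc = np.asarray(growth_increment(t_season, psi_cam, t_kelvin, dt,
                                      growth_params, growth_consts, mode), dtype=float)
    d_gro = np.concatenate([[0.0], np.cumsum(inc[:-1])])
    d_mod = tree.d0 + d_ela + d_gro

    phi = np.asarray(extensibility(t_kelvin, growth_params, growth_consts), dtype=float)
    if mode == "am2":
        p = np.full(n, growth_params.phi_max)
    else:
        p = np.asarray(expansion_rate(psi_cam, t_kelvin, growth_params, growth_consts),
                       dtype=float)
    n_c = (np.where(t_season >= 0, growth_consts.n_c_max, 0.0) if mode == "am1"
           else np.asarray(active_cells(t_season, growth_params, growth_consts), dtype=float))

    cols = {
        "T_degC": t_air, "ppfd_umol_m2_s": ppfd, "vpd_mol_m3": vpd, "rain_mm": rain,
        "theta": theta, "psi_s": psi_s, "S": s, "f": f, "lambda": lam,
        "k_sr": k_sr, "k_sl": np.broadcast_to(k_sl, (n,)).copy(),
        "g_sigma": g_sigma, "E_mod": e_mod, "A_mod": a_mod, "j_leaf": j_leaf,
        "q_b": q_b, "psi_cam": psi_cam, "phi": phi, "p": p, "N_c": n_c,
        "d_ela": d_ela, "d_gro": d_gro, "d_mod": d_mod,
    }
    return cols, ts


def simulate_srd(drivers: pd.DataFrame, tree: TreeAttributes,
                 osm_params: OSMParams, growth_params: GrowthParams,
                 soil: SoilConstants,
                 osm_consts: OSMConstants = OSMConstants(),
                 stem_consts: StemConstants = StemConstants(),
                 growth_consts: GrowthConstants = GrowthConstants(),
                 j_obs=None, k_rl: float | None = None, mode: str = "fm",
                 s_init: float | None = None) -> pd.DataFrame:
    """Run the coupled model over one driver series for one tree.

    ``drivers`` must carry a DatetimeIndex on an exact 30-min grid and
    columns ``T_degC``, ``ppfd_umol_m2_s``, ``vpd_mol_m3``, ``rain_mm``
    and either ``wtd_cm`` (peat) or ``swc_m3_m3`` (mineral).

    ``j_obs``: observed sap-flow density per sapwood area on the same
    grid (calibration mode); the root-to-leaf conductance is then
    derived from its seasonal maximum.  If omitted the model runs
    closed-loop: breast-height flow is the modelled transpiration
    delayed by the height-dependent lag beta * height, and ``k_rl``
    (a hydraulic trait, in multiples of k0) must be supplied.

    Returns the per-step trace with every intermediate quantity
    (conductances, lambda, g_sigma, E, A, psi_s, q_b, psi_cam, N_c, p,
    phi, d_ela, d_gro, d_mod).
    """
    cols, ts = simulate_arrays(drivers, tree, osm_params, growth_params, soil,
                               osm_consts, stem_consts, growth_consts,
                               j_obs=j_obs, k_rl=k_rl, mode=mode, s_init=s_init)
    return pd.DataFrame(cols, index=ts)


def simulate_srd_reference(drivers: pd.DataFrame, tree: TreeAttributes,
                           osm_params: OSMParams, growth_params: GrowthParams,
                           soil: SoilConstants,
                           osm_consts: OSMConstants = OSMConstants(),
                           stem_consts: StemConstants = StemConstants(),
                           growth_consts: GrowthConstants = GrowthConstants(),
                           j_obs=None, k_rl: float | None = None,
                           mode: str = "fm", n_sub: int = 100) -> pd.DataFrame:
    """Fine-step RK4 reference for the state variables S, q_b and d_gro.

    Integrates the continuous-time ODEs with ``n_sub`` RK4 sub-steps per
    30-min driver step (forcing held constant within a step, as the data
    are defined).  Independent of the production update rules; used to
    bound their discretisation error.  Returns a trace with columns
    ``S``, ``q_b``, ``psi_cam``, ``d_gro`` and ``d_mod`` at step starts.
    """
    base = simulate_srd(drivers, tree, osm_params, growth_params, soil,
                        osm_consts, stem_consts, growth_consts,
                        j_obs=j_obs, k_rl=k_rl, mode=mode)
    ts = base.index
    n = len(ts)
    dt = float(STEP_SECONDS)
    h = dt / n_sub

    t_leaf = gas_exchange.leaf_temperature(
        base["T_degC"].to_numpy(), base["ppfd_umol_m2_s"].to_numpy(), osm_consts)
    rain = base["rain_mm"].to_numpy()
    psi_s = base["psi_s"].to_numpy()
    j_leaf = base["j_leaf"].to_numpy()
    k_sr = base["k_sr"].to_numpy()
    k_rl_mult = _krl_from_ksl(base, k_sr)
    k_sb_abs = np.asarray(stem_water.ksb(
        k_sr * osm_consts.k0, k_rl_mult * osm_consts.k0, tree, stem_consts), dtype=float)
    t_season0 = season_hours(ts, growth_consts.start_doy)
    t_kelvin = base["T_degC"].to_numpy() + 273.15
    tau_s = osm_consts.tau_S_seconds
    tau_b = stem_water.bark_time_constant(stem_consts, tree.bark_thickness)
    eb_over_db0 = stem_consts.E_b / tree.bark_thickness

    s_out = np.empty(n); q_out = np.empty(n); g_out = np.empty(n)
    s = float(t_leaf[0]); q = 0.0; dgro = 0.0
    for i in range(n):
        s_out[i] = s; q_out[i] = q; g_out[i] = dgro
        j_bin = stem_water.bark_influx(rain[i], dt, stem_consts)
        base_psi = (psi_s[i] - j_leaf[i] / k_sb_abs[i]) / 1e6 - stem_consts.dpsi_g
        tl, tk = float(t_leaf[i]), float(t_kelvin[i])
        phi_i = float(extensibility(tk, growth_params, growth_consts))

        def deriv(tau_h, y):
            s_, q_, _ = y
            psi = base_psi + eb_over_db0 * q_
            t_h = t_season0[i] + tau_h
            if mode == "am2":
                p_ = growth_params.phi_max
                n_c = float(active_cells(t_h, growth_params, growth_consts))
            elif mode == "am1":
                p_ = phi_i * max(psi - growth_params.psi_0, 0.0)
                n_c = growth_consts.n_c_max if t_h >= 0 else 0.0
            else:
                p_ = phi_i * max(psi - growth_params.psi_0, 0.0)
                n_c = float(active_cells(t_h, growth_params, growth_consts))
            dgro_dot = growth_consts.g_f * n_c * p_ * growth_consts.d_c_bar / math.log(2.0) / 3600.0
            return np.array([(tl - s_) / tau_s,
                             j_bin - q_ / tau_b,
                             dgro_dot])

        y = np.array([s, q, dgro])
        for k in range(n_sub):
            t0h = (k * h) / 3600.0
            k1 = deriv(t0h, y)
            k2 = deriv(t0h + h / 7200.0, y + 0.5 * h * k1)
            k3 = deriv(t0h + h / 7200.0, y + 0.5 * h * k2)
            k4 = deriv(t0h + h / 3600.0, y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        s, q, dgro = float(y[0]), float(y[1]), float(y[2])

    psi_cam = (psi_s - j_leaf / k_sb_abs) / 1e6 + eb_over_db0 * q_out - stem_consts.dpsi_g
    d_mod = tree.d0 + (psi_cam - psi_cam[0]) * tree.d0 / tree.E_moe + g_out
    return pd.DataFrame({"S": s_out, "q_b": q_out, "psi_cam": psi_cam,
                         "d_gro": g_out, "d_mod": d_mod}, index=ts)


def _krl_from_ksl(base: pd.DataFrame, k_sr: np.ndarray) -> float:
    """Recover the constant k_rl multiple from a trace's k_sl and k_sr."""
    k_sl = base["k_sl"].to_numpy()
    vals = 1.0 / (1.0 / k_sl - 1.0 / k_sr)
    return float(np.median(vals))
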