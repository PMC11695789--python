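"""Relative-sensitivity analysis of growth and assimilation rates.

Evaluates the local elasticity (RSC) of the modelled growth rate (GR)
and net assimilation rate (A) to soil water content and air
temperature, with every other environmental variable held at a fixed
mean state.  Temperature and VPD remain coupled through the saturation
vapour curve at fixed relative humidity, as they are in the field, so
the declining temperature sensitivity of assimilation at high T (rising
evaporative demand) is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import analysis, env_soil
from .cambial_growth import GrowthConstants, GrowthParams, active_cells, extensibility
from .env_soil import MINERAL_SOIL, PEAT_SOIL, SoilConstants
from .gas_exchange import (OSMConstants, OSMParams, assimilation, ksr,
                           leaf_temperature, light_response, mwue,
                           optimal_conductance, respiration)
from .stem_water import StemConstants, TreeAttributes, ksb
from .synthetic_data import default_tree


@dataclass(frozen=True)
class MeanConditions:
    """The fixed mean state around which one input is swept.

    ``drawdown_at_mean`` anchors the viscous soil-to-stem potential
    drawdown (MPa) at the mean soil water state; the implied constant
    sap flow is then held while SWC is swept, so drier soil (lower
    conductance) deepens the drawdown as it does in the field.
    """

    t_mean: float = 15.0            # degC
    i_mean: float = 800.0           # umol m-2 s-1
    rh: float = 0.70
    swc_mean_frac: float = 0.55     # mean SWC as a fraction of theta_sat
    wtd_mean: float = 30.0          # cm, peat
    drawdown_at_mean: float = 0.30  # MPa
    k_rl: float = 0.006             # multiples of k0


def _mean_theta(site_kind: str, soil: SoilConstants, mc: MeanConditions) -> float:
    if site_kind == "peat":
        return float(env_soil.swc_from_wtd(mc.wtd_mean, soil))
    return mc.swc_mean_frac * soil.theta_sat


def _vpd_mol(t_c: float, rh: float) -> float:
    return float(env_soil.vpd_kpa_to_mol_m3(
        env_soil.saturation_vapour_pressure_kpa(t_c) * (1.0 - rh), t_c))


def _hydraulics(theta: float, site_kind: str, osm_p: OSMParams,
                soil: SoilConstants, tree: TreeAttributes,
                osm_c: OSMConstants, stem_c: StemConstants, mc: MeanConditions):
    """k_sr, k_sl (multiples of k0) and absolute k_sb at a soil state."""
    if site_kind == "peat":
        # invert retention is unnecessary: sweep enters through theta only
        k_sr = osm_p.xi_m * (theta / soil.theta_sat) ** osm_p.xi_p
    else:
        k_sr = float(ksr(theta, "mineral", osm_p, soil))
    k_sl = 1.0 / (1.0 / k_sr + 1.0 / mc.k_rl)
    k_sb_abs = float(ksb(k_sr * osm_c.k0, mc.k_rl * osm_c.k0, tree, stem_c))
    return k_sr, k_sl, k_sb_abs


def growth_assimilation_rsc(var: str, site_kind: str = "mineral",
                            osm_params: OSMParams = OSMParams(),
                            growth_params: GrowthParams = GrowthParams(),
                            mc: MeanConditions = MeanConditions(),
                            grid=None, h_rel: float = 1e-3) -> dict:
    """RSC curves of GR and A versus ``var`` ("swc" or "temp").

    Growth is evaluated at the phenology peak (the envelope is a common
    factor and cancels from the elasticity); assimilation uses the
    steady-state acclimation S = T_l.  Returns ``{"gr": RSCCurve, "a":
    RSCCurve}`` with NaN where the output is zero (sensitivity
    undefined, e.g. below the growth thresholds).
    """
    if var not in ("swc", "temp"):
        raise ValueError("var must be 'swc' or 'temp'")
    soil = PEAT_SOIL if site_kind == "peat" else MINERAL_SOIL
    tree = default_tree(site_kind)
    osm_c = OSMConstants() if site_kind == "peat" else OSMConstants(g0=7.5e-5,
                                                                   dpsi_sl_max=2.0e6)
    stem_c = StemConstants()
    gro_c = GrowthConstants()

    theta_bar = _mean_theta(site_kind, soil, mc)
    _, _, k_sb_bar = _hydraulics(theta_bar, site_kind, osm_params, soil, tree,
                                 osm_c, stem_c, mc)
    # constant per-leaf flow implied by the anchored mean drawdown
    e_bar = mc.drawdown_at_mean * 1e6 * k_sb_bar
    n_c_peak = float(active_cells(growth_params.tau_g * math.log(growth_params.b),
                                  growth_params, gro_c))
    conv = gro_c.g_f * n_c_peak * gro_c.d_c_bar / math.log(2.0)

    def psi_cam_at(theta: float) -> float:
        _, _, k_sb = _hydraulics(theta, site_kind, osm_params, soil, tree,
                                 osm_c, stem_c, mc)
        psi_s = float(env_soil.psi_soil(theta, soil, osm_params.xi_p))
        return psi_s / 1e6 - e_bar / k_sb / 1e6 - stem_c.dpsi_g

    def a_at(theta: float, t_c: float) -> float:
        _, k_sl, _ = _hydraulics(theta, site_kind, osm_params, soil, tree,
                                 osm_c, stem_c, mc)
        lam = float(mwue(k_sl, osm_params))
        t_l = float(leaf_temperature(t_c, mc.i_mean, osm_c))
        f = float(light_response(mc.i_mean, t_l, osm_params, osm_c))  # S = T_l
        r = float(respiration(t_l, osm_c))
        d = max(_vpd_mol(t_c, mc.rh), 1e-6)
        g = float(optimal_conductance(f, r, lam, d, osm_c))
        return float(assimilation(g, f, r, osm_c))

    if var == "swc":
        if grid is None:
            grid = (np.linspace(0.10, 0.45, 36) if site_kind == "mineral"
                    else np.linspace(0.45, 0.90, 46))
        t_k_bar = mc.t_mean + 273.15
        phi_bar = float(extensibility(t_k_bar, growth_params, gro_c))

        def gr_fn(theta):
            return conv * phi_bar * max(psi_cam_at(theta) - growth_params.psi_0, 0.0)

        def a_fn(theta):
            return a_at(theta, mc.t_mean)

        return {"gr": analysis.rsc_curve(gr_fn, grid, "swc", h_rel),
                "a": analysis.rsc_curve(a_fn, grid, "swc", h_rel)}

    if grid is None:
        grid = np.arange(5.0, 30.5, 1.0)
    psi_bar = psi_cam_at(theta_bar)
    surplus = max(psi_bar - growth_params.psi_0, 0.0)

    def gr_fn(t_c):
        return conv * float(extensibility(t_c + 273.15, growth_params, gro_c)) * surplus

    def a_fn(t_c):
        return a_at(theta_bar, t_c)

    return {"gr": analysis.rsc_curve(gr_fn, grid, "temp", h_rel),
            "a": analysis.rsc_curve(a_fn, grid, "temp", h_rel)}
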