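"""Cowan-Farquhar-type optimal stomata model (OSM).

Stomatal conductance maximises instantaneous assimilation minus
lambda-weighted transpiration, A(g) - lambda * 1.6 g D, where the
marginal water-use efficiency lambda is itself tied to the whole-tree
soil-to-leaf hydraulic conductance.  The module also carries the slow
photosynthetic-acclimation state S (a first-order filter of leaf
temperature) that gates the light response in spring and autumn.

Unit conventions
----------------
Conductances along the soil-root-leaf chain (k_sr, k_rl, k_sl) are
carried as dimensionless multiples of the reference conductance k0, so
the ratio k_sl/k0 entering the lambda correlation is O(1).  Stomatal
conductance g is in m s-1; D and C_a in mol m-3; fluxes in mol m-2
(all-sided) leaf s-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env_soil import SoilConstants


@dataclass(frozen=True)
class OSMConstants:
    """Fixed constants of the gas-exchange model (site/species level)."""

    C_a: float = 1.753e-2          # atmospheric CO2, mol m-3 (415 ppm)
    g0: float = 4.5525e-5          # minimum stomatal conductance, m s-1
    R0: float = 9.1e-8             # respiration at 0 degC, mol CO2 m-2 leaf s-1
    Q10: float = 2.3               # respiration temperature quotient
    S0: float = -4.5               # acclimation threshold, degC
    tau_S: float = 12.0            # acclimation time constant, days
    k0: float = 2.22e-8            # reference soil-to-leaf conductance, mol m-2 leaf s-1 Pa-1
    dpsi_sl_max: float = 3.0e6     # maximum soil-to-leaf potential difference, Pa
    leaf_temp_slope: float = 1.0 / 1500.0  # degC per (umol m-2 s-1) of PPFD

    def __post_init__(self) -> None:
        if self.Q10 <= 1.0:
            raise ValueError("Q10 must exceed 1")
        for name in ("C_a", "g0", "R0", "tau_S", "k0", "dpsi_sl_max"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    @property
    def tau_S_seconds(self) -> float:
        return self.tau_S * 86400.0


@dataclass(frozen=True)
class OSMParams:
    """Estimated gas-exchange parameters (per tree / tree-year).

    ``xi_m``/``xi_p`` govern soil-to-root conductance without
    waterlogging, ``eta_m``/``eta_p`` the waterlogging branch on peat;
    ``sigma_star`` is the optimal water-table depth (cm); ``z0``/``z1``
    (both < 0) the intercept/slope of log10 lambda versus
    log10(k_sl/k0); ``c`` the acclimation slope (m3 mol-1 degC-1);
    ``gamma`` the PPFD saturation of conductance (m s-1); ``beta`` the
    sap-flow time-lag slope (min per m of tree height).
    """

    xi_m: float = 0.135
    xi_p: float = 10.0
    eta_m: float = 0.265
    eta_p: float = 5.75
    sigma_star: float = 27.5
    z0: float = -4.5
    z1: float = -0.6
    c: float = 0.095
    gamma: float = 2.6e-3
    beta: float = 5.25

    def __post_init__(self) -> None:
        if self.z0 >= 0 or self.z1 >= 0:
            raise ValueError("z0 and z1 must both be negative")


def leaf_temperature(t_air, ppfd, consts: OSMConstants = OSMConstants()):
    """Leaf temperature (degC) from air temperature and PPFD.

    A linear radiative-load correction, T_l = T + I/1500 by default; the
    slope is a configurable constant.
    """
    ppfd = np.asarray(ppfd, dtype=float)
    if np.any(ppfd < 0):
        raise ValueError("PPFD must be non-negative")
    out = np.asarray(t_air, dtype=float) + consts.leaf_temp_slope * ppfd
    return out if out.shape else float(out)


def respiration(t_leaf, consts: OSMConstants):
    """Q10 respiration: R = R0 * Q10^(T_l/10), mol CO2 m-2 leaf s-1."""
    out = consts.R0 * consts.Q10 ** (np.asarray(t_leaf, dtype=float) / 10.0)
    return out if out.shape else float(out)


def acclim_update(s, t_air, ppfd, dt: float, consts: OSMConstants):
    """One step of the acclimation state S (degC).

    S relaxes toward leaf temperature with time constant tau_S.  The
    linear ODE is advanced with its exact exponential solution for
    piecewise-constant forcing, S' = T_l + (S - T_l) exp(-dt/tau_S),
    which is unconditionally stable and lies between S and T_l.
    """
    t_l = leaf_temperature(t_air, ppfd, consts)
    decay = math.exp(-dt / consts.tau_S_seconds)
    out = t_l + (np.asarray(s, dtype=float) - t_l) * decay
    return out if np.asarray(out).shape else float(out)


def light_response(ppfd, s, params: OSMParams, consts: OSMConstants):
    """Saturating stomatal light response f = iota*gamma*I / (iota*I + gamma).

    iota = max{c (S - S0), 0} is the (acclimation-gated) initial slope
    in m3 mol-1, so PPFD (umol m-2 s-1) is converted to mol m-2 s-1
    before entering the product iota*I.  f has units of conductance
    (m s-1), is bounded by gamma, and vanishes in darkness or when S is
    at/below the threshold S0.
    """
    ppfd_mol = np.asarray(ppfd, dtype=float) * 1e-6
    if np.any(ppfd_mol < 0):
        raise ValueError("PPFD must be non-negative")
    iota = np.maximum(params.c * (np.asarray(s, dtype=float) - consts.S0), 0.0)
    denom = iota * ppfd_mol + params.gamma
    out = np.where(denom > 0, iota * params.gamma * ppfd_mol / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.shape else float(out)


def ksr(theta_or_sigma, site_kind: str, params: OSMParams, soil: SoilConstants,
        floor: float = 1e-9):
    """Soil-to-root conductance in multiples of k0.

    Mineral soils: k_sr = xi_m (theta/theta_sat)^xi_p, increasing in
    theta (drier soil, poorer root contact).

    Peat: unimodal in water-table depth sigma.  Shallow water tables
    (sigma < sigma* - 15 cm) sit on the waterlogging branch
    k_sr- = eta_m ((2 theta* - theta)/theta_sat)^eta_p, which improves as
    the peat drains; deep water tables (sigma > sigma* + 15) sit on the
    drying branch k_sr+; in between, conductance plateaus at
    (max k_sr+ + max k_sr-)/2 evaluated at the plateau edges.  theta* is
    the SWC at the optimal depth sigma*.

    If waterlogging is total (2 theta* - theta <= 0), a small positive
    floor is returned so downstream harmonic sums stay defined.
    """
    if site_kind == "mineral":
        theta = np.asarray(theta_or_sigma, dtype=float)
        if np.any(theta <= 0) or np.any(theta > soil.theta_sat + 1e-12):
            raise ValueError("mineral theta must lie in (0, theta_sat]")
        out = params.xi_m * (theta / soil.theta_sat) ** params.xi_p
        return out if out.shape else float(out)
    if site_kind != "peat":
        raise ValueError(f"unknown site kind {site_kind!r}")

    from .env_soil import swc_from_wtd

    sigma = np.asarray(theta_or_sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("water-table depth must be non-negative")
    theta = np.asarray(swc_from_wtd(sigma, soil), dtype=float)
    theta_star = swc_from_wtd(params.sigma_star, soil)

    def k_plus(th):
        return params.xi_m * (th / soil.theta_sat) ** params.xi_p

    def k_minus(th):
        arg = (2.0 * theta_star - th) / soil.theta_sat
        return np.where(arg > 0, params.eta_m * np.maximum(arg, 0.0) ** params.eta_p, floor)

    lo, hi = params.sigma_star - 15.0, params.sigma_star + 15.0
    # branch maxima over their own domains sit at the plateau edges:
    # k_sr- increases with sigma on [0, lo], k_sr+ decreases on [hi, inf)
    plateau = 0.5 * (k_minus(swc_from_wtd(max(lo, 0.0), soil))
                     + k_plus(swc_from_wtd(hi, soil)))
    out = np.where(sigma < lo, k_minus(theta),
                   np.where(sigma > hi, k_plus(theta), plateau))
    out = np.maximum(out, floor)
    return out if out.shape else float(out)


def krl_from_sapflow(j_obs, rho: float, consts: OSMConstants):
    """Root-to-leaf conductance from the seasonal sap-flow maximum.

    k_rl = max_t J(t) / (rho * dpsi_sl_max), returned in multiples of
    k0.  J is sap-flow density per sapwood area (mol H2O m-2 s-1); the
    leaf-to-sapwood area ratio rho converts it to a per-leaf-area flux.
    Constant per tree-year.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    j = np.asarray(j_obs, dtype=float)
    j = j[np.isfinite(j)]
    if j.size == 0 or np.nanmax(j) <= 0:
        raise ValueError("sap-flow series has no positive finite values; k_rl undefined")
    return float(np.max(j) / (rho * consts.dpsi_sl_max) / consts.k0)


def series_conductance(*ks):
    """Harmonic (series-resistor) combination of conductances."""
    ks = [np.asarray(k, dtype=float) for k in ks]
    for k in ks:
        if np.any(k <= 0):
            raise ValueError("conductances must be positive")
    inv = sum(1.0 / k for k in ks)
    out = 1.0 / inv
    return out if np.asarray(out).shape else float(out)


def mwue(k_sl, params_or_z0, z1: float | None = None, *, k0_units: bool = True):
    """Marginal water-use efficiency lambda (mol CO2 per mol H2O).

    log10 lambda = z0 + z1 log10(k_sl / k0); with z1 < 0 lambda falls as
    the hydraulic pathway improves.  ``k_sl`` is in multiples of k0.
    """
    if isinstance(params_or_z0, OSMParams):
        z0, z1 = params_or_z0.z0, params_or_z0.z1
    else:
        z0 = float(params_or_z0)
        if z1 is None:
            raise ValueError("z1 required when z0 given as a float")
    k_sl = np.asarray(k_sl, dtype=float)
    if np.any(k_sl <= 0):
        raise ValueError("k_sl must be positive")
    out = 10.0 ** (z0 + z1 * np.log10(k_sl))
    return out if out.shape else float(out)


def optimal_conductance(f, resp, lam, d, consts: OSMConstants):
    """Optimal stomatal conductance with the g0 floor (m s-1).

    The interior optimum of A(g) - lambda*1.6*g*D under the
    supply-demand assimilation model A = g (f C_a - R)/(g + f) is

        g* = f [ sqrt((C_a - R/f) / (1.6 lambda D)) - 1 ]

    (setting dA/dg = 1.6 lambda D and solving for g).  Whenever the
    optimum is undefined or below the minimum conductance — darkness
    (f = 0), respiration exceeding gross supply, huge D — the stomata
    sit at the floor: g_sigma = max(g0, g*).
    """
    f = np.asarray(f, dtype=float)
    lam = np.asarray(lam, dtype=float)
    d = np.asarray(d, dtype=float)
    resp = np.asarray(resp, dtype=float)
    if np.any(lam <= 0) or np.any(d <= 0):
        raise ValueError("lambda and D must be positive")
    safe_f = np.where(f > 0, f, 1.0)
    radicand = (consts.C_a - resp / safe_f) / (1.6 * lam * d)
    ok = (f > 0) & (radicand > 0)
    g_star = np.where(ok, safe_f * (np.sqrt(np.maximum(radicand, 0.0)) - 1.0), -np.inf)
    out = np.maximum(consts.g0, g_star)
    return out if out.shape else float(out)


def transpiration(g_sigma, d):
    """E = 1.6 g_sigma D, mol H2O m-2 leaf s-1 (1.6 = H2O/CO2 diffusivity ratio)."""
    out = 1.6 * np.asarray(g_sigma, dtype=float) * np.asarray(d, dtype=float)
    return out if out.shape else float(out)


def assimilation(g_sigma, f, resp, consts: OSMConstants, include_respiration: bool = True):
    """Net assimilation A (mol C m-2 leaf s-1), supply-demand form.

    Eliminating the internal CO2 concentration from supply
    g (C_a - C_i) and linear demand f C_i - R gives

        A = g (f C_a - R) / (g + f).

    In darkness (f = 0) this reduces to A = -R (night respiration);
    with ``include_respiration=False`` the gross form
    A = g C_a f/(g + f) is returned instead.
    """
    g = np.asarray(g_sigma, dtype=float)
    f = np.asarray(f, dtype=float)
    resp = np.asarray(resp, dtype=float) if include_respiration else np.zeros_like(g)
    if np.any(g <= 0):
        raise ValueError("g_sigma must be positive")
    out = g * (f * consts.C_a - resp) / (g + f)
    return out if out.shape else float(out)


def lag_steps(beta: float, height: float, step_seconds: float = 1800.0) -> int:
    """Sap-flow lag behind transpiration, rounded to whole grid steps."""
    return int(round(beta * height * 60.0 / step_seconds))


def lag_shift(series, beta: float, height: float, step_seconds: float = 1800.0):
    """Advance a sap-flow series by the height-dependent lag.

    Sap flow at breast height lags leaf transpiration by beta*height
    minutes; shifting it earlier aligns it with modelled E.  Vacated
    trailing positions are NaN-padded.
    """
    x = np.asarray(series, dtype=float)
    n = lag_steps(beta, height, step_seconds)
    if n >= x.size:
        raise ValueError("lag longer than the series")
    if n == 0:
        return x.copy()
    out = np.full_like(x, np.nan)
    out[:-n] = x[n:]
    return out


def season_onset(s_series, timestamps) -> int | None:
    """First day of year on which the acclimation state reaches 0 degC.

    Returns the DOY of the earliest timestamp with S >= 0, or None if S
    never crosses zero (no onset).
    """
    s = np.asarray(s_series, dtype=float)
    idx = np.nonzero(s >= 0.0)[0]
    if idx.size == 0:
        return None
    ts = pd.DatetimeIndex(timestamps)
    return int(ts[idx[0]].dayofyear)
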