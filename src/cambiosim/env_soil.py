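"""Soil water state and driver preprocessing.

Two site archetypes are supported:

* drained peatland, where the measured quantity is water-table depth
  (WTD, ``sigma``, cm below the surface) and volumetric soil water
  content (SWC, ``theta``) is derived from a Van Genuchten retention
  curve calibrated for Finnish peat;
* mineral soil, where SWC is measured directly and water potential
  follows a Campbell-type power law anchored at the air-entry potential.

All potentials are in Pa and are non-positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: grid step of every driver and observation series (seconds)
STEP_SECONDS = 1800

# Van Genuchten coefficients for Finnish drained peat (taken as literals)
_VG_ALPHA = 0.072      # cm^-1
_VG_N = 1.371
_PEAT_PSI_EXP_NUM = -4.4248
_PEAT_PSI_EXP = 0.0231 / 0.774
_PA_PER_CM = 98.2      # pressure-head conversion, Pa per cm of water


@dataclass(frozen=True)
class SoilConstants:
    """Site-level soil retention constants.

    Parameters
    ----------
    theta_sat : float
        Saturated volumetric water content (m3 m-3).
    theta_res : float
        Residual volumetric water content (m3 m-3).  Defaults: 0.10 for
        peat, 0.03 for mineral soil (placeholder values; the retention
        calibrations this package borrows do not publish one).
    psi_e : float
        Air-entry water potential (Pa, <= 0).
    site_kind : {"peat", "mineral"}
    """

    theta_sat: float
    theta_res: float
    psi_e: float
    site_kind: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_res < self.theta_sat <= 1.0):
            raise ValueError(
                f"require 0 <= theta_res < theta_sat <= 1, got "
                f"theta_res={self.theta_res}, theta_sat={self.theta_sat}"
            )
        if self.psi_e >= 0.0 and self.site_kind == "mineral":
            raise ValueError(f"air-entry potential must be negative, got {self.psi_e}")
        if self.site_kind not in ("peat", "mineral"):
            raise ValueError(f"unknown site_kind {self.site_kind!r}")


#: Table-style defaults for the two study-site archetypes.
PEAT_SOIL = SoilConstants(theta_sat=0.918, theta_res=0.10, psi_e=-745.0, site_kind="peat")
MINERAL_SOIL = SoilConstants(theta_sat=0.57, theta_res=0.03, psi_e=-745.0, site_kind="mineral")


def swc_from_wtd(sigma, soil: SoilConstants):
    """Volumetric water content of peat from water-table depth.

    theta(sigma) = theta_res + (theta_sat - theta_res)
                   * [1 + (0.072 sigma)^1.371]^(1/1.371 - 1)

    ``sigma`` is in cm below the surface (positive downward).  The curve
    is strictly decreasing: a deeper water table means drier peat.
    Accepts scalars or arrays.
    """
    if soil.site_kind != "peat":
        raise ValueError("swc_from_wtd applies to peat sites only")
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0.0):
        raise ValueError("negative water-table depth (sensor artifact); clamp upstream")
    bracket = 1.0 + (_VG_ALPHA * sigma) ** _VG_N
    theta = soil.theta_res + (soil.theta_sat - soil.theta_res) * bracket ** (1.0 / _VG_N - 1.0)
    return theta if theta.shape else float(theta)


def psi_soil_peat(theta, soil: SoilConstants):
    """Peat soil water potential (Pa) from SWC.

    psi = -[ S_e^(-4.4248) - 1 ]^(0.0231/0.774) cm  * 98.2 Pa/cm,
    with effective saturation S_e = (theta - theta_res)/(theta_sat - theta_res).

    The exponent grouping is chosen so that psi(theta_sat) = 0 and psi is
    monotone non-decreasing in theta; it is isolated here so alternative
    readings of the coefficient chain can be swapped in one place.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= soil.theta_res):
        raise ValueError("theta <= theta_res: peat water potential undefined")
    if np.any(theta > soil.theta_sat + 1e-12):
        raise ValueError("theta exceeds saturation")
    s_e = (theta - soil.theta_res) / (soil.theta_sat - soil.theta_res)
    inner = np.maximum(s_e ** _PEAT_PSI_EXP_NUM - 1.0, 0.0)
    psi = -(inner ** _PEAT_PSI_EXP) * _PA_PER_CM
    return psi if psi.shape else float(psi)


def psi_soil_mineral(theta, soil: SoilConstants, xi_p: float):
    """Mineral soil water potential (Pa), Campbell retention form.

    psi = psi_e * (theta/theta_sat)^((3 - xi_p)/2)

    ``xi_p`` is the power of the soil-to-root conductance law; in the
    Campbell framework the conductivity exponent is 2b + 3, so the
    retention exponent is -b = (3 - xi_p)/2.  At saturation the power
    term is 1 and psi equals the air-entry constant psi_e.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0.0):
        raise ValueError("theta must be positive")
    psi = soil.psi_e * (theta / soil.theta_sat) ** ((3.0 - xi_p) / 2.0)
    return psi if psi.shape else float(psi)


def psi_soil(theta, soil: SoilConstants, xi_p: float | None = None):
    """Dispatch to the peat or mineral retention curve by site kind."""
    if soil.site_kind == "peat":
        return psi_soil_peat(theta, soil)
    if xi_p is None:
        raise ValueError("mineral soil requires the retention exponent xi_p")
    return psi_soil_mineral(theta, soil, xi_p)


def rolling_mean(series, window_steps: int, centred: bool = False):
    """Moving average on the regular driver grid.

    ``window_steps`` counts grid steps (48 steps = 24 h).  Trailing by
    default, matching how smoothed SWC is used as a model input; edges
    are averaged over the available part of the window so the output has
    no missing values and a constant series is returned unchanged.
    """
    if window_steps < 1:
        raise ValueError("window must span at least one grid step")
    s = pd.Series(np.asarray(series, dtype=float))
    out = s.rolling(window=window_steps, min_periods=1, center=centred).mean()
    return out.to_numpy()


def vpd_kpa_to_mol_m3(vpd_kpa, t_air_c):
    """Convert VPD from kPa to mol m-3 via the ideal-gas law at air temperature."""
    r_gas = 8.3145
    return np.asarray(vpd_kpa, dtype=float) * 1000.0 / (r_gas * (np.asarray(t_air_c, dtype=float) + 273.15))


def saturation_vapour_pressure_kpa(t_c):
    """Magnus form over water, kPa."""
    t_c = np.asarray(t_c, dtype=float)
    return 0.6112 * np.exp(17.62 * t_c / (243.12 + t_c))
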