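"""Stem water relations at breast height.

The cambial water potential is assembled from four terms: soil water
potential, viscous drawdown proportional to sap flow, a bark rainwater
capacitor term, and a fixed gravitational offset,

    psi_cam = psi_s - J/(rho k_sb) + (E_b/d_b0) q_b - dpsi_g .

The bark is a linear capacitor charged by rain interception (influx
clamped at J_bin_max) and discharged into the cambium through the
conductance k_bc.  Because cambial osmolality is taken as constant,
turgor dynamics equal psi_cam dynamics, and the reversible (elastic)
component of stem radial dimension follows d_ela_dot = psi_cam_dot *
d0 / E with a constant per-tree-year modulus of elasticity E.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class StemConstants:
    """Bark and stem hydraulic constants."""

    E_b: float = 15.48          # bark modulus of elasticity, MPa
    k_bc: float = 3.643e-5      # bark-to-cambium conductance, mm MPa-1 s-1
    J_bin_max: float = 2e-5     # maximum bark water influx, mm s-1
    dpsi_g: float = 0.01473     # gravitational potential offset, MPa
    l_rb: float = 1.5           # root-to-breast-height distance, m
    alpha_rain: float = None    # bark influx per rain intensity (mm bark water per mm rain)

    def __post_init__(self) -> None:
        # default: 1 mm/h of rain just saturates the influx at J_bin_max
        if self.alpha_rain is None:
            object.__setattr__(self, "alpha_rain", self.J_bin_max / (1.0 / 3600.0))
        for name in ("E_b", "k_bc", "J_bin_max", "dpsi_g", "l_rb", "alpha_rain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TreeAttributes:
    """Static per-tree attributes (the tree-table row)."""

    tree_id: str
    height: float               # m
    dbh: float                  # cm
    sapwood_area: float         # m2
    leaf_area: float            # m2, all-sided
    bark_thickness: float       # d_b0, mm
    d0: float                   # reference stem radial dimension, mm
    E_moe: float = 650.0        # bulk stem modulus of elasticity, MPa (per tree-year)
    rho: float = field(default=None)  # leaf-to-sapwood area ratio

    def __post_init__(self) -> None:
        if self.rho is None:
            object.__setattr__(self, "rho", self.leaf_area / self.sapwood_area)
        for name in ("height", "dbh", "sapwood_area", "leaf_area",
                     "bark_thickness", "d0", "E_moe", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class StemState:
    """Mutable per-step stem water state."""

    q_b: float = 0.0            # bark water per area, mm
    psi_cam: float = 0.0        # cambial water potential, MPa
    d_ela: float = 0.0          # cumulative elastic SRD component, mm

    def dpsi_bc(self, consts: "StemConstants", d_b0: float) -> float:
        """Bark-cambium potential difference, E_b q_b / d_b0 (MPa)."""
        return consts.E_b * self.q_b / d_b0


def bark_influx(w_rain_mm: float, dt: float, consts: StemConstants) -> float:
    """Bark charging flux J_bin (mm s-1): linear in rain intensity, clamped."""
    if w_rain_mm < 0:
        raise ValueError("rain must be non-negative")
    return min(consts.alpha_rain * w_rain_mm / dt, consts.J_bin_max)


def bark_time_constant(consts: StemConstants, d_b0: float) -> float:
    """Discharge time constant of the bark capacitor, d_b0/(E_b k_bc), s."""
    return d_b0 / (consts.E_b * consts.k_bc)


def bark_step(q_b: float, w_rain_mm: float, dt: float, consts: StemConstants,
              d_b0: float) -> float:
    """Advance the bark water store one step.

    q_b_dot = J_bin - k_bc * dpsi_bc with dpsi_bc = E_b q_b / d_b0 is a
    linear capacitor; with forcing constant over the step the exact
    update is q' = q e^(-dt/tau) + J_bin tau (1 - e^(-dt/tau)), with
    tau = d_b0/(E_b k_bc).  Exact for piecewise-constant rain and
    unconditionally positive.
    """
    if q_b < 0:
        raise ValueError("bark water store cannot be negative")
    tau = bark_time_constant(consts, d_b0)
    j_in = bark_influx(w_rain_mm, dt, consts)
    decay = math.exp(-dt / tau)
    return q_b * decay + j_in * tau * (1.0 - decay)


def bark_series(w_rain_mm, dt: float, consts: StemConstants, d_b0: float,
                q0: float = 0.0) -> np.ndarray:
    """Vectorised bark trajectory; q[i] is the state at the start of step i."""
    from scipy.signal import lfilter

    rain = np.asarray(w_rain_mm, dtype=float)
    tau = bark_time_constant(consts, d_b0)
    decay = math.exp(-dt / tau)
    j_in = np.minimum(consts.alpha_rain * rain / dt, consts.J_bin_max)
    forcing = j_in * tau * (1.0 - decay)
    # q[i+1] = decay*q[i] + forcing[i]
    q = np.empty(rain.size, dtype=float)
    q[0] = q0
    if rain.size > 1:
        z = lfilter([1.0], [1.0, -decay], forcing[:-1], zi=[decay * q0])[0]
        q[1:] = z
    return q


def ksb(k_sr: float, k_rl: float, tree: TreeAttributes, consts: StemConstants,
        path_total: float | None = None):
    """Soil-to-breast-height conductance (same units as its inputs).

    Series combination 1/k_sb = 1/k_sr + 1/k_rb, where the root-to-
    breast-height leg is scaled from the root-to-leaf conductance by
    inverse path length: k_rb = k_rl * path_total / l_rb, with
    path_total defaulting to tree height + l_rb.
    """
    k_sr = np.asarray(k_sr, dtype=float)
    if np.any(k_sr <= 0) or k_rl <= 0:
        raise ValueError("conductances must be positive")
    if path_total is None:
        path_total = tree.height + consts.l_rb
    k_rb = k_rl * path_total / consts.l_rb
    out = 1.0 / (1.0 / k_sr + 1.0 / k_rb)
    return out if out.shape else float(out)


def cambium_potential(psi_s_pa, j_leaf, k_sb_abs, q_b, consts: StemConstants,
                      d_b0: float):
    """Cambial water potential (MPa).

    psi_cam = psi_s - J/(rho k_sb) + (E_b/d_b0) q_b - dpsi_g, where
    ``j_leaf`` is sap flow already expressed per leaf area (J/rho, mol
    m-2 leaf s-1) and ``k_sb_abs`` is in mol m-2 leaf s-1 Pa-1 so the
    drawdown is in Pa.  Missing sap-flow values propagate as NaN and
    should be carried forward by the caller.
    """
    k_sb_abs = np.asarray(k_sb_abs, dtype=float)
    if np.any(k_sb_abs <= 0):
        raise ValueError("k_sb must be positive")
    drawdown_pa = np.asarray(j_leaf, dtype=float) / k_sb_abs
    psi = (np.asarray(psi_s_pa, dtype=float) - drawdown_pa) / 1e6 \
        + (consts.E_b / d_b0) * np.asarray(q_b, dtype=float) - consts.dpsi_g
    return psi if np.asarray(psi).shape else float(psi)


def elastic_increment(psi_cam_prev, psi_cam_now, e_moe: float, d0: float):
    """Reversible SRD increment (mm): d0/E times the turgor change.

    Sums to zero over any closed psi_cam loop (pure elasticity).
    """
    if e_moe <= 0 or d0 <= 0:
        raise ValueError("E and d0 must be positive")
    out = (np.asarray(psi_cam_now, dtype=float) - np.asarray(psi_cam_prev, dtype=float)) * d0 / e_moe
    return out if np.asarray(out).shape else float(out)
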