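"""Shared fixtures: synthetic site-years and stationary driver grids."""

import numpy as np
import pandas as pd
import pytest

from cambiosim import SynthConfig, generate_drivers, generate_observations
from cambiosim.env_soil import saturation_vapour_pressure_kpa, vpd_kpa_to_mol_m3
from cambiosim.synthetic_data import default_tree


@pytest.fixture(scope="session")
def short_site():
    """A 60-day peatland site-year with noisy observations."""
    cfg = SynthConfig(seed=7, n_days=60)
    drivers = generate_drivers(cfg)
    obs = generate_observations(drivers, cfg)
    return cfg, drivers, obs


@pytest.fixture(scope="session")
def season_site():
    """A full 153-day peatland site-year."""
    cfg = SynthConfig(seed=42, n_days=153)
    drivers = generate_drivers(cfg)
    obs = generate_observations(drivers, cfg)
    return cfg, drivers, obs


def make_stationary_drivers(n_days: int = 140, start: str = "2021-05-12",
                            t_mean: float = 15.0, t_amp: float = 5.0,
                            i_max: float = 1200.0, wtd: float = 30.0,
                            rain: float = 0.0) -> pd.DataFrame:
    """Identical diurnal cycles: no weather noise, fixed soil state."""
    idx = pd.date_range(start, periods=n_days * 48, freq="1800s")
    hour = (idx.hour + idx.minute / 60.0).to_numpy()
    t_air = t_mean + t_amp * np.sin(2 * np.pi * (hour - 9) / 24.0)
    daylength, sunrise = 18.0, 3.0
    phase = (hour - sunrise) / daylength
    ppfd = i_max * np.where((phase > 0) & (phase < 1),
                            np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
    vpd = vpd_kpa_to_mol_m3(saturation_vapour_pressure_kpa(t_air) * 0.3, t_air)
    return pd.DataFrame({"T_degC": t_air, "ppfd_umol_m2_s": ppfd,
                         "vpd_mol_m3": vpd, "rain_mm": rain, "wtd_cm": wtd},
                        index=idx)


@pytest.fixture(scope="session")
def stationary_drivers():
    return make_stationary_drivers()


@pytest.fixture(scope="session")
def peat_tree():
    return default_tree("peat")
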