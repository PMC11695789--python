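"""Readers, writers and run configuration.

All observational exchange is CSV on a strict 30-min grid.  The reader
enforces the grid, interpolates short gaps (up to 2 h) in drivers and
rejects longer ones; observation series may keep missing values (they
are simply excluded from likelihoods downstream).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .env_soil import STEP_SECONDS, SoilConstants, vpd_kpa_to_mol_m3
from .gas_exchange import OSMConstants, OSMParams
from .cambial_growth import GrowthConstants, GrowthParams
from .stem_water import StemConstants, TreeAttributes

log = logging.getLogger("cambiosim")

DRIVER_COLUMNS = {"T_degC", "ppfd_umol_m2_s", "rain_mm"}
MAX_GAP_STEPS = 4  # 2 h


def _to_grid(df: pd.DataFrame) -> pd.DataFrame:
    ts = pd.to_datetime(df["timestamp"])
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise ValueError(f"duplicated timestamp {dup}")
    df = df.drop(columns=["timestamp"]).set_index(pd.DatetimeIndex(ts)).sort_index()
    return df


def read_timeseries(path, kind: str) -> pd.DataFrame:
    """Read and validate a drivers/sapflow/dendrometer CSV.

    Drivers are re-indexed onto the exact 30-min grid spanning the
    file; gaps of at most 2 h are linearly interpolated (and reported),
    longer gaps are an error.  Observation tables keep NaN gaps.
    """
    if kind not in ("drivers", "sapflow", "dendrometer"):
        raise ValueError(f"unknown series kind {kind!r}")
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: missing 'timestamp' column")
    df = _to_grid(df)
    full = pd.date_range(df.index[0], df.index[-1], freq=f"{STEP_SECONDS}s")
    if kind == "drivers":
        missing = DRIVER_COLUMNS - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing driver columns {sorted(missing)}")
        has_vpd = "vpd_mol_m3" in df.columns or "vpd_kpa" in df.columns
        has_soil = "wtd_cm" in df.columns or "swc_m3_m3" in df.columns
        if not has_vpd or not has_soil:
            raise ValueError(f"{path}: need a VPD column and one of wtd_cm/swc_m3_m3")
        out = df.reindex(full)
        gap_runs = out["T_degC"].isna()
        if gap_runs.any():
            run = gap_runs.astype(int).groupby((~gap_runs).cumsum()).sum().max()
            if run > MAX_GAP_STEPS:
                raise ValueError(f"{path}: driver gap of {run} steps exceeds the 2-h policy")
            log.info("%s: interpolated %d missing driver steps", path, int(gap_runs.sum()))
        out = out.interpolate(method="linear", limit_direction="both")
        if "vpd_mol_m3" not in out.columns:
            out["vpd_mol_m3"] = vpd_kpa_to_mol_m3(out["vpd_kpa"], out["T_degC"])
        return out
    out = df.reindex(full)  # observations: keep gaps as NaN
    log.info("%s: %d rows (%d missing)", path, len(out),
             int(out.isna().any(axis=1).sum()))
    return out


def write_trace(trace: pd.DataFrame, path) -> None:
    """Write a simulation trace CSV that round-trips numerically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = trace.copy()
    out.insert(0, "timestamp", out.index)
    out.to_csv(path, index=False, float_format="%.17g")


def read_trace(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _to_grid(df)


def read_trees(path) -> list[TreeAttributes]:
    """Read the tree-attribute table (one row per tree)."""
    df = pd.read_csv(path)
    required = {"tree_id", "height_m", "dbh_cm", "sapwood_m2", "leaf_area_m2",
                "bark_mm", "d0_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing tree columns {sorted(missing)}")
    trees = []
    for _, row in df.iterrows():
        trees.append(TreeAttributes(
            tree_id=str(row["tree_id"]), height=row["height_m"], dbh=row["dbh_cm"],
            sapwood_area=row["sapwood_m2"], leaf_area=row["leaf_area_m2"],
            bark_thickness=row["bark_mm"], d0=row["d0_mm"],
            E_moe=row.get("e_moe_mpa", 650.0)))
    return trees


@dataclass
class RunConfig:
    """Validated run configuration assembled from a YAML file."""

    soil: SoilConstants
    osm_consts: OSMConstants
    stem_consts: StemConstants
    growth_consts: GrowthConstants
    osm_params: OSMParams
    growth_params: GrowthParams
    mode: str = "fm"
    seed: int = 0

    def manifest(self) -> dict:
        """Replay metadata: config hash, seed, package version."""
        from . import __version__
        payload = json.dumps({k: asdict(v) if hasattr(v, "__dataclass_fields__") else v
                              for k, v in self.__dict__.items()}, sort_keys=True,
                             default=str)
        return {"config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
                "seed": self.seed, "version": __version__}


_SECTION_TYPES = {
    "soil": SoilConstants, "osm_consts": OSMConstants, "stem_consts": StemConstants,
    "growth_consts": GrowthConstants, "osm_params": OSMParams,
    "growth_params": GrowthParams,
}


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(_SECTION_TYPES) | {"mode", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        payload = raw.get(section, {})
        bad = set(payload) - set(cls.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
        kwargs[section] = cls(**payload) if payload or section != "soil" else None
    if kwargs["soil"] is None:
        raise ValueError("config must define the soil section")
    return RunConfig(mode=raw.get("mode", "fm"), seed=int(raw.get("seed", 0)), **kwargs)
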