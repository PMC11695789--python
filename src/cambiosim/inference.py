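"""Bayesian calibration of the coupled model.

Uniform (box) priors per parameter, an iid Gaussian data model per
observation stream (transpiration and stem radial dimension, with the
residual standard deviations treated as estimated nuisance parameters),
and an adaptive population MCMC sampler: differential-evolution
proposals mixed with snooker updates over an ensemble of chains, the
same family of algorithms as DREAM-style adaptive samplers.  The
maximum-a-posteriori (MAP) vector is taken as the optimal estimate and
predictive credible bands are formed by resampling the posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

import emcee

from .cambial_growth import GrowthConstants, GrowthParams, simulate_arrays, simulate_srd
from .env_soil import SoilConstants
from .gas_exchange import OSMConstants, OSMParams, lag_shift
from .stem_water import StemConstants, TreeAttributes

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """One uniform prior: name, box bounds and scope.

    ``scope`` records whether the parameter is shared (``global``),
    tree-specific (``per_tree``) or tree-and-year-specific
    (``per_tree_year``); blocks are independent with shared bounds (no
    partial pooling).
    """

    name: str
    lo: float
    hi: float
    scope: str = "global"

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"empty prior box for {self.name}")
        if self.scope not in ("global", "per_tree", "per_tree_year"):
            raise ValueError(f"unknown scope {self.scope!r}")


def default_priors(site_kind: str = "peat") -> dict[str, PriorSpec]:
    """The full prior table of the estimated parameters.

    Site-specific bounds where the two study-site archetypes differ
    (acclimation slope c, PPFD saturation gamma, stem MOE).
    """
    peat = site_kind == "peat"
    specs = [
        PriorSpec("xi_m", 0.02, 0.25, "per_tree_year"),
        PriorSpec("xi_p", 5.0, 15.0),
        PriorSpec("eta_m", 0.03, 0.5, "per_tree"),
        PriorSpec("eta_p", 1.5, 10.0),
        PriorSpec("sigma_star", 20.0, 35.0),
        PriorSpec("z0", -7.0, -2.0, "per_tree_year"),
        PriorSpec("z1", -1.0, -0.2, "per_tree_year"),
        PriorSpec("c", 0.04 if peat else 0.01, 0.15 if peat else 0.10, "per_tree_year"),
        PriorSpec("gamma", 1.2e-3 if peat else 1.6e-3, 4.0e-3),
        PriorSpec("beta", 1.0, 9.5),
        PriorSpec("E_moe", 300.0 if peat else 600.0, 1000.0 if peat else 1500.0,
                  "per_tree_year"),
        PriorSpec("psi_0", -1.1, -0.3),
        PriorSpec("t_0", 4.0, 10.0),
        PriorSpec("dh_a", -9.2e4, -5.4e4),
        PriorSpec("dh_d", 1.80e5, 5.25e5),
        PriorSpec("ds_d", 600.0, 1500.0),
        PriorSpec("phi_max", 4e-3, 17e-3, "per_tree_year"),
        PriorSpec("b", 2.5, 11.0, "per_tree_year"),
        PriorSpec("tau_g", 200.0, 600.0, "per_tree_year"),
    ]
    return {s.name: s for s in specs}


@dataclass
class ErrorModel:
    """Gaussian iid residual SDs of the two observation streams.

    Units follow the streams they describe: ``sigma_e`` those of the
    transpiration stream, ``sigma_d`` those of the dendrometer stream.
    """

    sigma_e: float
    sigma_d: float

    def __post_init__(self) -> None:
        if self.sigma_e <= 0 or self.sigma_d <= 0:
            raise ValueError("residual SDs must be positive")


def gaussian_loglik(obs, mod, sigma: float) -> float:
    """Sum of iid Gaussian log-densities over paired finite values."""
    if sigma <= 0:
        return -np.inf
    obs = np.asarray(obs, dtype=float)
    mod = np.asarray(mod, dtype=float)
    m = np.isfinite(obs) & np.isfinite(mod)
    n = int(m.sum())
    if n == 0:
        raise ValueError("no usable observations in stream")
    r = obs[m] - mod[m]
    return float(-0.5 * np.sum((r / sigma) ** 2) - n * (math.log(sigma) + 0.5 * _LOG_2PI))


def log_likelihood(e_obs, e_mod, d_obs, d_mod, err: ErrorModel) -> float:
    """Total log-likelihood: product of the two streams' Gaussian PDFs.

    The transpiration stream compares modelled E with the lag-aligned,
    leaf-area-normalised sap flow; the dimension stream compares
    modelled and observed stem radial dimension.  Missing observations
    are skipped.  Invariant under stream ordering (a plain sum).
    """
    return gaussian_loglik(e_obs, e_mod, err.sigma_e) + \
        gaussian_loglik(d_obs, d_mod, err.sigma_d)


@dataclass
class PosteriorSample:
    """MCMC output: chains, matching log-posteriors and metadata."""

    chains: np.ndarray          # (n_iter, n_chains, n_params)
    log_post: np.ndarray        # (n_iter, n_chains)
    param_names: list[str]
    bounds: np.ndarray          # (n_params, 2)
    seed: int
    acceptance: np.ndarray      # per-chain acceptance fraction

    @property
    def n_iter(self) -> int:
        return self.chains.shape[0]

    def flat(self, burn_frac: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """Post-burn-in samples flattened to (n, n_params) with log-posts."""
        burn = int(self.n_iter * burn_frac)
        c = self.chains[burn:].reshape(-1, self.chains.shape[2])
        lp = self.log_post[burn:].reshape(-1)
        return c, lp

    def gelman_rubin(self, burn_frac: float = 0.5) -> np.ndarray:
        """Split-R-hat per parameter (arviz rank-normalised version)."""
        import arviz as az
        burn = int(self.n_iter * burn_frac)
        # arviz expects (chain, draw, ...)
        data = {name: self.chains[burn:, :, i].T
                for i, name in enumerate(self.param_names)}
        r = az.rhat(az.convert_to_dataset(data))
        return np.array([float(r[name]) for name in self.param_names])


def sample_posterior(log_likelihood_fn, bounds, n_chains: int, n_iter: int,
                     seed: int, param_names: list[str] | None = None,
                     progress: bool = False) -> PosteriorSample:
    """Adaptive population MCMC over a uniform prior box.

    ``bounds`` is a sequence of (lo, hi) pairs; the posterior is the
    likelihood restricted to the box (proposals outside are rejected
    through a -inf prior).  Chains are initialised uniformly in the box
    from the seeded RNG; proposals mix differential-evolution moves
    (80%) with snooker moves (20%) across the chain population, which
    adapts the proposal geometry to the posterior as the ensemble
    evolves.  Fully reproducible: the same seed yields identical
    chains.
    """
    bounds = np.asarray(bounds, dtype=float)
    ndim = bounds.shape[0]
    if n_chains < 3:
        raise ValueError("population MCMC needs at least 3 chains")
    if param_names is None:
        param_names = [f"p{i}" for i in range(ndim)]
    lo, hi = bounds[:, 0], bounds[:, 1]

    def log_prob(theta):
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        ll = log_likelihood_fn(theta)
        return ll if np.isfinite(ll) else -np.inf

    rng = np.random.default_rng(seed)
    p0 = lo + (hi - lo) * rng.random((n_chains, ndim))
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_chains, ndim, log_prob, moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
    sampler.run_mcmc(state, n_iter, progress=progress, skip_initial_state_check=True)
    return PosteriorSample(
        chains=sampler.get_chain(),
        log_post=sampler.get_log_prob(),
        param_names=list(param_names),
        bounds=bounds,
        seed=seed,
        acceptance=sampler.acceptance_fraction,
    )


def map_estimate(post: PosteriorSample) -> np.ndarray:
    """The sampled vector with maximal log-posterior (first occurrence)."""
    if post.chains.size == 0:
        raise ValueError("empty chains")
    lp = post.log_post.reshape(-1)
    idx = int(np.argmax(lp))  # argmax returns the first maximal index
    return post.chains.reshape(-1, post.chains.shape[2])[idx].copy()


def credible_band(post: PosteriorSample, predict_fn, n_draws: int = 9000,
                  level: float = 0.99, burn_frac: float = 0.5,
                  seed: int = 0) -> pd.DataFrame:
    """Per-step predictive credible band from posterior resampling.

    Draws ``n_draws`` parameter vectors from the post-burn-in chains
    (with replacement when fewer are available), maps each through
    ``predict_fn(theta, rng) -> trajectory`` — which should include
    observation noise drawn from the error model — and returns the
    lower/upper quantiles (e.g. 0.5% and 99.5% for level 0.99) plus the
    median per step.
    """
    flat, _ = post.flat(burn_frac)
    rng = np.random.default_rng(seed)
    replacing = n_draws > flat.shape[0]
    idx = rng.choice(flat.shape[0], size=n_draws, replace=replacing)
    sims = np.stack([np.asarray(predict_fn(flat[i], rng), dtype=float) for i in idx])
    alpha = (1.0 - level) / 2.0
    if level >= 1.0:
        lo_q, hi_q = sims.min(axis=0), sims.max(axis=0)
    else:
        lo_q = np.quantile(sims, alpha, axis=0)
        hi_q = np.quantile(sims, 1.0 - alpha, axis=0)
    return pd.DataFrame({"lower": lo_q, "median": np.median(sims, axis=0), "upper": hi_q})


class CalibrationProblem:
    """Joint likelihood of one tree-year against sap-flow and SRD data.

    Binds the driver series, observations and fixed constants, and
    exposes ``log_likelihood(theta)`` over a chosen subset of estimated
    parameters (``param_names``), with the two residual SDs appended as
    nuisance parameters unless ``error_model`` fixes them.

    Stream definitions follow the calibration layout: modelled E is
    compared with the observed sap flow advanced by the height lag and
    divided by the leaf-to-sapwood ratio; modelled SRD with the
    dendrometer series.  Simulation runs in calibration (data-driven)
    mode, with observed sap flow driving the stem water submodel.
    """

    _OSM_FIELDS = set(OSMParams.__dataclass_fields__)
    _GROWTH_FIELDS = set(GrowthParams.__dataclass_fields__)
    # parameters that cannot alter the soil state, acclimation, light
    # response, bark store or (data-driven) cambial potential; when the
    # estimated subset stays inside this set those intermediates are
    # computed once and cached
    _CACHE_SAFE = {"psi_0", "t_0", "dh_a", "dh_d", "ds_d", "phi_max", "b",
                   "tau_g", "E_moe", "z0", "z1"}

    def __init__(self, drivers: pd.DataFrame, tree: TreeAttributes,
                 j_obs, d_obs, soil: SoilConstants,
                 param_names: list[str],
                 osm_params: OSMParams = OSMParams(),
                 growth_params: GrowthParams = GrowthParams(),
                 osm_consts: OSMConstants = OSMConstants(),
                 stem_consts: StemConstants = StemConstants(),
                 growth_consts: GrowthConstants = GrowthConstants(),
                 priors: dict[str, PriorSpec] | None = None,
                 error_model: ErrorModel | None = None,
                 mode: str = "fm",
                 sigma_e_max: float | None = None,
                 sigma_d_max: float | None = None):
        self.drivers = drivers
        self.tree = tree
        self.j_obs = np.asarray(j_obs, dtype=float)
        self.d_obs = np.asarray(d_obs, dtype=float)
        self.soil = soil
        self.param_names = list(param_names)
        self.osm_params = osm_params
        self.growth_params = growth_params
        self.osm_consts = osm_consts
        self.stem_consts = stem_consts
        self.growth_consts = growth_consts
        self.mode = mode
        self.error_model = error_model
        priors = priors if priors is not None else default_priors(soil.site_kind)

        bounds = []
        for name in self.param_names:
            if name not in priors:
                raise KeyError(f"no prior for parameter {name!r}")
            bounds.append((priors[name].lo, priors[name].hi))
        self.names_full = list(self.param_names)
        if error_model is None:
            # nuisance residual SDs with wide uniform priors scaled to the data
            if sigma_e_max is None:
                e_scale = np.nanstd(self.j_obs / tree.rho)
                sigma_e_max = 10.0 * float(e_scale if e_scale > 0 else 1.0)
            if sigma_d_max is None:
                d_scale = np.nanstd(self.d_obs)
                sigma_d_max = 10.0 * float(d_scale if d_scale > 0 else 1.0)
            bounds.append((1e-6 * sigma_e_max, sigma_e_max))
            bounds.append((1e-6 * sigma_d_max, sigma_d_max))
            self.names_full += ["sigma_e", "sigma_d"]
        self.bounds = np.asarray(bounds, dtype=float)
        self._cache = None
        if set(self.param_names) <= self._CACHE_SAFE:
            self._build_cache()

    def _build_cache(self) -> None:
        """Precompute every intermediate the estimated subset cannot touch."""
        from .cambial_growth import season_hours
        from .gas_exchange import leaf_temperature, respiration

        cols, ts = simulate_arrays(
            self.drivers, self.tree, self.osm_params, self.growth_params,
            self.soil, self.osm_consts, self.stem_consts, self.growth_consts,
            j_obs=self.j_obs, mode=self.mode)
        t_leaf = np.asarray(leaf_temperature(cols["T_degC"], cols["ppfd_umol_m2_s"],
                                             self.osm_consts), dtype=float)
        self._cache = {
            "log10_ksl": np.log10(cols["k_sl"]),
            "f": cols["f"],
            "resp": np.asarray(respiration(t_leaf, self.osm_consts), dtype=float),
            "d_safe": np.maximum(cols["vpd_mol_m3"], 1e-9),
            "vpd": cols["vpd_mol_m3"],
            "psi_cam": cols["psi_cam"],
            "t_season": season_hours(ts, self.growth_consts.start_doy),
            "t_kelvin": cols["T_degC"] + 273.15,
            "e_obs": lag_shift(self.j_obs, self.osm_params.beta,
                               self.tree.height) / self.tree.rho,
        }

    def _log_likelihood_cached(self, theta) -> float:
        from .gas_exchange import optimal_conductance
        from .cambial_growth import growth_increment

        osm, gro, tree, err = self._split(theta)
        c = self._cache
        lam = 10.0 ** (osm.z0 + osm.z1 * c["log10_ksl"])
        g = np.asarray(optimal_conductance(c["f"], c["resp"], lam, c["d_safe"],
                                           self.osm_consts), dtype=float)
        e_mod = 1.6 * g * c["vpd"]
        inc = np.asarray(growth_increment(c["t_season"], c["psi_cam"], c["t_kelvin"],
                                          1800.0, gro, self.growth_consts, self.mode),
                         dtype=float)
        d_gro = np.concatenate([[0.0], np.cumsum(inc[:-1])])
        d_mod = tree.d0 + (c["psi_cam"] - c["psi_cam"][0]) * tree.d0 / tree.E_moe + d_gro
        return log_likelihood(c["e_obs"], e_mod, self.d_obs, d_mod, err)

    def _split(self, theta):
        theta = np.asarray(theta, dtype=float)
        osm_kw, gro_kw, e_moe = {}, {}, None
        for name, value in zip(self.param_names, theta):
            if name == "E_moe":
                e_moe = float(value)
            elif name in self._OSM_FIELDS:
                osm_kw[name] = float(value)
            elif name in self._GROWTH_FIELDS:
                gro_kw[name] = float(value)
            else:
                raise KeyError(f"parameter {name!r} matches no model field")
        osm = replace(self.osm_params, **osm_kw) if osm_kw else self.osm_params
        gro = replace(self.growth_params, **gro_kw) if gro_kw else self.growth_params
        tree = replace(self.tree, E_moe=e_moe) if e_moe is not None else self.tree
        if self.error_model is not None:
            err = self.error_model
        else:
            err = ErrorModel(sigma_e=float(theta[-2]), sigma_d=float(theta[-1]))
        return osm, gro, tree, err

    def simulate(self, theta) -> pd.DataFrame:
        osm, gro, tree, _ = self._split(theta)
        return simulate_srd(self.drivers, tree, osm, gro, self.soil,
                            self.osm_consts, self.stem_consts, self.growth_consts,
                            j_obs=self.j_obs, mode=self.mode)

    def log_likelihood(self, theta, use_cache: bool = True) -> float:
        try:
            if self._cache is not None and use_cache:
                return self._log_likelihood_cached(theta)
            osm, gro, tree, err = self._split(theta)
            cols, _ = simulate_arrays(self.drivers, tree, osm, gro, self.soil,
                                      self.osm_consts, self.stem_consts,
                                      self.growth_consts, j_obs=self.j_obs,
                                      mode=self.mode)
            e_obs = lag_shift(self.j_obs, osm.beta, tree.height) / tree.rho
            return log_likelihood(e_obs, cols["E_mod"], self.d_obs, cols["d_mod"], err)
        except (ValueError, FloatingPointError, OverflowError):
            return -np.inf

    def sample(self, n_chains: int, n_iter: int, seed: int,
               progress: bool = False) -> PosteriorSample:
        return sample_posterior(self.log_likelihood, self.bounds, n_chains,
                                n_iter, seed, param_names=self.names_full,
                                progress=progress)
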