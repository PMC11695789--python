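"""Likelihood, sampler and posterior summaries."""

import numpy as np
import pytest
from scipy import stats

from cambiosim.inference import (CalibrationProblem, ErrorModel, PosteriorSample,
                                 credible_band, default_priors, gaussian_loglik,
                                 log_likelihood, map_estimate, sample_posterior)


class TestGaussianLoglik:
    def test_zero_residuals_closed_form(self):
        n, sigma = 50, 0.3
        x = np.linspace(0, 1, n)
        expected = n * np.log(1.0 / (sigma * np.sqrt(2 * np.pi)))
        assert gaussian_loglik(x, x, sigma) == pytest.approx(expected)

    def test_doubling_residuals_quadratic_drop(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=80)
        mod = obs + rng.normal(size=80) * 0.1
        sigma = 0.25
        ssr = np.sum((obs - mod) ** 2)
        base = gaussian_loglik(obs, mod, sigma)
        doubled = gaussian_loglik(obs, obs - 2 * (obs - mod), sigma)
        assert base - doubled == pytest.approx(3 * ssr / (2 * sigma ** 2))

    def test_matches_scipy_density_sum(self):
        rng = np.random.default_rng(1)
        obs, mod, sigma = rng.normal(size=40), rng.normal(size=40), 0.7
        expected = stats.norm.logpdf(obs - mod, scale=sigma).sum()
        assert gaussian_loglik(obs, mod, sigma) == pytest.approx(expected)

    def test_skips_missing_and_rejects_empty(self):
        obs = np.array([1.0, np.nan, 3.0])
        mod = np.array([1.1, 2.0, np.nan])
        assert gaussian_loglik(obs, mod, 1.0) == pytest.approx(stats.norm.logpdf(-0.1))
        with pytest.raises(ValueError):
            gaussian_loglik([np.nan], [1.0], 1.0)

    def test_stream_order_invariance(self):
        rng = np.random.default_rng(2)
        e_o, e_m = rng.normal(size=30), rng.normal(size=30)
        d_o, d_m = rng.normal(size=30), rng.normal(size=30)
        err = ErrorModel(0.5, 0.8)
        a = log_likelihood(e_o, e_m, d_o, d_m, err)
        b = gaussian_loglik(d_o, d_m, 0.8) + gaussian_loglik(e_o, e_m, 0.5)
        assert a == pytest.approx(b)


class TestSampler:
    BOUNDS = [(-1.0, 1.0), (0.0, 10.0), (100.0, 200.0)]

    def test_same_seed_bit_identical(self):
        a = sample_posterior(lambda t: 0.0, self.BOUNDS, 12, 100, seed=3)
        b = sample_posterior(lambda t: 0.0, self.BOUNDS, 12, 100, seed=3)
        assert np.array_equal(a.chains, b.chains)
        assert np.array_equal(a.log_post, b.log_post)

    def test_flat_likelihood_recovers_uniform_prior(self):
        post = sample_posterior(lambda t: 0.0, self.BOUNDS, 20, 1500, seed=5)
        flat, _ = post.flat(0.5)
        for i, (lo, hi) in enumerate(self.BOUNDS):
            u = (flat[::37, i] - lo) / (hi - lo)
            assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_gaussian_target_moments_and_rhat(self):
        mu = np.array([0.2, -0.5])
        cov = np.array([[0.04, 0.01], [0.01, 0.09]])
        icov = np.linalg.inv(cov)

        def logp(th):
            d = th - mu
            return -0.5 * d @ icov @ d

        post = sample_posterior(logp, [(-3, 3), (-3, 3)], 24, 4000, seed=11)
        flat, _ = post.flat(0.5)
        assert np.allclose(flat.mean(axis=0), mu, atol=0.02)
        assert np.allclose(np.cov(flat.T), cov, atol=0.02)
        assert np.all(post.gelman_rubin() < 1.1)

    def test_proposals_respect_prior_box(self):
        post = sample_posterior(lambda t: 0.0, self.BOUNDS, 10, 300, seed=7)
        flat = post.chains.reshape(-1, 3)
        for i, (lo, hi) in enumerate(self.BOUNDS):
            assert flat[:, i].min() >= lo and flat[:, i].max() <= hi
        assert np.all(np.isfinite(post.log_post))


class TestMapEstimate:
    def _post(self, chains, lp):
        return PosteriorSample(chains=chains, log_post=lp, param_names=["a"],
                               bounds=np.array([[0.0, 1.0]]), seed=0,
                               acceptance=np.ones(chains.shape[1]))

    def test_single_sample(self):
        post = self._post(np.full((1, 1, 1), 0.3), np.full((1, 1), -1.0))
        assert map_estimate(post)[0] == 0.3

    def test_injected_optimum_returned(self):
        rng = np.random.default_rng(9)
        chains = rng.random((50, 4, 1))
        lp = rng.normal(-10, 1, (50, 4))
        lp[17, 2] = 5.0
        post = self._post(chains, lp)
        assert map_estimate(post)[0] == chains[17, 2, 0]

    def test_matches_scan_oracle_with_first_tie(self):
        rng = np.random.default_rng(10)
        chains = rng.random((30, 3, 1))
        lp = np.round(rng.normal(-5, 1, (30, 3)), 1)  # force ties
        post = self._post(chains, lp)
        flat_lp = lp.reshape(-1)
        idx = next(i for i in range(len(flat_lp)) if flat_lp[i] == flat_lp.max())
        assert map_estimate(post)[0] == chains.reshape(-1, 1)[idx, 0]


class TestCredibleBand:
    def test_degenerate_posterior_collapses(self):
        chains = np.tile(np.array([0.5, 2.0]), (40, 6, 1))
        lp = np.zeros((40, 6))
        post = PosteriorSample(chains, lp, ["a", "b"],
                               np.array([[0, 1], [0, 3]]), 0, np.ones(6))
        traj = np.arange(5.0)
        band = credible_band(post, lambda th, rng: traj * th[0], n_draws=200, seed=1)
        assert np.allclose(band["lower"], 0.5 * traj)
        assert np.allclose(band["upper"], 0.5 * traj)

    def test_gaussian_predictive_quantiles(self):
        chains = np.zeros((200, 10, 1))
        post = PosteriorSample(chains, np.zeros((200, 10)), ["a"],
                               np.array([[-1, 1]]), 0, np.ones(10))
        band = credible_band(post, lambda th, rng: rng.normal(0, 1, 3),
                             n_draws=8000, level=0.99, seed=2)
        z = stats.norm.ppf(0.995)
        assert np.allclose(band["upper"], z, atol=0.15)
        assert np.allclose(band["lower"], -z, atol=0.15)

    def test_full_level_spans_min_max(self):
        chains = np.linspace(0, 1, 120).reshape(20, 6, 1)
        post = PosteriorSample(chains, np.zeros((20, 6)), ["a"],
                               np.array([[0, 1]]), 0, np.ones(6))
        band = credible_band(post, lambda th, rng: np.array([th[0]]),
                             n_draws=5000, level=1.0, seed=3)
        flat, _ = post.flat(0.5)
        assert band["upper"][0] == flat.max()
        assert band["lower"][0] == flat.min()


class TestCalibrationProblem:
    def test_cached_equals_full_likelihood(self, short_site):
        cfg, drivers, obs = short_site
        names = ["psi_0", "t_0", "b", "tau_g", "E_moe", "z0", "z1"]
        prob = CalibrationProblem(drivers, obs.tree, obs.j_obs.to_numpy(),
                                  obs.d_obs.to_numpy(), cfg.soil, names)
        assert prob._cache is not None
        rng = np.random.default_rng(6)
        lo, hi = prob.bounds[:, 0], prob.bounds[:, 1]
        for _ in range(5):
            th = lo + (hi - lo) * rng.random(len(lo))
            fast = prob.log_likelihood(th, use_cache=True)
            slow = prob.log_likelihood(th, use_cache=False)
            assert fast == pytest.approx(slow, rel=1e-12)

    def test_cache_disabled_outside_safe_subset(self, short_site):
        cfg, drivers, obs = short_site
        prob = CalibrationProblem(drivers, obs.tree, obs.j_obs.to_numpy(),
                                  obs.d_obs.to_numpy(), cfg.soil,
                                  ["psi_0", "gamma"])
        assert prob._cache is None

    def test_priors_cover_table_scopes(self):
        priors = default_priors("peat")
        assert priors["E_moe"].scope == "per_tree_year"
        assert priors["z0"].lo == -7.0 and priors["z0"].hi == -2.0
        assert priors["phi_max"].lo == pytest.approx(4e-3)
        mineral = default_priors("mineral")
        assert mineral["E_moe"].hi == 1500.0
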