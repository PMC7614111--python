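import math

import numpy as np
import pytest

from bgwr.dataset import SpatialDataset
from bgwr.families import PriorSpec, get_family
from bgwr.kernels import KernelSpec, WeightVector, compute_weight_vector
from bgwr.mcmc import (
    ChainResult,
    MCMCConfig,
    _split_rhat,
    fit_all_locations,
    sample_powered_posterior,
    summarize_chains,
)
from bgwr.posterior import PoweredPosteriorProblem
from bgwr.simulate import simulate_gaussian_toy

from conftest import pooled_mcse


def _gaussian_problem(ds, center, weights, prior=None):
    wv = WeightVector(center, dict(weights))
    return PoweredPosteriorProblem(ds, center, wv, "gaussian", prior or PriorSpec())


class TestSampler:
    def test_same_seed_identical_draws(self, gaussian_toy3):
        prob = _gaussian_problem(
            gaussian_toy3, "loc0", {"loc0": 1.0, "loc1": 0.5, "loc2": 0.1}
        )
        cfg = MCMCConfig(n_chains=2, n_iterations=200, burn_in=100, seed=42)
        a = sample_powered_posterior(prob, cfg)
        b = sample_powered_posterior(prob, cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_conjugate_weighted_posterior(self, gaussian_toy3):
        # known sd: posterior precision = prior precision + sum_i W_i m_i,
        # posterior mean = precision-weighted sum of the weighted data
        weights = {"loc0": 1.0, "loc1": 0.5, "loc2": 0.1}
        prior = PriorSpec(phi_sd=10.0)
        prob = _gaussian_problem(gaussian_toy3, "loc0", weights, prior)
        cfg = MCMCConfig(n_chains=2, n_iterations=2000, burn_in=500, seed=3, fix_theta=1.0)
        res = sample_powered_posterior(prob, cfg)
        phi = res.pooled()[:, 1]
        ds = gaussian_toy3
        prec = 1 / prior.phi_sd**2 + sum(w * ds.m(l) for l, w in weights.items())
        mean = sum(w * ds.outcomes[l].sum() for l, w in weights.items()) / prec
        sd = math.sqrt(1 / prec)
        assert phi.mean() == pytest.approx(mean, abs=3 * pooled_mcse(phi))
        assert phi.std() == pytest.approx(sd, rel=0.15)

    def test_augmented_target_matches_grid_oracle(self):
        # 2-location NB toy, p=1: marginal mean/sd of (phi, theta_center)
        # from a brute-force grid over (phi, log th0, log th1) — checks the
        # full augmented target including the joint theta~ updates
        rng = np.random.default_rng(12)
        from bgwr.simulate import nb_rvs

        y0 = nb_rvs(rng, np.full(25, 5.0), 0.5).astype(float)
        y1 = nb_rvs(rng, np.full(25, 7.0), 0.8).astype(float)
        from bgwr.dataset import Location

        ds = SpatialDataset(
            locations=[Location("c", 0, 0), Location("n", 1, 0)],
            outcomes={"c": y0, "n": y1},
            covariates={"c": np.ones((25, 1)), "n": np.ones((25, 1))},
            family="negative_binomial",
        )
        w = 0.7
        prior = PriorSpec()
        prob = PoweredPosteriorProblem(
            ds, "c", WeightVector("c", {"c": 1.0, "n": w}), "negative_binomial", prior
        )
        fam = get_family("negative_binomial")

        phis = np.linspace(0.8, 2.4, 60)
        lts = np.linspace(-2.5, 1.0, 60)
        # vectorized log target on the 3-d grid
        ll0 = np.array(
            [[np.sum(fam.log_density(y0, p, math.exp(t))) for t in lts] for p in phis]
        )  # (phi, t0)
        ll1 = np.array(
            [[np.sum(fam.log_density(y1, p, math.exp(t))) for t in lts] for p in phis]
        )
        lp_phi = np.array([prior.log_phi_prior(np.array([p])) for p in phis])
        lp_t = np.array([prior.log_logtheta_prior(np.array([t])) for t in lts])
        grid = (
            ll0[:, :, None]
            + w * ll1[:, None, :]
            + lp_phi[:, None, None]
            + lp_t[None, :, None]
            + lp_t[None, None, :]
        )
        dens = np.exp(grid - grid.max())
        dens /= dens.sum()
        marg_phi = dens.sum(axis=(1, 2))
        marg_t0 = dens.sum(axis=(0, 2))
        want_phi_mean = float(phis @ marg_phi)
        want_phi_sd = math.sqrt(float((phis - want_phi_mean) ** 2 @ marg_phi))
        want_th_mean = float(np.exp(lts) @ marg_t0)

        cfg = MCMCConfig(n_chains=2, n_iterations=4000, burn_in=1000, seed=5)
        res = sample_powered_posterior(prob, cfg)
        phi = res.pooled()[:, 1]
        th = res.pooled()[:, 0]
        assert phi.mean() == pytest.approx(want_phi_mean, abs=4 * pooled_mcse(phi))
        assert phi.std() == pytest.approx(want_phi_sd, rel=0.2)
        assert th.mean() == pytest.approx(want_th_mean, abs=4 * pooled_mcse(th))

    def test_acceptance_rates_near_targets(self, nb_small_lattice):
        ds, _ = nb_small_lattice
        spec = KernelSpec("truncated_gaussian", 2.0, 0.01)
        wv = compute_weight_vector(ds, "3_3", spec)
        prob = PoweredPosteriorProblem(ds, "3_3", wv, "negative_binomial", PriorSpec())
        cfg = MCMCConfig(n_chains=2, n_iterations=1000, burn_in=800, seed=1)
        res = sample_powered_posterior(prob, cfg)
        for rate in res.acceptance["phi_block"]:
            assert abs(rate - cfg.target_accept_block) < 0.15
        for rate in res.acceptance["theta_scalar"]:
            assert abs(rate - cfg.target_accept_scalar) < 0.15

    def test_initialization_failure_reported(self):
        ds = simulate_gaussian_toy(1, [0.0], 1.0, 5, seed=0)
        ds.outcomes["loc0"] = ds.outcomes["loc0"] * np.inf  # poisoned data
        prob = _gaussian_problem(ds, "loc0", {"loc0": 1.0})
        with pytest.raises(RuntimeError, match="initialization"):
            sample_powered_posterior(prob, MCMCConfig(n_chains=1, n_iterations=10, burn_in=5))


class TestFitAllLocations:
    def test_permutation_invariance(self, gaussian_toy3):
        ds = gaussian_toy3
        perm = SpatialDataset(
            locations=list(reversed(ds.locations)),
            outcomes=dict(ds.outcomes),
            covariates=dict(ds.covariates),
            offsets=dict(ds.offsets),
            metric=ds.metric,
            family=ds.family,
            covariate_names=list(ds.covariate_names),
        )
        spec = KernelSpec("gaussian", 2.0)
        cfg = MCMCConfig(n_chains=1, n_iterations=100, burn_in=60, seed=9)
        a = fit_all_locations(ds, spec, "gaussian", PriorSpec(), cfg)
        b = fit_all_locations(perm, spec, "gaussian", PriorSpec(), cfg)
        for lid in ds.location_ids:
            np.testing.assert_array_equal(a[lid].draws, b[lid].draws)

    def test_single_location_degenerate(self):
        ds = simulate_gaussian_toy(1, [2.0], 1.0, 10, seed=5)
        cfg = MCMCConfig(n_chains=1, n_iterations=150, burn_in=80, seed=2)
        res = fit_all_locations(ds, KernelSpec("gaussian", 1.0), "gaussian", PriorSpec(), cfg)
        prob = _gaussian_problem(ds, "loc0", {"loc0": 1.0})
        direct = sample_powered_posterior(prob, cfg)
        np.testing.assert_array_equal(res["loc0"].draws, direct.draws)

    def test_pooled_limit_on_lattice(self):
        # huge bandwidth -> all weights 1 -> every location's phi posterior
        # equals the pooled standard posterior (known sd conjugate form)
        means = np.full(9, 1.5)
        coords = [(u, v) for u in range(3) for v in range(3)]
        ds = simulate_gaussian_toy(9, means, 1.0, 8, coords=coords, seed=21)
        prior = PriorSpec(phi_sd=10.0)
        cfg = MCMCConfig(n_chains=2, n_iterations=1200, burn_in=400, seed=4, fix_theta=1.0)
        res = fit_all_locations(ds, KernelSpec("gaussian", 1e6), "gaussian", prior, cfg)
        total = sum(ds.outcomes[l].sum() for l in ds.location_ids)
        n = sum(ds.m(l) for l in ds.location_ids)
        prec = 1 / prior.phi_sd**2 + n
        pooled_mean = total / prec
        for lid in ds.location_ids:
            phi = res[lid].pooled()[:, 1]
            assert phi.mean() == pytest.approx(pooled_mean, abs=4 * pooled_mcse(phi))


class TestSummaries:
    def _result(self, draws):
        draws = np.asarray(draws, dtype=float)[:, :, None]
        return ChainResult("c", draws, ["theta"])

    def test_identical_chains(self):
        res = self._result([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        s = summarize_chains(res)
        assert s.loc["theta", "mean"] == 2.0
        assert s.loc["theta", "median"] == 2.0

    def test_constant_chains_rhat_one(self):
        res = self._result([[5.0] * 4, [5.0] * 4])
        assert summarize_chains(res).loc["theta", "rhat"] == 1.0

    def test_single_chain_warns(self):
        res = self._result([[1.0, 2.0, 3.0, 4.0]])
        with pytest.warns(RuntimeWarning, match="R-hat"):
            s = summarize_chains(res)
        assert np.isnan(s.loc["theta", "rhat"])

    def test_shifted_chains_raise_rhat(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(2, 400))
        shifted = base + np.array([[0.0], [3.0]])
        assert _split_rhat(shifted) > _split_rhat(base) * 1.5
        assert _split_rhat(base) == pytest.approx(1.0, abs=0.05)

    def test_quantiles_match_declared_rule(self):
        draws = np.arange(1.0, 101.0).reshape(2, 50)
        s = summarize_chains(ChainResult("c", draws[:, :, None], ["theta"]))
        assert s.loc["theta", "median"] == pytest.approx(50.5)
        assert s.loc["theta", "ci_lower"] == pytest.approx(np.quantile(np.arange(1.0, 101.0), 0.025))


class TestParallelScheduling:
    def test_n_jobs_does_not_change_results(self, gaussian_toy3):
        ds = gaussian_toy3
        spec = KernelSpec("gaussian", 2.0)
        cfg = MCMCConfig(n_chains=2, n_iterations=80, burn_in=40, seed=17)
        serial = fit_all_locations(ds, spec, "gaussian", PriorSpec(), cfg, n_jobs=1)
        parallel = fit_all_locations(ds, spec, "gaussian", PriorSpec(), cfg, n_jobs=2)
        for lid in ds.location_ids:
            np.testing.assert_array_equal(serial[lid].draws, parallel[lid].draws)
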