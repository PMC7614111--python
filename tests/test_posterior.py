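import math

import numpy as np
import pytest

from bgwr.families import ParameterState, PriorSpec, get_family
from bgwr.kernels import WeightVector
from bgwr.posterior import (
    PoweredPosteriorProblem,
    log_powered_posterior,
    log_single_location_posterior,
    truncation_relative_change,
)
from bgwr.simulate import simulate_gaussian_toy


def _two_loc_ds(y_center=1.0, y_other=3.0):
    """Two Gaussian locations, one observation each, intercept-only design."""
    ds = simulate_gaussian_toy(2, [0.0, 0.0], 1.0, 1, coords=[(0, 0), (1, 0)], seed=0)
    ds.outcomes["loc0"] = np.array([y_center])
    ds.outcomes["loc1"] = np.array([y_other])
    return ds


def _problem(ds, weights, prior=None):
    wv = WeightVector("loc0", dict(weights))
    return PoweredPosteriorProblem(ds, "loc0", wv, "gaussian", prior or PriorSpec())


class TestPoweredPosterior:
    def test_hand_computed_value(self):
        # centre y=1, neighbour y=3 at weight 0.5, theta=1 everywhere, phi=0,
        # prior phi ~ N(0, 10^2).  Likelihood/phi-prior part:
        #   -3.2215236 + (-1.4189385) + 0.5*(-5.4189385) = -7.3499314
        # theta prior terms (lognormal at theta=1, twice) are subtracted off.
        ds = _two_loc_ds()
        prior = PriorSpec(phi_sd=10.0)
        prob = _problem(ds, {"loc0": 1.0, "loc1": 0.5}, prior)
        state = ParameterState(1.0, np.zeros(1), {"loc1": 1.0})
        got = log_powered_posterior(state, prob) - prior.log_theta_prior([1.0, 1.0])
        assert got == pytest.approx(-7.3499314, abs=1e-6)

    def test_pure_function(self):
        ds = _two_loc_ds()
        prob = _problem(ds, {"loc0": 1.0, "loc1": 0.5})
        state = ParameterState(1.3, np.array([0.2]), {"loc1": 0.7})
        assert log_powered_posterior(state, prob) == log_powered_posterior(state, prob)

    def test_cut_limit_equals_single_location(self):
        ds = _two_loc_ds()
        prob = _problem(ds, {"loc0": 1.0, "loc1": 0.0})
        rng = np.random.default_rng(7)
        for _ in range(5):
            theta = float(rng.uniform(0.3, 3))
            phi = rng.normal(size=1)
            state = ParameterState(theta, phi, {})
            got = log_powered_posterior(state, prob)
            want = log_single_location_posterior(theta, phi, "loc0", ds, "gaussian", PriorSpec())
            assert got == pytest.approx(want)

    def test_all_weights_one_equals_standard_joint(self):
        # weights all 1: prior + sum of per-location likelihoods with each
        # location's own dispersion — the standard joint posterior factorization
        ds = simulate_gaussian_toy(3, [0.0, 1.0, 2.0], 1.0, 4, seed=2)
        wv = WeightVector("loc0", {"loc0": 1.0, "loc1": 1.0, "loc2": 1.0})
        prior = PriorSpec()
        prob = PoweredPosteriorProblem(ds, "loc0", wv, "gaussian", prior)
        fam = get_family("gaussian")
        rng = np.random.default_rng(8)
        for _ in range(5):
            state = ParameterState(
                float(rng.uniform(0.5, 2)),
                rng.normal(size=1),
                {"loc1": float(rng.uniform(0.5, 2)), "loc2": float(rng.uniform(0.5, 2))},
            )
            want = prior.log_phi_prior(state.phi)
            thetas = {"loc0": state.theta_center, **state.theta_aux}
            want += prior.log_theta_prior(np.array(list(thetas.values())))
            for lid, th in thetas.items():
                eta = ds.covariates[lid] @ state.phi
                want += float(np.sum(fam.log_density(ds.outcomes[lid], eta, th)))
            assert log_powered_posterior(state, prob) == pytest.approx(want)

    def test_missing_aux_entry_raises(self):
        ds = _two_loc_ds()
        prob = _problem(ds, {"loc0": 1.0, "loc1": 0.5})
        state = ParameterState(1.0, np.zeros(1), {})
        with pytest.raises(ValueError, match="theta_aux"):
            log_powered_posterior(state, prob)


class TestSingleLocationPosterior:
    def test_conjugate_grid_posterior(self):
        # known sd=1: normalized over a phi grid, the exponentiated density
        # must match the closed-form normal posterior
        ds = simulate_gaussian_toy(1, [1.5], 1.0, 30, seed=4)
        prior = PriorSpec(phi_sd=10.0)
        y = ds.outcomes["loc0"]
        grid = np.linspace(0, 3, 2001)
        logpost = np.array(
            [log_single_location_posterior(1.0, np.array([v]), "loc0", ds, "gaussian", prior) for v in grid]
        )
        dens = np.exp(logpost - logpost.max())
        dens /= np.trapezoid(dens, grid)
        prec = 1 / prior.phi_sd**2 + len(y)
        mean = y.sum() / prec
        np.testing.assert_allclose(np.trapezoid(grid * dens, grid), mean, atol=1e-3)
        var = np.trapezoid((grid - mean) ** 2 * dens, grid)
        np.testing.assert_allclose(var, 1 / prec, rtol=1e-2)

    def test_unknown_location_raises(self):
        ds = _two_loc_ds()
        with pytest.raises(KeyError):
            log_single_location_posterior(1.0, np.zeros(1), "zzz", ds, "gaussian", PriorSpec())


class TestLargeSampleLimit:
    def test_grid_mode_approaches_weighted_mean(self):
        # Gaussian mean model with known sd: at large m the posterior mode
        # approaches the kernel-weighted average of the per-location means
        means = [0.0, 2.0, 5.0]
        weights = {"loc0": 1.0, "loc1": 0.6, "loc2": 0.2}
        ds = simulate_gaussian_toy(3, means, 1.0, 4000, seed=9)
        prob = _problem(ds, weights)
        target = sum(w * mu for w, mu in zip(weights.values(), means)) / sum(weights.values())
        grid = np.linspace(target - 1, target + 1, 801)
        vals = np.array(
            [
                log_powered_posterior(
                    ParameterState(1.0, np.array([v]), {"loc1": 1.0, "loc2": 1.0}), prob
                )
                for v in grid
            ]
        )
        mode = grid[np.argmax(vals)]
        assert mode == pytest.approx(target, abs=0.05)

    def test_weight_pulls_mean_toward_neighbour(self):
        # grid-normalized posterior mean of phi moves monotonically toward the
        # neighbour's sample mean as its weight rises
        ds = _two_loc_ds(y_center=0.0, y_other=4.0)
        grid = np.linspace(-3, 6, 1201)
        means = []
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            prob = _problem(ds, {"loc0": 1.0, "loc1": w})
            aux = {"loc1": 1.0} if w > 0 else {}
            vals = np.array(
                [
                    log_powered_posterior(ParameterState(1.0, np.array([v]), dict(aux)), prob)
                    for v in grid
                ]
            )
            dens = np.exp(vals - vals.max())
            dens /= dens.sum()
            means.append(float(grid @ dens))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestTruncationDiagnostic:
    def _draws(self, n=4, seed=0):
        rng = np.random.default_rng(seed)
        return [
            ParameterState(
                float(rng.uniform(0.5, 2)), rng.normal(size=1), {"loc1": float(rng.uniform(0.5, 2))}
            )
            for _ in range(n)
        ]

    def test_zero_threshold_zero_change(self):
        ds = _two_loc_ds()
        rep = truncation_relative_change(
            self._draws(), ds, "loc0", 1.0, 0.0, "gaussian", PriorSpec()
        )
        np.testing.assert_array_equal(rep.per_draw_changes, 0.0)
        assert rep.max_abs_pct_change == 0.0

    def test_two_location_hand_value(self):
        # threshold removes the single weighted term: change = 100|W1 l1| / |total|
        ds = _two_loc_ds()
        prior = PriorSpec()
        eta = 1.0
        state = ParameterState(1.0, np.zeros(1), {"loc1": 1.0})
        w1 = math.exp(-1.0)  # d=1, eta=1
        fam = get_family("gaussian")
        l1 = float(np.sum(fam.log_density(ds.outcomes["loc1"], 0.0, 1.0)))
        full = log_single_location_posterior(1.0, np.zeros(1), "loc0", ds, "gaussian", prior)
        full += prior.log_theta_prior(1.0) + w1 * l1
        expected = 100.0 * abs(w1 * l1) / abs(full)
        rep = truncation_relative_change([state], ds, "loc0", eta, 0.5, "gaussian", prior)
        assert rep.per_draw_changes[0] == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_threshold(self):
        ds = simulate_gaussian_toy(4, [0, 1, 2, 3], 1.0, 3, coords=[(0, 0), (1, 0), (2, 0), (3, 0)], seed=3)
        state = ParameterState(1.0, np.zeros(1), {f"loc{i}": 1.0 for i in (1, 2, 3)})
        changes = []
        for wstar in (0.0, 0.05, 0.2, 0.5, 0.9):
            rep = truncation_relative_change([state], ds, "loc0", 1.5, wstar, "gaussian", PriorSpec())
            changes.append(rep.max_abs_pct_change)
        assert all(b >= a for a, b in zip(changes, changes[1:]))

    def test_requires_full_support(self):
        ds = _two_loc_ds()
        state = ParameterState(1.0, np.zeros(1), {})
        with pytest.raises(ValueError, match="all non-centre"):
            truncation_relative_change([state], ds, "loc0", 1.0, 0.1, "gaussian", PriorSpec())
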