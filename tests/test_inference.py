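"""Tests for the likelihood, priors, population MCMC, and evidence stack."""

import numpy as np
import pytest
from scipy.stats import norm

from yeastcolony import (Hypothesis, generate_growth_curves,
                         hypothesis_posterior, log_likelihood, log_prior,
                         make_ladder, psrf, run_population_mcmc,
                         thermodynamic_evidence)
from yeastcolony.inference import (FAILED_SOLVE_LOGLIK, MCMCConfig,
                                   TemperatureLadder, make_growth_loglik,
                                   swap_log_accept)
from yeastcolony.synthdata import GrowthDataset, default_truth_vector


class TestLikelihood:
    def test_perfect_fit_equals_normalization(self, truth):
        """At an exact fit, only the Gaussian normalization constants
        remain: -1/2 sum log(2 pi v_k) - 1/2 log(2 pi s_e^2) - ..."""
        from yeastcolony import simulate_microenv, steady_fractions, total_mass

        params, init = truth
        times = np.arange(0.0, 88.25, 0.25)
        traj = simulate_microenv(params, init, times, "H2")
        fe, fq = steady_fractions(traj, 80.0)
        v = np.full(times.size, 3.7e-4)
        data = GrowthDataset(times=times, mean_mass=total_mass(traj),
                             variance=v, n_replicates=6, alpha_e=fe,
                             alpha_q=fq, sigma_alpha_e=0.02,
                             sigma_alpha_q=0.02, t_N=80.0)
        expected = (-0.5 * np.sum(np.log(2 * np.pi * v))
                    - 0.5 * np.log(2 * np.pi * 0.02 ** 2) * 2)
        got = log_likelihood(data, default_truth_vector(), "H2")
        assert got == pytest.approx(expected, abs=0.5)  # integrator error

    def test_doubling_variances_at_perfect_fit(self, truth):
        """With zero residuals only the normalizations change: doubling
        every curve variance lowers the log-likelihood by N/2 * log 2."""
        from yeastcolony import simulate_microenv, steady_fractions, total_mass

        params, init = truth
        times = np.arange(0.0, 88.25, 0.25)
        traj = simulate_microenv(params, init, times, "H2")
        fe, fq = steady_fractions(traj, 80.0)

        def make(v):
            return GrowthDataset(times=times, mean_mass=total_mass(traj),
                                 variance=v, n_replicates=6, alpha_e=fe,
                                 alpha_q=fq, sigma_alpha_e=0.02,
                                 sigma_alpha_q=0.02, t_N=80.0)

        v = np.full(times.size, 3.7e-4)
        theta = default_truth_vector()
        base = log_likelihood(make(v), theta, "H2")
        doubled = log_likelihood(make(2 * v), theta, "H2")
        assert doubled - base == pytest.approx(
            -0.5 * times.size * np.log(2.0), abs=0.05)

    def test_composition_only_dataset(self, truth):
        data = GrowthDataset(times=np.array([]), mean_mass=np.array([]),
                             variance=np.array([]), n_replicates=6,
                             alpha_e=0.29, alpha_q=0.62, sigma_alpha_e=0.02,
                             sigma_alpha_q=0.02, t_N=80.0)
        ll = log_likelihood(data, default_truth_vector(), "H2", fast=False)
        # exactly two Gaussian summands, both near their means
        cap = -np.log(2 * np.pi * 0.02 ** 2)
        assert ll <= cap + 1e-9
        assert ll > cap - 2.0

    def test_failed_solve_returns_sentinel(self, growth_data):
        theta = np.full(9, 29.0)  # wild but within the hard bound
        assert log_likelihood(growth_data, theta, "H2") == \
            FAILED_SOLVE_LOGLIK

    def test_fast_and_stiff_paths_agree(self, growth_data):
        theta = default_truth_vector()
        fast = log_likelihood(growth_data, theta, "H2", fast=True)
        slow = log_likelihood(growth_data, theta, "H2", fast=False)
        assert fast == pytest.approx(slow, abs=0.05)

    def test_closure_matches_function(self, growth_data):
        theta = default_truth_vector()
        fn = make_growth_loglik(growth_data, "H2")
        assert fn(theta) == log_likelihood(growth_data, theta, "H2")


class TestPrior:
    def test_zero_vector_density(self):
        d = 9
        assert log_prior(np.zeros(d)) == pytest.approx(
            -d / 2 * np.log(2 * np.pi))

    def test_symmetry_and_coordinate_increment(self, rng):
        theta = rng.normal(0, 1, 10)
        assert log_prior(theta) == pytest.approx(log_prior(-theta))
        ext = np.concatenate([theta, [0.0]])
        assert log_prior(ext) - log_prior(theta) == pytest.approx(
            -0.5 * np.log(2 * np.pi))


class TestLadder:
    def test_endpoints_and_formula(self):
        lad = make_ladder(30)
        assert lad.betas[0] == 0.0
        assert lad.betas[-1] == 1.0
        assert lad.betas[1] == pytest.approx((1 / 29) ** 5)
        assert lad.n_beta == 30

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_ladder(1)
        with pytest.raises(ValueError):
            TemperatureLadder(np.array([0.0, 0.5, 0.4, 1.0]))


def _gaussian_toy(y_obs=0.8, sigma=0.5):
    def ll(theta):
        return float(-0.5 * ((y_obs - theta[0]) / sigma) ** 2
                     - np.log(sigma * np.sqrt(2 * np.pi)))
    log_z = float(norm.logpdf(y_obs, 0.0, np.sqrt(1 + sigma ** 2)))
    post_mean = y_obs / (1 + sigma ** 2)
    post_var = sigma ** 2 / (1 + sigma ** 2)
    return ll, log_z, post_mean, post_var


class TestPopulationMCMC:
    def test_prior_chain_moments(self):
        ll, *_ = _gaussian_toy()
        chains = run_population_mcmc(
            ll, 1, make_ladder(5),
            MCMCConfig(n_burn=1000, n_keep=4000, thin=1, seed=0))
        prior_samples = chains.samples[0][:, 0]
        se = 1.0 / np.sqrt(len(prior_samples) / 10)  # crude ESS discount
        assert abs(prior_samples.mean()) < 4 * se
        assert prior_samples.var() == pytest.approx(1.0, abs=0.15)

    def test_posterior_chain_matches_conjugate(self):
        ll, _, mu, var = _gaussian_toy()
        chains = run_population_mcmc(
            ll, 1, make_ladder(5),
            MCMCConfig(n_burn=1000, n_keep=4000, thin=1, seed=1))
        post = chains.samples[-1][:, 0]
        se = np.sqrt(var / (len(post) / 10))
        assert post.mean() == pytest.approx(mu, abs=3 * se)
        assert post.var() == pytest.approx(var, rel=0.2)

    def test_same_seed_identical(self):
        ll, *_ = _gaussian_toy()
        cfg = MCMCConfig(n_burn=200, n_keep=100, thin=1, seed=42)
        a = run_population_mcmc(ll, 1, make_ladder(4), cfg)
        b = run_population_mcmc(ll, 1, make_ladder(4), cfg)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.logliks, b.logliks)

    def test_swap_acceptance_detailed_balance(self):
        """On a discrete two-state toy, the exchange kernel satisfies
        detailed balance with respect to the product target."""
        betas = (0.2, 1.0)
        ll_states = {0: np.log(0.3), 1: np.log(2.0)}
        # pi_i(x) proportional to exp(beta_i * ll(x)) with flat prior
        def target(i, x):
            return np.exp(betas[i] * ll_states[x])

        for xa in (0, 1):
            for xb in (0, 1):
                fwd = min(1.0, np.exp(swap_log_accept(
                    betas[0], betas[1], ll_states[xa], ll_states[xb])))
                rev = min(1.0, np.exp(swap_log_accept(
                    betas[0], betas[1], ll_states[xb], ll_states[xa])))
                lhs = target(0, xa) * target(1, xb) * fwd
                rhs = target(0, xb) * target(1, xa) * rev
                assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_hdf5_round_trip(self, tmp_path):
        ll, *_ = _gaussian_toy()
        cfg = MCMCConfig(n_burn=100, n_keep=50, thin=1, seed=3)
        ch = run_population_mcmc(ll, 1, make_ladder(3), cfg)
        path = tmp_path / "chains.h5"
        ch.to_hdf5(path)
        from yeastcolony.inference import ChainSet
        back = ChainSet.from_hdf5(path)
        assert np.array_equal(back.samples, ch.samples)
        assert np.array_equal(back.logliks, ch.logliks)
        assert back.seed == ch.seed


class TestEvidence:
    def test_conjugate_toy_evidence(self):
        ll, log_z, *_ = _gaussian_toy()
        chains = run_population_mcmc(
            ll, 1, make_ladder(10),
            MCMCConfig(n_burn=1500, n_keep=3000, thin=1, seed=5))
        z, se = thermodynamic_evidence(chains)
        assert z == pytest.approx(log_z, abs=0.1)

    def test_constant_likelihood_gives_zero(self):
        def ll(theta):
            return 0.0
        chains = run_population_mcmc(
            ll, 2, make_ladder(4),
            MCMCConfig(n_burn=100, n_keep=100, thin=1, seed=0))
        z, se = thermodynamic_evidence(chains)
        assert z == 0.0 and se == 0.0

    def test_ladder_refinement_reduces_error(self):
        ll, log_z, *_ = _gaussian_toy(y_obs=1.5, sigma=0.3)
        errs = {}
        for n_beta in (4, 12):
            e = []
            for seed in range(12):
                ch = run_population_mcmc(
                    ll, 1, make_ladder(n_beta),
                    MCMCConfig(n_burn=500, n_keep=1500, thin=1, seed=seed))
                z, _ = thermodynamic_evidence(ch)
                e.append(abs(z - log_z))
            errs[n_beta] = np.mean(e)
        assert errs[12] < errs[4]


class TestHypothesisPosterior:
    def test_uniform_cases(self):
        assert np.allclose(hypothesis_posterior([0.0, 0.0, 0.0]),
                           np.full(3, 1 / 3))
        p = hypothesis_posterior([0.0, -np.log(9.0)])
        assert np.allclose(p, [0.9, 0.1])

    def test_minus_inf_excluded(self):
        p = hypothesis_posterior([0.0, -np.inf])
        assert p[1] == 0.0 and p[0] == 1.0

    def test_all_minus_inf_rejected(self):
        with pytest.raises(ValueError):
            hypothesis_posterior([-np.inf, -np.inf])

    def test_nonuniform_prior(self):
        p = hypothesis_posterior([0.0, 0.0], [0.8, 0.2])
        assert np.allclose(p, [0.8, 0.2])
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestPSRF:
    def test_identical_chains_finite_sample_factor(self, rng):
        c = rng.normal(0, 1, (500, 3))
        n = c.shape[0]
        r = psrf([c, c.copy()])
        assert np.allclose(r, np.sqrt((n - 1) / n))

    def test_disjoint_chains_large(self, rng):
        a = rng.normal(0, 1, (400, 2))
        b = rng.normal(50, 1, (400, 2))
        r = psrf([a, b])
        # brute-force evaluation of the between/within form
        m, n = 2, 400
        w = (a.var(ddof=1, axis=0) + b.var(ddof=1, axis=0)) / 2
        bt = n * np.stack([a.mean(0), b.mean(0)]).var(axis=0, ddof=1)
        vh = (n - 1) / n * w + (1 + 1 / m) * bt / n
        assert np.allclose(r, np.sqrt(vh / w))
        assert np.all(r > 10)

    def test_affine_invariance(self, rng):
        a = rng.normal(0, 1, (300, 2))
        b = rng.normal(0.2, 1.1, (300, 2))
        r1 = psrf([a, b])
        r2 = psrf([5 * a + 3, 5 * b + 3])
        assert np.allclose(r1, r2)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            psrf([rng.normal(size=(10, 2))])
        with pytest.raises(ZeroDivisionError):
            psrf([np.ones((10, 1)), np.ones((10, 1))])


def test_growth_data_under_truth_is_probable(growth_data):
    """The generating parameters should sit in the bulk of their own
    likelihood: no gross mis-specification between generator and model."""
    theta = default_truth_vector()
    ll = log_likelihood(growth_data, theta, "H2")
    n = growth_data.times.size
    # perfect-fit ceiling minus the chi-square scale of n residuals
    ceiling = -0.5 * np.sum(np.log(2 * np.pi * growth_data.variance)) \
        - np.log(2 * np.pi * 0.02 ** 2)
    assert ll > ceiling - 3 * n
    assert ll < ceiling + 1
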