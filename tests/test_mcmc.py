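"""Metropolis–Hastings sampler: closed-form densities, proposal statistics,
prior recovery under a flat likelihood, quantile summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from amoxkin.datasets import TimeSeriesDataset, generate_dataset
from amoxkin.kinetics import InvalidInputError
from amoxkin.mcmc import (
    Chain,
    MCMCConfig,
    credible_interval,
    log_likelihood,
    log_prior,
    posterior_summary,
    propose,
    run_mcmc,
    run_mcmc_tuned,
)
from amoxkin.simulate import simulate


def _config(p0, **kw):
    return MCMCConfig(p0=tuple(np.atleast_1d(np.asarray(p0, float))), **kw)


def _batch_means_se(samples, n_batches=40):
    n = (samples.shape[0] // n_batches) * n_batches
    bm = samples[:n].reshape(n_batches, -1, samples.shape[1]).mean(axis=1)
    return bm.std(axis=0, ddof=1) / math.sqrt(n_batches)


class TestLogPrior:
    def test_maximal_at_p0(self):
        cfg = _config([1.0, 2.0], n_iter=10)
        at_mode = log_prior(np.array([1.0, 2.0]), cfg)
        rng = np.random.default_rng(0)
        for _ in range(20):
            other = np.abs(np.array([1.0, 2.0]) + 0.3 * rng.standard_normal(2))
            assert log_prior(other, cfg) <= at_mode

    def test_nonpositive_component_is_impossible(self):
        cfg = _config([1.0, 1.0], n_iter=10)
        assert log_prior(np.array([1.0, 0.0]), cfg) == -math.inf
        assert log_prior(np.array([-0.5, 1.0]), cfg) == -math.inf

    def test_one_sd_displacement_costs_half(self):
        cfg = _config([1.0, 1.0], n_iter=10, prior_rel_sd=0.6)
        drop = log_prior(np.array([1.0, 1.0]), cfg) - log_prior(np.array([1.6, 1.0]), cfg)
        assert drop == pytest.approx(0.5, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            log_prior(np.ones(3), _config([1.0, 1.0], n_iter=10))


class TestLogLikelihood:
    @pytest.fixture()
    def noiseless(self, p1_lc, lc_conditions):
        t = np.linspace(0, 240, 9)
        states = simulate("model1", p1_lc, lc_conditions, t_eval=t).states
        return TimeSeriesDataset(times=t, observations=states, noise_sd=1.0)

    def test_zero_residual_value_exact(self, noiseless, p1_lc, lc_conditions):
        val = log_likelihood(p1_lc.to_array(), noiseless, "model1", lc_conditions, 1.0)
        expect = -noiseless.n_observed * math.log(math.sqrt(2 * math.pi))
        assert val == pytest.approx(expect, abs=1e-4)

    def test_one_sd_perturbation_costs_half(self, noiseless, p1_lc, lc_conditions):
        base = log_likelihood(p1_lc.to_array(), noiseless, "model1", lc_conditions, 1.0)
        obs = noiseless.observations.copy()
        obs[3, 0] += 1.0
        bumped = TimeSeriesDataset(times=noiseless.times, observations=obs, noise_sd=1.0)
        val = log_likelihood(p1_lc.to_array(), bumped, "model1", lc_conditions, 1.0)
        assert base - val == pytest.approx(0.5, abs=1e-4)

    def test_missing_cells_contribute_nothing(self, noiseless, p1_lc, lc_conditions):
        obs = noiseless.observations.copy()
        obs[2, 1] = np.nan
        holey = TimeSeriesDataset(times=noiseless.times, observations=obs, noise_sd=1.0)
        val = log_likelihood(p1_lc.to_array(), holey, "model1", lc_conditions, 1.0)
        expect = -holey.n_observed * math.log(math.sqrt(2 * math.pi))
        assert val == pytest.approx(expect, abs=1e-4)

    def test_empty_dataset_is_flat(self, p1_lc, lc_conditions):
        empty = TimeSeriesDataset.empty()
        assert log_likelihood(p1_lc.to_array(), empty, "model1", lc_conditions, 1.0) == 0.0


class TestPropose:
    def test_zero_step_returns_previous(self):
        rng = np.random.default_rng(0)
        p = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(propose(p, 0.0, rng, p), p)

    def test_walk_is_centred_with_prescribed_scale(self):
        rng = np.random.default_rng(1)
        p0 = np.array([0.5, 5.0])
        draws = np.array([propose(p0, 0.1, rng, p0) for _ in range(10_000)])
        steps = draws - p0
        se = 0.1 * p0 / math.sqrt(10_000)
        np.testing.assert_array_less(np.abs(steps.mean(axis=0)), 3 * se)
        np.testing.assert_allclose(steps.std(axis=0), 0.1 * p0, rtol=0.05)


class TestRunMcmc:
    def test_prior_recovery_under_flat_likelihood(self, p1_lc, lc_conditions):
        # flat likelihood: the sampler must reproduce the positivity-truncated
        # Gaussian prior; oracle moments from scipy's truncnorm
        p0 = p1_lc.to_array()
        cfg = _config(p0, n_iter=50_000, w=0.6, prior_rel_sd=0.6, seed=0)
        chain = run_mcmc("model1", TimeSeriesDataset.empty(), lc_conditions, cfg)
        tn = stats.truncnorm(-1 / 0.6, np.inf, loc=1.0, scale=0.6)
        se = _batch_means_se(chain.samples)
        np.testing.assert_array_less(np.abs(chain.samples.mean(0) - tn.mean() * p0), 3 * se)
        np.testing.assert_allclose(chain.samples.std(0), tn.std() * p0, rtol=0.10)

    def test_burn_in_choice_does_not_move_the_answer(self, p1_lc, lc_conditions):
        p0 = p1_lc.to_array()
        cfg = _config(p0, n_iter=50_000, w=0.6, prior_rel_sd=0.6, seed=0)
        chain = run_mcmc("model1", TimeSeriesDataset.empty(), lc_conditions, cfg)
        se = _batch_means_se(chain.samples)
        deeper = chain.samples[chain.samples.shape[0] // 4:]
        np.testing.assert_array_less(np.abs(deeper.mean(0) - chain.samples.mean(0)), 3 * se)

    def test_null_moves_always_accepted(self, p1_lc, lc_conditions):
        cfg = _config(p1_lc.to_array(), n_iter=200, w=0.0, seed=0)
        chain = run_mcmc("model1", TimeSeriesDataset.empty(), lc_conditions, cfg)
        assert chain.acceptance_rate == 1.0

    def test_same_seed_identical_chains(self, p1_lc, lc_conditions):
        ds = generate_dataset("model1", p1_lc, lc_conditions, n_points=5, seed=0)
        cfg = _config(p1_lc.to_array(), n_iter=300, w=0.05, seed=42)
        a = run_mcmc("model1", ds, lc_conditions, cfg)
        b = run_mcmc("model1", ds, lc_conditions, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_retained_count_follows_burn_in(self, p1_lc, lc_conditions):
        cfg = _config(p1_lc.to_array(), n_iter=1000, w=0.6, burn_in_frac=0.2, seed=0)
        chain = run_mcmc("model1", TimeSeriesDataset.empty(), lc_conditions, cfg)
        assert chain.samples.shape == (800, 10)

    def test_fixed_mask_freezes_parameters(self, p1_lc, lc_conditions):
        mask = (False,) * 9 + (True,)
        cfg = _config(p1_lc.to_array(), n_iter=500, w=0.6, seed=0, fixed_mask=mask)
        chain = run_mcmc("model1", TimeSeriesDataset.empty(), lc_conditions, cfg)
        assert np.all(chain.samples[:, 9] == p1_lc.kNH)
        assert chain.samples[:, 0].std() > 0

    def test_posterior_tighter_than_prior_on_informative_data(self, p1_lc, lc_conditions):
        ds = generate_dataset("model1", p1_lc, lc_conditions, n_points=13,
                              noise_sd=1.0, seed=1)
        cfg = _config(p1_lc.to_array(), n_iter=4000, w=0.02, seed=0)
        chain = run_mcmc("model1", ds, lc_conditions, cfg)
        prior_sd_kcat1 = 0.6 * p1_lc.Kcat1
        assert chain.samples[:, 0].std() < prior_sd_kcat1


class TestTunedSampler:
    def test_matches_plain_sampler_target(self, p1_lc, lc_conditions):
        # on the prior-only target the tuned and plain samplers must agree
        p0 = p1_lc.to_array()
        cfg = _config(p0, n_iter=30_000, w=0.6, seed=3)
        tuned = run_mcmc_tuned("model1", TimeSeriesDataset.empty(), lc_conditions,
                               cfg, n_pilot=5_000, n_stages=1)
        tn = stats.truncnorm(-1 / 0.6, np.inf, loc=1.0, scale=0.6)
        np.testing.assert_allclose(tuned.samples.mean(0), tn.mean() * p0, rtol=0.10)

    def test_reproducible(self, p1_lc, lc_conditions):
        ds = generate_dataset("model1", p1_lc, lc_conditions, n_points=5, seed=0)
        cfg = _config(p1_lc.to_array(), n_iter=400, w=0.02, seed=7)
        a = run_mcmc_tuned("model1", ds, lc_conditions, cfg, n_pilot=300, n_stages=1)
        b = run_mcmc_tuned("model1", ds, lc_conditions, cfg, n_pilot=300, n_stages=1)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestSummaries:
    def _chain_from(self, samples):
        samples = np.asarray(samples, float)
        cfg = _config(np.ones(samples.shape[1]), n_iter=samples.shape[0])
        return Chain(samples=samples, acceptance_rate=0.5,
                     log_posterior_trace=np.zeros(samples.shape[0]), config=cfg)

    def test_gaussian_quantile_oracle(self):
        rng = np.random.default_rng(0)
        chain = self._chain_from(3.0 + rng.standard_normal((100_000, 1)))
        ci = credible_interval(chain, level=0.99)
        assert ci[0, 0] == pytest.approx(3.0 - 2.5758, abs=0.05)
        assert ci[0, 1] == pytest.approx(3.0 + 2.5758, abs=0.05)

    def test_constant_chain_zero_width(self):
        chain = self._chain_from(np.full((50, 2), 7.0))
        ci = credible_interval(chain, level=0.99)
        np.testing.assert_array_equal(ci, 7.0)

    def test_degenerate_level_rejected(self):
        chain = self._chain_from(np.ones((10, 1)))
        with pytest.raises(InvalidInputError):
            credible_interval(chain, level=0.0)

    def test_summary_of_constant_chain(self):
        chain = self._chain_from(np.tile([1.5, 2.5], (30, 1)))
        fr = posterior_summary(chain)
        assert list(fr.estimates.values()) == [1.5, 2.5]

    def test_summary_invariant_under_reordering(self):
        rng = np.random.default_rng(4)
        samples = rng.uniform(1, 2, size=(500, 2))
        a = posterior_summary(self._chain_from(samples))
        b = posterior_summary(self._chain_from(samples[rng.permutation(500)]))
        assert a.estimates == pytest.approx(b.estimates)
        for k in a.ci:
            assert a.ci[k] == pytest.approx(b.ci[k])


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"n_iter": 0}, {"w": -0.1}, {"prior_rel_sd": 0.0},
        {"burn_in_frac": 1.0}, {"ci_level": 1.0},
    ])
    def test_bad_settings_rejected(self, kw):
        with pytest.raises(InvalidInputError):
            _config([1.0], **kw)

    def test_nonpositive_p0_rejected(self):
        with pytest.raises(InvalidInputError):
            _config([1.0, 0.0], n_iter=10)
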