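"""Genetic algorithm: operator statistics, elitism monotonicity, convergence."""

import numpy as np
import pytest
from scipy import stats

from amoxkin.datasets import generate_dataset, scenario
from amoxkin.ga import (
    GAConfig,
    GAResult,
    crossover_scattered,
    default_bounds,
    fitness,
    init_population,
    minimize_ga,
    mutate,
    run_ga,
    select_roulette,
)
from amoxkin.kinetics import InvalidInputError, MODEL1_PARAM_NAMES
from amoxkin.simulate import simulate
from amoxkin.datasets import TimeSeriesDataset


def _cfg(d=3, **kw):
    kw.setdefault("lb", (0.1,) * d)
    kw.setdefault("ub", (10.0,) * d)
    kw.setdefault("pop_size", 20)
    kw.setdefault("n_generations", 5)
    return GAConfig(**kw)


class TestInitPopulation:
    def test_within_bounds_and_reproducible(self):
        cfg = _cfg(pop_size=50)
        a = init_population(cfg, np.random.default_rng(3))
        b = init_population(cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)
        assert np.all(a >= 0.1) and np.all(a <= 10.0)

    def test_gene_means_match_uniform(self):
        cfg = GAConfig(lb=(1.0, 4.0), ub=(3.0, 20.0), pop_size=10_000, n_generations=1)
        pop = init_population(cfg, np.random.default_rng(0))
        expect = np.array([2.0, 12.0])
        se = (np.array([2.0, 16.0]) / np.sqrt(12)) / 100.0
        np.testing.assert_array_less(np.abs(pop.mean(axis=0) - expect), 3 * se)


class TestRoulette:
    def test_best_dominates_in_the_limit(self):
        pop = np.array([[1.0], [2.0]])
        picks = select_roulette(pop, np.array([0.0, 5.0]), np.random.default_rng(0),
                                n_select=2000)
        assert np.mean(picks == 1.0) > 0.99

    def test_equal_fitness_is_uniform(self):
        ps = 4
        pop = np.arange(ps, dtype=float).reshape(-1, 1)
        picks = select_roulette(pop, np.zeros(ps), np.random.default_rng(1),
                                n_select=10_000)
        freq = np.array([(picks == k).mean() for k in range(ps)])
        se = np.sqrt(0.25 * 0.75 / 10_000)
        np.testing.assert_array_less(np.abs(freq - 0.25), 3 * se)

    def test_returns_only_population_members(self):
        pop = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        picks = select_roulette(pop, np.array([1.0, 2.0, 3.0]), np.random.default_rng(2))
        for row in picks:
            assert any(np.array_equal(row, m) for m in pop)

    def test_all_infinite_rejected(self):
        with pytest.raises(InvalidInputError):
            select_roulette(np.ones((2, 1)), np.array([np.inf, np.inf]),
                            np.random.default_rng(0))


class TestCrossover:
    def test_identical_parents_identical_child(self):
        p = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(crossover_scattered(p, p, np.random.default_rng(0)), p)

    def test_genes_come_from_a_parent(self):
        a, b = np.zeros(6), np.ones(6)
        child = crossover_scattered(a, b, np.random.default_rng(1))
        assert set(child).issubset({0.0, 1.0})

    def test_inheritance_is_a_fair_coin(self):
        a, b = np.zeros(4), np.ones(4)
        rng = np.random.default_rng(2)
        freq = np.mean([crossover_scattered(a, b, rng) for _ in range(10_000)], axis=0)
        se = 0.5 / np.sqrt(10_000)
        np.testing.assert_array_less(np.abs(freq - 0.5), 3 * se)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            crossover_scattered(np.ones(2), np.ones(3), np.random.default_rng(0))


class TestMutate:
    def test_zero_rate_is_identity(self):
        cfg = _cfg(mutation_rate=0.0)
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(mutate(x, cfg, np.random.default_rng(0)), x)

    def test_rate_one_matches_fresh_uniform(self):
        cfg = GAConfig(lb=(2.0,), ub=(5.0,), pop_size=4, n_generations=1, mutation_rate=1.0)
        rng = np.random.default_rng(3)
        draws = np.array([mutate(np.array([3.0]), cfg, rng)[0] for _ in range(10_000)])
        ks = stats.kstest(draws, stats.uniform(2.0, 3.0).cdf)
        assert ks.pvalue > 0.01

    def test_always_within_bounds(self):
        cfg = _cfg(mutation_rate=0.5)
        rng = np.random.default_rng(4)
        for _ in range(200):
            out = mutate(np.array([0.1, 5.0, 10.0]), cfg, rng)
            assert np.all(out >= 0.1) and np.all(out <= 10.0)


class TestMinimize:
    def test_quadratic_objective_convergence(self):
        # separable quadratic, optimum at known interior point
        target = np.array([2.0, 5.0, 0.6, 8.0])
        lb, ub = target / 10, target * 10

        def objective(x):
            return float(np.sum(((x - target) / target) ** 2))

        cfg = GAConfig(lb=tuple(lb), ub=tuple(ub), pop_size=100, n_generations=200, seed=0)
        res = minimize_ga(objective, cfg)
        np.testing.assert_allclose(res.best_params, target,
                                   rtol=0.01 * (ub / target - lb / target).max())
        # within 1% of the optimum location on every coordinate (span-relative)
        assert np.all(np.abs(res.best_params - target) <= 0.01 * (ub - lb))

    def test_history_monotone_and_final(self):
        def objective(x):
            return float(np.sum(x))

        res = minimize_ga(objective, _cfg(pop_size=12, n_generations=40, seed=1))
        assert np.all(np.diff(res.fitness_history) <= 0)
        assert res.best_fitness == res.fitness_history[-1]

    def test_result_invariant_enforced(self):
        with pytest.raises(InvalidInputError):
            GAResult(best_params=np.ones(2), best_fitness=1.0,
                     fitness_history=np.array([1.0, 2.0]), config=_cfg())


class TestFitness:
    def test_noiseless_data_scores_zero(self, p1_lc, lc_conditions):
        t = np.linspace(0, 240, 9)
        states = simulate("model1", p1_lc, lc_conditions, t_eval=t).states
        ds = TimeSeriesDataset(times=t, observations=states, noise_sd=1.0)
        assert fitness(p1_lc.to_array(), ds, "model1", lc_conditions) == pytest.approx(0.0, abs=1e-4)

    def test_nonnegative_and_penalises_failures(self, p1_lc, lc_conditions):
        ds = generate_dataset("model1", p1_lc, lc_conditions, n_points=5, seed=0)
        assert fitness(p1_lc.to_array(), ds, "model1", lc_conditions) >= 0.0
        diverging = np.array([1e12, 1e12, 1e-9, 1e-9, 0.9, 1e-9, 1e-12, 1e-12, 1e-12, 1e-12])
        val = fitness(diverging, ds, "model1", lc_conditions)
        assert val == np.inf or val >= 0.0


class TestRunGa:
    def test_smoke_minimal_budget(self, p1_lc, lc_conditions):
        ds = generate_dataset("model1", p1_lc, lc_conditions, n_points=5, seed=0)
        cfg = GAConfig(lb=tuple(p1_lc.to_array() / 2), ub=tuple(np.maximum(p1_lc.to_array() * 2, p1_lc.to_array() / 2 * 1.01)),
                       pop_size=4, n_generations=1, seed=0)
        res = run_ga("model1", ds, lc_conditions, cfg)
        assert np.isfinite(res.best_fitness)

    def test_reproducible(self, p1_lc, lc_conditions):
        ds = generate_dataset("model1", p1_lc, lc_conditions, n_points=5, seed=0)
        cfg = GAConfig(lb=tuple(p1_lc.to_array() / 2), ub=tuple(p1_lc.to_array() * 2),
                       pop_size=6, n_generations=3, seed=5)
        a = run_ga("model1", ds, lc_conditions, cfg)
        b = run_ga("model1", ds, lc_conditions, cfg)
        np.testing.assert_array_equal(a.best_params, b.best_params)
        np.testing.assert_array_equal(a.fitness_history, b.fitness_history)


class TestDefaultBounds:
    def test_tmax_capped_at_one(self, p1_hc):
        lb, ub = default_bounds("model1", p1_hc.to_array(), factor=5.0)
        j = MODEL1_PARAM_NAMES.index("Tmax")
        assert ub[j] == 1.0
        assert lb[j] < ub[j]
        # other parameters keep the plain factor box
        assert ub[0] == pytest.approx(5.0 * p1_hc.Kcat1)

    def test_model2_unconstrained(self, p2_ref):
        lb, ub = default_bounds("model2", p2_ref.to_array(), factor=10.0)
        np.testing.assert_allclose(ub, p2_ref.to_array() * 10.0)
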