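"""Real-coded genetic algorithm for kinetic-parameter estimation.

Minimises the sum over the four state variables of the relative RMSE between
data and model prediction, over a box-bounded parameter space.  Operators
follow the classic real-coded recipe: roulette-wheel parent selection
(minimisation transform: selection weight proportional to the deviation
below the worst member), scattered (uniform-mask) crossover, per-gene
uniform-resampling mutation, and elitism so the best-so-far fitness is
monotone non-increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .datasets import TimeSeriesDataset
from .kinetics import InvalidInputError, ReactorConditions, param_names
from .simulate import sample_states

__all__ = [
    "GAConfig", "GAResult", "fitness", "init_population", "select_roulette",
    "crossover_scattered", "mutate", "run_ga", "minimize_ga", "default_bounds",
    "write_ga_result",
]

#: tie-break/floor weight in the roulette transform
_ROULETTE_DELTA = 1e-12


@dataclass(frozen=True)
class GAConfig:
    """Search-space bounds and operator rates.

    ``lb``/``ub`` are per-parameter positive bounds; ``pop_size`` and
    ``n_generations`` set the budget; ``crossover_rate`` is the fraction of
    offspring produced by scattered crossover (the rest are parent clones);
    ``mutation_rate`` the per-gene uniform-resampling probability;
    ``elitism_count`` members copied unchanged each generation.
    """

    lb: tuple[float, ...]
    ub: tuple[float, ...]
    pop_size: int = 100
    n_generations: int = 10_000
    crossover_rate: float = 0.90
    mutation_rate: float = 0.10
    elitism_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lb, ub = self.lb_array, self.ub_array
        if lb.shape != ub.shape or lb.ndim != 1:
            raise InvalidInputError("lb and ub must be vectors of equal length")
        if np.any(lb <= 0) or np.any(lb >= ub):
            raise InvalidInputError("bounds must satisfy 0 < lb < ub componentwise")
        if self.pop_size < 4:
            raise InvalidInputError("pop_size must be >= 4")
        if self.n_generations < 1:
            raise InvalidInputError("n_generations must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise InvalidInputError(f"{name} must lie in [0, 1]")
        if not (0 <= self.elitism_count < self.pop_size):
            raise InvalidInputError("elitism_count must lie in [0, pop_size)")

    @property
    def lb_array(self) -> np.ndarray:
        return np.asarray(self.lb, float)

    @property
    def ub_array(self) -> np.ndarray:
        return np.asarray(self.ub, float)

    @classmethod
    def around(cls, center, factor: float = 10.0, **kwargs) -> "GAConfig":
        """Bounds [center/factor, center*factor] about a reference vector."""
        c = np.asarray(center, float)
        return cls(lb=tuple(c / factor), ub=tuple(c * factor), **kwargs)


@dataclass(frozen=True)
class GAResult:
    """Best individual found plus the best-fitness-per-generation history."""

    best_params: np.ndarray
    best_fitness: float
    fitness_history: np.ndarray
    config: GAConfig
    model_id: str | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.fitness_history, float)
        if h.size and np.any(np.diff(h) > 0):
            raise InvalidInputError("fitness_history must be non-increasing (elitism)")
        if h.size and h[-1] != self.best_fitness:
            raise InvalidInputError("best_fitness must equal the final history entry")


#: hard physical upper limits on individual parameters: Tmax is the fraction
#: of the acyl-enzyme–nucleus complex converted to product, so it cannot
#: exceed 1 regardless of how wide the search box is drawn
PARAM_UPPER_CAPS = {"model1": {"Tmax": 1.0}}


def default_bounds(model_id: str, center, factor: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Search box [center/factor, center*factor] clipped to physical limits."""
    center = np.asarray(center, float)
    lb, ub = center / factor, center * factor
    caps = PARAM_UPPER_CAPS.get(model_id, {})
    names = param_names(model_id)
    for pname, cap in caps.items():
        j = names.index(pname)
        ub[j] = min(ub[j], cap)
        lb[j] = min(lb[j], ub[j] / 2)   # keep lb < ub after capping
    return lb, ub


def fitness(
    p: np.ndarray,
    dataset: TimeSeriesDataset,
    model_id: str,
    conditions: ReactorConditions,
) -> float:
    """Sum over the four species of relative RMSE (as a fraction, not %).

    Each variable's RMSE is normalised by the mean of its observed values;
    an integration failure is penalised with +inf.
    """
    sim = sample_states(model_id, np.asarray(p, float), conditions, dataset.times)
    if sim is None:
        return math.inf
    total = 0.0
    obs = dataset.observations
    for v in range(4):
        col = obs[:, v]
        mask = ~np.isnan(col)
        if not mask.any():
            continue
        mean = float(np.mean(col[mask]))
        if mean == 0.0:
            raise InvalidInputError(f"observed mean of variable {v} is zero; rRMSE undefined")
        rmse = math.sqrt(float(np.mean((col[mask] - sim[mask, v]) ** 2)))
        total += rmse / abs(mean)
    return total


def init_population(config: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Population of shape (pop_size, d), each gene uniform on [lb_j, ub_j]."""
    return rng.uniform(config.lb_array, config.ub_array,
                       size=(config.pop_size, config.lb_array.size))


def select_roulette(
    population: np.ndarray,
    fitnesses: np.ndarray,
    rng: np.random.Generator,
    n_select: int | None = None,
) -> np.ndarray:
    """Fitness-proportional parent selection under minimisation.

    Selection weight of member i is (f_worst - f_i) + delta, where f_worst is
    the worst finite fitness: the further below the worst a member sits, the
    likelier its selection; delta keeps an all-equal population uniform.
    Non-finite members get weight delta only.
    """
    fitnesses = np.asarray(fitnesses, float)
    finite = np.isfinite(fitnesses)
    if not finite.any():
        raise InvalidInputError("all fitnesses are non-finite; cannot select")
    f_worst = float(fitnesses[finite].max())
    weights = np.where(finite, f_worst - fitnesses, 0.0) + _ROULETTE_DELTA
    prob = weights / weights.sum()
    n = population.shape[0] if n_select is None else n_select
    idx = rng.choice(population.shape[0], size=n, p=prob)
    return population[idx]


def crossover_scattered(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Offspring with each gene drawn from parent a or b by a fair coin mask."""
    parent_a = np.asarray(parent_a, float)
    parent_b = np.asarray(parent_b, float)
    if parent_a.shape != parent_b.shape:
        raise InvalidInputError("parents must have equal dimension")
    mask = rng.random(parent_a.size) < 0.5
    return np.where(mask, parent_a, parent_b)


def mutate(individual: np.ndarray, config: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene uniform resampling within bounds with probability mutation_rate."""
    individual = np.asarray(individual, float)
    mask = rng.random(individual.size) < config.mutation_rate
    fresh = rng.uniform(config.lb_array, config.ub_array)
    return np.where(mask, fresh, individual)


def minimize_ga(
    objective: Callable[[np.ndarray], float],
    config: GAConfig,
    model_id: str | None = None,
) -> GAResult:
    """Generic GA minimisation of an arbitrary objective over the box.

    The generational loop: evaluate, carry over ``elitism_count`` best
    members unchanged, fill the rest with roulette-selected parents combined
    by scattered crossover (a ``crossover_rate`` fraction; the rest cloned),
    then mutate the non-elite offspring.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_population(config, rng)
    fit = np.array([objective(x) for x in pop])
    best_idx = int(np.argmin(fit))
    best_x, best_f = pop[best_idx].copy(), float(fit[best_idx])
    history = np.empty(config.n_generations)

    for gen in range(config.n_generations):
        order = np.argsort(fit, kind="stable")
        elites = pop[order[: config.elitism_count]].copy()
        n_children = config.pop_size - config.elitism_count
        parents = select_roulette(pop, fit, rng, n_select=2 * n_children)
        children = np.empty((n_children, pop.shape[1]))
        for k in range(n_children):
            pa, pb = parents[2 * k], parents[2 * k + 1]
            if rng.random() < config.crossover_rate:
                child = crossover_scattered(pa, pb, rng)
            else:
                child = pa.copy()
            children[k] = mutate(child, config, rng)
        pop = np.vstack([elites, children])
        child_fit = np.array([objective(x) for x in children])
        fit = np.concatenate([fit[order[: config.elitism_count]], child_fit])
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_f:
            best_f = float(fit[gen_best])
            best_x = pop[gen_best].copy()
        history[gen] = best_f

    return GAResult(best_params=best_x, best_fitness=best_f,
                    fitness_history=history, config=config, model_id=model_id)


def run_ga(
    model_id: str,
    dataset: TimeSeriesDataset,
    conditions: ReactorConditions,
    config: GAConfig,
) -> GAResult:
    """GA fit of a kinetic model to a dataset (objective: summed rRMSE)."""
    d = len(param_names(model_id))
    if config.lb_array.size != d:
        raise InvalidInputError(f"{model_id} has {d} parameters, bounds have {config.lb_array.size}")

    def objective(p: np.ndarray) -> float:
        return fitness(p, dataset, model_id, conditions)

    return minimize_ga(objective, config, model_id=model_id)


def write_ga_result(result: GAResult, path: str | Path) -> None:
    """Export best parameters (canonical order) + history as delimited text."""
    import json

    path = Path(path)
    names = param_names(result.model_id) if result.model_id else tuple(
        f"p{i}" for i in range(result.best_params.size))
    best = pd.DataFrame([dict(zip(names, result.best_params))])
    best.to_csv(path, index=False, float_format="%.10g")
    hist_path = Path(str(path) + ".history.csv")
    pd.DataFrame({"generation": np.arange(1, result.fitness_history.size + 1),
                  "best_fitness": result.fitness_history}).to_csv(hist_path, index=False)
    cfg = {"lb": list(result.config.lb), "ub": list(result.config.ub),
           "pop_size": result.config.pop_size, "n_generations": result.config.n_generations,
           "crossover_rate": result.config.crossover_rate,
           "mutation_rate": result.config.mutation_rate,
           "elitism_count": result.config.elitism_count, "seed": result.config.seed,
           "model_id": result.model_id, "best_fitness": result.best_fitness}
    Path(str(path) + ".meta.json").write_text(json.dumps(cfg, indent=2))
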