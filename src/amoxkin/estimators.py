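"""Scikit-learn style estimators for kinetic-parameter calibration.

Both estimators regress the four-species concentration table on sample time
through a kinetic ODE model: ``fit(X, y)`` takes sample times ``X`` of shape
(n, 1) (or (n,)) in minutes and observed concentrations ``y`` of shape
(n, 4) in mM, ordered (C_AB, C_AN, C_NH, C_AOH); ``predict(X)`` returns the
model trajectory at the point estimates.  They compose with sklearn model
selection and pipelines via ``get_params``/``set_params``.

:class:`MCMCKineticRegressor` calibrates by Metropolis–Hastings sampling of
the Bayesian posterior (point estimate: posterior mean, uncertainty: 99%
credible intervals); :class:`GAKineticRegressor` by a real-coded genetic
algorithm minimising the summed relative RMSE over a box.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import TimeSeriesDataset
from .ga import GAConfig, run_ga
from .kinetics import InvalidInputError, ReactorConditions, param_names
from .mcmc import MCMCConfig, credible_interval, posterior_summary, run_mcmc, run_mcmc_tuned
from .reference import MODEL1_LITERATURE_INIT, model2_reference
from .simulate import sample_states

__all__ = ["MCMCKineticRegressor", "GAKineticRegressor"]


def _default_center(model: str) -> np.ndarray:
    ref = MODEL1_LITERATURE_INIT if model == "model1" else model2_reference()
    return np.array([ref[n] for n in param_names(model)], float)


def _validate_t_y(X, y):
    t = np.asarray(X, float)
    if t.ndim == 2:
        if t.shape[1] != 1:
            raise InvalidInputError("X must be sample times of shape (n,) or (n, 1)")
        t = t[:, 0]
    y = np.asarray(y, float)
    if y.shape != (t.size, 4):
        raise InvalidInputError(f"y must have shape (n, 4), got {y.shape}")
    if t.size and np.any(np.diff(t) <= 0):
        raise InvalidInputError("sample times must be strictly increasing")
    return t, y


class _KineticRegressorBase(BaseEstimator, RegressorMixin):
    def _dataset(self, X, y) -> TimeSeriesDataset:
        t, obs = _validate_t_y(X, y)
        return TimeSeriesDataset(times=t, observations=obs, noise_sd=self.noise_sd)

    def _conditions(self) -> ReactorConditions:
        if self.conditions is None:
            raise InvalidInputError("conditions must be set before fitting")
        return self.conditions

    def predict(self, X) -> np.ndarray:
        """Model concentrations (n, 4) at the point estimates."""
        check_is_fitted(self, "params_")
        t = np.asarray(X, float)
        if t.ndim == 2:
            t = t[:, 0]
        order = np.argsort(t, kind="stable")
        sim = sample_states(self.model, self.params_, self._conditions(), t[order])
        if sim is None:
            raise InvalidInputError("simulation failed at the fitted parameters")
        out = np.empty_like(sim)
        out[order] = sim
        return out


class MCMCKineticRegressor(_KineticRegressorBase):
    """Bayesian calibration of a kinetic model by Metropolis–Hastings.

    Parameters
    ----------
    model : "model1" or "model2"
        Rate law to calibrate.
    conditions : ReactorConditions
        Reactor charge, enzyme load and horizon the data were collected under.
    p0 : array-like or None
        Prior centre / chain start / proposal-scale anchor, in canonical
        order; defaults to the literature estimates for the model.
    n_iter, w, prior_rel_sd, noise_sd, burn_in_frac, ci_level
        Sampler settings; see :class:`~amoxkin.mcmc.MCMCConfig`.  ``noise_sd``
        is the fixed likelihood error standard deviation in mM.
    random_state : int
        Seed; identical seeds give identical chains.

    Attributes
    ----------
    params_ : ndarray of shape (d,)
        Posterior means in canonical parameter order.
    ci_ : ndarray of shape (d, 2)
        Equal-tailed credible bounds at ``ci_level``.
    chain_ : Chain
        Retained post burn-in states.
    acceptance_rate_ : float
    summary_ : FitResult

    Notes
    -----
    ``pilot_tune=True`` switches to the pilot-tuned sampler
    (:func:`~amoxkin.mcmc.run_mcmc_tuned`), recommended whenever the
    posterior couples parameters along ridges; ``fixed_params`` freezes
    named parameters at their ``p0`` value.
    """

    def __init__(self, model: str = "model1", conditions: ReactorConditions | None = None,
                 p0=None, n_iter: int = 100_000, w: float = 6e-3,
                 prior_rel_sd: float = 0.6, noise_sd: float = 1.0,
                 burn_in_frac: float = 0.2, ci_level: float = 0.99,
                 pilot_tune: bool = False, n_pilot: int = 30_000,
                 fixed_params: tuple[str, ...] = (),
                 random_state: int = 0):
        self.model = model
        self.conditions = conditions
        self.p0 = p0
        self.n_iter = n_iter
        self.w = w
        self.prior_rel_sd = prior_rel_sd
        self.noise_sd = noise_sd
        self.burn_in_frac = burn_in_frac
        self.ci_level = ci_level
        self.pilot_tune = pilot_tune
        self.n_pilot = n_pilot
        self.fixed_params = fixed_params
        self.random_state = random_state

    def fit(self, X, y):
        dataset = self._dataset(X, y)
        p0 = _default_center(self.model) if self.p0 is None else np.asarray(self.p0, float)
        mask = None
        if self.fixed_params:
            names = param_names(self.model)
            unknown = set(self.fixed_params) - set(names)
            if unknown:
                raise InvalidInputError(f"unknown fixed parameters {sorted(unknown)}")
            mask = tuple(n in self.fixed_params for n in names)
        config = MCMCConfig(
            p0=tuple(p0), n_iter=self.n_iter, w=self.w,
            prior_rel_sd=self.prior_rel_sd, noise_sd=self.noise_sd,
            burn_in_frac=self.burn_in_frac, ci_level=self.ci_level,
            seed=self.random_state, fixed_mask=mask,
        )
        if self.pilot_tune:
            self.chain_ = run_mcmc_tuned(self.model, dataset, self._conditions(),
                                         config, n_pilot=self.n_pilot)
        else:
            self.chain_ = run_mcmc(self.model, dataset, self._conditions(), config)
        self.params_ = self.chain_.samples.mean(axis=0)
        self.ci_ = credible_interval(self.chain_)
        self.acceptance_rate_ = self.chain_.acceptance_rate
        self.summary_ = posterior_summary(self.chain_)
        self.n_features_in_ = 1
        return self


class GAKineticRegressor(_KineticRegressorBase):
    """Genetic-algorithm calibration of a kinetic model.

    Minimises the sum over species of relative RMSE between data and model
    on the box ``[lb, ub]`` (defaults: literature estimates divided and
    multiplied by ``bound_factor``).

    Attributes
    ----------
    params_ : ndarray of shape (d,)
        Best individual found, canonical order.
    best_fitness_ : float
        Its summed fractional rRMSE.
    fitness_history_ : ndarray
        Best-so-far fitness per generation (non-increasing).
    """

    def __init__(self, model: str = "model1", conditions: ReactorConditions | None = None,
                 lb=None, ub=None, bound_factor: float = 10.0,
                 pop_size: int = 100, n_generations: int = 10_000,
                 crossover_rate: float = 0.90, mutation_rate: float = 0.10,
                 elitism_count: int = 2, noise_sd: float = 1.0,
                 random_state: int = 0):
        self.model = model
        self.conditions = conditions
        self.lb = lb
        self.ub = ub
        self.bound_factor = bound_factor
        self.pop_size = pop_size
        self.n_generations = n_generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.elitism_count = elitism_count
        self.noise_sd = noise_sd
        self.random_state = random_state

    def fit(self, X, y):
        dataset = self._dataset(X, y)
        if self.lb is None or self.ub is None:
            from .ga import default_bounds

            dlb, dub = default_bounds(self.model, _default_center(self.model),
                                      self.bound_factor)
            lb = dlb if self.lb is None else np.asarray(self.lb, float)
            ub = dub if self.ub is None else np.asarray(self.ub, float)
        else:
            lb, ub = np.asarray(self.lb, float), np.asarray(self.ub, float)
        config = GAConfig(
            lb=tuple(lb), ub=tuple(ub), pop_size=self.pop_size,
            n_generations=self.n_generations, crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate, elitism_count=self.elitism_count,
            seed=self.random_state,
        )
        self.result_ = run_ga(self.model, dataset, self._conditions(), config)
        self.params_ = self.result_.best_params
        self.best_fitness_ = self.result_.best_fitness
        self.fitness_history_ = self.result_.fitness_history
        self.n_features_in_ = 1
        return self
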