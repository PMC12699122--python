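"""Metropolis–Hastings sampling of kinetic-parameter posteriors.

The posterior targeted is the product of a truncated Gaussian prior and an
i.i.d. Gaussian likelihood with fixed, known error standard deviation (no
hyperparameters are estimated):

* prior: independent Gaussians centred at the initial estimate ``P0`` with
  per-component standard deviation ``prior_rel_sd * P0_j`` (relative, because
  the parameters span four orders of magnitude), truncated to the positive
  orthant;
* likelihood: observations are the simulated trajectory plus i.i.d. N(0,
  noise_sd^2) errors; an integration failure is treated as zero likelihood.

The proposal is an additive Gaussian random walk with per-component scale
``w * P0_j`` anchored to the initial estimate, hence exactly symmetric: the
Hastings correction cancels and plain Metropolis acceptance applies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .datasets import TimeSeriesDataset
from .kinetics import InvalidInputError, ReactorConditions, param_names
from .simulate import sample_states

__all__ = [
    "MCMCConfig", "Chain", "log_prior", "log_likelihood", "propose",
    "run_mcmc", "run_mcmc_tuned", "credible_interval", "posterior_summary",
    "write_chain",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``p0`` is the initial parameter vector (prior centre and proposal-scale
    anchor); ``n_iter`` the chain length; ``w`` the relative random-walk step
    (default 6e-3); ``prior_rel_sd`` the relative prior standard deviation
    (default 0.6); ``noise_sd`` the likelihood error sd in mM (``None`` means
    use the dataset's recorded value); ``burn_in_frac`` the fraction of the
    chain discarded before summarisation; ``ci_level`` the credible level.
    ``fixed_mask`` optionally freezes parameters at their ``p0`` value (they
    receive no proposal steps), for partially known models.
    """

    p0: tuple[float, ...]
    n_iter: int = 100_000
    w: float = 6e-3
    prior_rel_sd: float = 0.6
    noise_sd: float | None = None
    burn_in_frac: float = 0.2
    ci_level: float = 0.99
    seed: int = 0
    fixed_mask: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        p0 = np.asarray(self.p0, float)
        if p0.ndim != 1 or np.any(p0 <= 0) or np.any(~np.isfinite(p0)):
            raise InvalidInputError("p0 must be a vector of positive finite values")
        if self.fixed_mask is not None and len(self.fixed_mask) != p0.size:
            raise InvalidInputError("fixed_mask must have one flag per parameter")
        if self.n_iter < 1:
            raise InvalidInputError("n_iter must be >= 1")
        if not (self.w >= 0):
            raise InvalidInputError("w must be >= 0")
        if not (self.prior_rel_sd > 0):
            raise InvalidInputError("prior_rel_sd must be > 0")
        if not (0 <= self.burn_in_frac < 1):
            raise InvalidInputError("burn_in_frac must lie in [0, 1)")
        if not (0 < self.ci_level < 1):
            raise InvalidInputError("ci_level must lie in (0, 1)")

    @property
    def p0_array(self) -> np.ndarray:
        return np.asarray(self.p0, float)


@dataclass(frozen=True)
class Chain:
    """Retained (post burn-in) states of one Metropolis–Hastings run."""

    samples: np.ndarray
    acceptance_rate: float
    log_posterior_trace: np.ndarray
    config: MCMCConfig
    model_id: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.acceptance_rate <= 1.0):
            raise InvalidInputError("acceptance_rate must lie in [0, 1]")


def log_prior(p: np.ndarray, config: MCMCConfig) -> float:
    """Log-density of the positivity-truncated Gaussian prior at ``p``.

    Independent components N(P0_j, (prior_rel_sd * P0_j)^2); any non-positive
    component gives -inf.  (The truncation's normalising constant is omitted:
    it is parameter-independent and cancels in the Metropolis ratio.)
    """
    p = np.asarray(p, float)
    p0 = config.p0_array
    if p.shape != p0.shape:
        raise InvalidInputError(f"parameter dimension {p.shape} does not match p0 {p0.shape}")
    if np.any(p <= 0) or np.any(~np.isfinite(p)):
        return -math.inf
    sd = config.prior_rel_sd * p0
    z = (p - p0) / sd
    return float(-0.5 * np.dot(z, z) - np.sum(np.log(sd)) - p.size * _LOG_SQRT_2PI)


def log_likelihood(
    p: np.ndarray,
    dataset: TimeSeriesDataset,
    model_id: str,
    conditions: ReactorConditions,
    noise_sd: float | None = None,
) -> float:
    """Gaussian i.i.d. log-likelihood of the observations at parameters ``p``.

    Missing cells contribute nothing; an integration failure returns -inf
    (zero likelihood) rather than raising, so samplers simply reject.
    """
    sd = float(noise_sd if noise_sd is not None else dataset.noise_sd)
    obs = dataset.observations
    n = dataset.n_observed
    if n == 0:
        return 0.0
    sim = sample_states(model_id, np.asarray(p, float), conditions, dataset.times)
    if sim is None:
        return -math.inf
    resid = obs - sim
    ss = float(np.nansum(resid * resid))
    return -0.5 * ss / (sd * sd) - n * (math.log(sd) + _LOG_SQRT_2PI)


def propose(p_prev: np.ndarray, w: float, rng: np.random.Generator,
            p0: np.ndarray) -> np.ndarray:
    """Symmetric Gaussian random-walk candidate: p + w * P0 ⊙ z, z ~ N(0, I).

    The per-component scale is anchored to the initial estimate ``p0`` (not
    the current state), which keeps the proposal symmetric and the Metropolis
    ratio exact.  Non-positive candidates are legal outputs; the truncated
    prior rejects them.
    """
    p_prev = np.asarray(p_prev, float)
    return p_prev + w * np.asarray(p0, float) * rng.standard_normal(p_prev.size)


def _mh_loop(
    log_post: Callable[[np.ndarray], float],
    config: MCMCConfig,
    rng: np.random.Generator,
    start: np.ndarray | None = None,
    step_chol: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Plain Metropolis with a fixed symmetric Gaussian proposal.

    The proposal is diagonal with scale ``w * P0`` unless ``step_chol`` (a
    Cholesky factor of a full proposal covariance) is supplied; either way it
    is frozen for the whole loop, so the chain is exactly Markov.
    """
    p0 = config.p0_array
    n, d = config.n_iter, p0.size
    if step_chol is None:
        scale = config.w * p0
        if config.fixed_mask is not None:
            scale = np.where(np.asarray(config.fixed_mask, bool), 0.0, scale)

        def step() -> np.ndarray:
            return scale * rng.standard_normal(d)
    else:
        def step() -> np.ndarray:
            return step_chol @ rng.standard_normal(d)

    current = (p0 if start is None else np.asarray(start, float)).copy()
    lp_current = log_post(current)
    if not np.isfinite(lp_current):
        warnings.warn("log-posterior is not finite at the chain start; chain may not move sensibly")
    states = np.empty((n, d))
    trace = np.empty(n)
    accepted = 0
    for i in range(n):
        cand = current + step()
        lp_cand = log_post(cand)
        u = rng.random()
        if lp_cand == -math.inf:
            accept = False
        elif lp_current == -math.inf:
            accept = True
        else:
            accept = math.log(u) if u > 0 else -math.inf
            accept = accept < lp_cand - lp_current
        if accept:
            current, lp_current = cand, lp_cand
            accepted += 1
        states[i] = current
        trace[i] = lp_current
    return states, accepted / n, trace


def run_mcmc(
    model_id: str,
    dataset: TimeSeriesDataset,
    conditions: ReactorConditions,
    config: MCMCConfig,
) -> Chain:
    """Run Metropolis–Hastings and return the post burn-in chain.

    The number of retained states is ``floor(n_iter * (1 - burn_in_frac))``.
    Fully reproducible from ``config.seed``.  An all-rejected chain raises a
    warning, not an error.
    """
    expected_dim = len(param_names(model_id))
    if config.p0_array.size != expected_dim:
        raise InvalidInputError(
            f"{model_id} has {expected_dim} parameters, p0 has {config.p0_array.size}")
    noise_sd = config.noise_sd if config.noise_sd is not None else dataset.noise_sd

    def log_post(p: np.ndarray) -> float:
        lp = log_prior(p, config)
        if lp == -math.inf:
            return lp
        return lp + log_likelihood(p, dataset, model_id, conditions, noise_sd)

    rng = np.random.default_rng(config.seed)
    states, acc_rate, trace = _mh_loop(log_post, config, rng)
    if acc_rate == 0.0 and config.n_iter > 1:
        warnings.warn("Metropolis–Hastings accepted no moves; check w and the posterior")
    n_keep = int(math.floor(config.n_iter * (1.0 - config.burn_in_frac)))
    return Chain(
        samples=states[config.n_iter - n_keep:],
        acceptance_rate=acc_rate,
        log_posterior_trace=trace,
        config=config,
        model_id=model_id,
    )


def run_mcmc_tuned(
    model_id: str,
    dataset: TimeSeriesDataset,
    conditions: ReactorConditions,
    config: MCMCConfig,
    n_pilot: int = 30_000,
    n_stages: int = 2,
    pilot_w: float = 0.02,
) -> Chain:
    """Pilot-tuned Metropolis–Hastings for strongly correlated posteriors.

    The P0-anchored diagonal walk mixes poorly when the posterior couples
    parameters along narrow ridges (e.g. a catalytic constant against its
    Michaelis constant).  This runs ``n_stages`` pilot chains — the first
    with the diagonal walk at relative step ``pilot_w``, each subsequent one
    with a Gaussian proposal whose covariance is the previous pilot's sample
    covariance scaled by the standard 2.38^2/d factor — then a final chain
    of ``config.n_iter`` states with the last (frozen) proposal covariance.
    Every stage is a plain fixed-proposal Metropolis chain, so the final
    chain targets the exact posterior; no within-chain adaptation occurs.
    """
    expected_dim = len(param_names(model_id))
    if config.p0_array.size != expected_dim:
        raise InvalidInputError(
            f"{model_id} has {expected_dim} parameters, p0 has {config.p0_array.size}")
    noise_sd = config.noise_sd if config.noise_sd is not None else dataset.noise_sd

    def log_post(p: np.ndarray) -> float:
        lp = log_prior(p, config)
        if lp == -math.inf:
            return lp
        return lp + log_likelihood(p, dataset, model_id, conditions, noise_sd)

    d = expected_dim
    free = np.ones(d, bool)
    if config.fixed_mask is not None:
        free = ~np.asarray(config.fixed_mask, bool)
    rngs = [np.random.default_rng(s) for s in
            np.random.SeedSequence(config.seed).spawn(n_stages + 1)]

    from dataclasses import replace

    pilot_cfg = replace(config, n_iter=n_pilot, w=pilot_w)
    start = config.p0_array
    step_chol = None
    for stage in range(n_stages):
        states, _, _ = _mh_loop(log_post, pilot_cfg, rngs[stage], start=start,
                                step_chol=step_chol)
        kept = states[n_pilot // 5:]
        cov = np.cov(kept[:, free].T) * (2.38 ** 2 / max(int(free.sum()), 1))
        cov += 1e-15 * np.eye(int(free.sum()))   # guard a rank-deficient pilot
        chol_free = np.linalg.cholesky(cov)
        step_chol = np.zeros((d, d))
        step_chol[np.ix_(free, free)] = chol_free
        start = states[-1]

    final_cfg = replace(config)
    states, acc_rate, trace = _mh_loop(log_post, final_cfg, rngs[-1],
                                       start=start, step_chol=step_chol)
    if acc_rate == 0.0 and config.n_iter > 1:
        warnings.warn("final tuned chain accepted no moves; check the pilot stages")
    n_keep = int(math.floor(config.n_iter * (1.0 - config.burn_in_frac)))
    return Chain(
        samples=states[config.n_iter - n_keep:],
        acceptance_rate=acc_rate,
        log_posterior_trace=trace,
        config=config,
        model_id=model_id,
    )


def credible_interval(chain: Chain, level: float | None = None) -> np.ndarray:
    """Per-parameter equal-tailed credible bounds, shape (d, 2).

    Bounds are the empirical quantiles at (1-level)/2 and 1-(1-level)/2 of
    the retained states; a constant chain yields a zero-width interval.
    """
    level = chain.config.ci_level if level is None else float(level)
    if not (0 < level < 1):
        raise InvalidInputError("credible level must lie strictly in (0, 1)")
    if chain.samples.size == 0:
        raise InvalidInputError("empty chain")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(chain.samples, alpha, axis=0)
    hi = np.quantile(chain.samples, 1.0 - alpha, axis=0)
    return np.column_stack([lo, hi])


def posterior_summary(chain: Chain):
    """Posterior means, credible intervals and acceptance rate as a FitResult."""
    from .selection import FitResult  # deferred: selection composes on top of fits

    if chain.samples.size == 0:
        raise InvalidInputError("empty chain")
    means = chain.samples.mean(axis=0)
    ci = credible_interval(chain)
    names = param_names(chain.model_id) if chain.model_id else tuple(
        f"p{i}" for i in range(means.size))
    return FitResult(
        model_id=chain.model_id or "unknown",
        method="MCMC",
        condition=None,
        estimates=dict(zip(names, map(float, means))),
        ci={n: (float(l), float(h)) for n, (l, h) in zip(names, ci)},
        diagnostics={"acceptance_rate": chain.acceptance_rate,
                     "n_retained": int(chain.samples.shape[0])},
    )


def write_chain(chain: Chain, path: str | Path) -> None:
    """Export retained states as delimited text (canonical parameter order
    plus log-posterior), with the sampler config in a JSON sidecar."""
    import json

    path = Path(path)
    names = param_names(chain.model_id) if chain.model_id else tuple(
        f"p{i}" for i in range(chain.samples.shape[1]))
    n_kept = chain.samples.shape[0]
    df = pd.DataFrame(chain.samples, columns=list(names))
    df["log_posterior"] = chain.log_posterior_trace[-n_kept:]
    df.to_csv(path, index=False, float_format="%.10g")
    cfg = {
        "p0": list(chain.config.p0), "n_iter": chain.config.n_iter,
        "w": chain.config.w, "prior_rel_sd": chain.config.prior_rel_sd,
        "noise_sd": chain.config.noise_sd, "burn_in_frac": chain.config.burn_in_frac,
        "ci_level": chain.config.ci_level, "seed": chain.config.seed,
        "acceptance_rate": chain.acceptance_rate, "model_id": chain.model_id,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(cfg, indent=2))
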