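"""Transfer of batch-calibrated parameters to semi-batch prediction.

Parameters estimated on batch data are applied, without re-fitting, to
predict fed-batch operation in which ester and 6-APA are added during the
run.  Solid substrate addition is modelled as a volumetric molar feed at
constant working volume (instantaneous dissolution, no volume dynamics).
Posterior predictive uncertainty is propagated by simulating a thinned
subsample of the chain and taking pointwise quantile envelopes.
"""

from __future__ import annotations

import numpy as np

from .datasets import TimeSeriesDataset
from .kinetics import FeedSchedule, InvalidInputError, ReactorConditions
from .mcmc import Chain
from .selection import FitResult
from .simulate import Trajectory, simulate

__all__ = ["MOLAR_MASS_G_PER_MOL", "predict_semibatch", "predictive_band",
           "to_mass_units", "default_semibatch_conditions"]

#: molar masses (g/mol) of the four species, from their molecular formulas:
#: ester = p-hydroxyphenylglycine methyl ester C9H11NO3, amoxicillin
#: C16H19N3O5S, 6-APA C8H12N2O3S, POHPG C8H9NO3
MOLAR_MASS_G_PER_MOL = {
    "C_AB": 181.19,
    "C_AN": 365.40,
    "C_NH": 216.26,
    "C_AOH": 167.16,
}


def default_semibatch_conditions(model_id: str = "model1") -> ReactorConditions:
    """Default fed-batch validation scenario.

    Low-concentration charge and enzyme load, constant 0.2 mM/min feed of
    both substrates over the first 120 min, then no feed, 400 min horizon.
    A package default (the reference fed-batch schedule is not published).
    """
    from .datasets import DEFAULT_CEZ
    from .kinetics import scenario_state

    return ReactorConditions(
        cez=DEFAULT_CEZ[model_id],
        initial_state=scenario_state("LC"),
        t_end=400.0,
        mode="semi-batch",
        feed=FeedSchedule.pulse(0.2, 0.2, 120.0),
        cez_unit="iu_per_ml" if model_id == "model1" else "mM",
    )


def predict_semibatch(
    model_id: str,
    batch_fit: FitResult,
    conditions: ReactorConditions,
    t_eval=None,
) -> Trajectory:
    """Forward-simulate a semi-batch run at batch-estimated parameters."""
    if conditions.mode != "semi-batch":
        raise InvalidInputError("conditions.mode must be 'semi-batch'")
    if batch_fit.model_id != model_id:
        raise InvalidInputError(
            f"batch fit is for {batch_fit.model_id!r}, requested {model_id!r}")
    return simulate(model_id, batch_fit.theta, conditions, t_eval=t_eval)


def predictive_band(
    model_id: str,
    chain: Chain,
    conditions: ReactorConditions,
    t_eval,
    level: float = 0.99,
    max_draws: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise posterior predictive envelope of the concentration curves.

    Simulates the model at an evenly thinned subsample of at most
    ``max_draws`` retained chain states and returns the per-time, per-species
    empirical quantile bounds (lower, upper), each shaped (n_times, 4).
    """
    if chain.samples.size == 0:
        raise InvalidInputError("empty chain")
    if not (0 < level < 1):
        raise InvalidInputError("level must lie in (0, 1)")
    t_eval = np.asarray(t_eval, float)
    n = chain.samples.shape[0]
    idx = np.unique(np.linspace(0, n - 1, min(max_draws, n)).astype(int))
    curves = np.empty((idx.size, t_eval.size, 4))
    for k, i in enumerate(idx):
        traj = simulate(model_id, chain.samples[i], conditions, t_eval=t_eval,
                        check_unit=False)
        curves[k] = traj.states
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(curves, alpha, axis=0)
    upper = np.quantile(curves, 1.0 - alpha, axis=0)
    return lower, upper


def to_mass_units(obj):
    """Convert a Trajectory or TimeSeriesDataset from mM to g/L.

    Multiplies each species by its molar mass over 1000; round-trips with
    the inverse conversion to within 1e-9.
    """
    factors = np.array([MOLAR_MASS_G_PER_MOL[s] for s in
                        ("C_AB", "C_AN", "C_NH", "C_AOH")]) / 1000.0
    if isinstance(obj, Trajectory):
        if obj.unit != "mM":
            raise InvalidInputError(f"expected unit 'mM', got {obj.unit!r}")
        return Trajectory(times=obj.times, states=obj.states * factors,
                          model_id=obj.model_id, conditions=obj.conditions,
                          unit="g_per_L", _segments=obj._segments)
    if isinstance(obj, TimeSeriesDataset):
        prov = dict(obj.provenance)
        prov["unit"] = "g_per_L"
        return TimeSeriesDataset(times=obj.times,
                                 observations=obj.observations * factors,
                                 noise_sd=obj.noise_sd, provenance=prov)
    raise InvalidInputError(f"cannot convert object of type {type(obj).__name__}")


def from_mass_units(obj):
    """Inverse of :func:`to_mass_units` (g/L back to mM)."""
    factors = np.array([MOLAR_MASS_G_PER_MOL[s] for s in
                        ("C_AB", "C_AN", "C_NH", "C_AOH")]) / 1000.0
    if isinstance(obj, Trajectory):
        if obj.unit != "g_per_L":
            raise InvalidInputError(f"expected unit 'g_per_L', got {obj.unit!r}")
        return Trajectory(times=obj.times, states=obj.states / factors,
                          model_id=obj.model_id, conditions=obj.conditions,
                          unit="mM", _segments=obj._segments)
    raise InvalidInputError(f"cannot convert object of type {type(obj).__name__}")
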