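"""Model selection by relative RMSE across models, methods and charges.

The selection metric is the per-variable relative root-mean-square error,

    rRMSE = 100 * sqrt( sum_i (Ym_i - Ye_i)^2 / n ) / mean(Ym)   [%]

computed separately for each of the four species and summed for ranking.
The full study design crosses two models (semi-empirical / mechanism-based),
two estimation methods (MCMC / GA) and two charge conditions (LC / HC),
giving an eight-cell interaction grid; within each condition the winner is
the cell with the smallest summed rRMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .datasets import TimeSeriesDataset
from .kinetics import InvalidInputError, ReactorConditions, param_names

__all__ = ["FitResult", "rrmse", "evaluate_fit", "interaction_grid", "InteractionGrid"]

_VARIABLES = ("C_AB", "C_AN", "C_NH", "C_AOH")


@dataclass
class FitResult:
    """One calibrated model: estimates, optional uncertainty, optional fit error.

    ``estimates`` maps canonical parameter names to point estimates; ``ci``
    optionally carries per-parameter (low, high) credible bounds;
    ``rrmse_per_variable`` (percent, one entry per species) and ``rrmse_sum``
    are filled by :func:`evaluate_fit`.
    """

    model_id: str
    method: str
    estimates: dict[str, float]
    condition: str | None = None
    ci: dict[str, tuple[float, float]] | None = None
    rrmse_per_variable: dict[str, float] | None = None
    rrmse_sum: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.estimates[n] for n in param_names(self.model_id)])


def rrmse(measured, estimated) -> float:
    """Relative RMSE between two equal-length sequences, in percent.

    RMSE normalised by the mean of the measured values: invariant under a
    common positive rescaling, zero iff the sequences coincide.
    """
    ym = np.asarray(measured, float)
    ye = np.asarray(estimated, float)
    if ym.shape != ye.shape or ym.ndim != 1 or ym.size == 0:
        raise InvalidInputError("measured and estimated must be equal-length nonempty vectors")
    mean = float(np.mean(ym))
    if mean == 0.0:
        raise InvalidInputError("mean of the measured sequence is zero; rRMSE undefined")
    return 100.0 * math.sqrt(float(np.mean((ym - ye) ** 2))) / abs(mean)


def evaluate_fit(
    dataset: TimeSeriesDataset,
    model_id: str,
    params,
    conditions: ReactorConditions,
) -> tuple[dict[str, float], float]:
    """Per-variable rRMSE (percent) of a parameter set against a dataset."""
    from .simulate import sample_states

    theta = params.to_array() if hasattr(params, "to_array") else np.asarray(params, float)
    sim = sample_states(model_id, theta, conditions, dataset.times)
    if sim is None:
        raise InvalidInputError("simulation failed at the supplied parameters")
    per_var: dict[str, float] = {}
    for v, name in enumerate(_VARIABLES):
        col = dataset.observations[:, v]
        mask = ~np.isnan(col)
        if not mask.any():
            raise InvalidInputError(f"dataset has no observations of {name}")
        per_var[name] = rrmse(col[mask], sim[mask, v])
    return per_var, float(sum(per_var.values()))


@dataclass
class InteractionGrid:
    """All eight (model, method, condition) fits plus per-condition winners."""

    results: list[FitResult]
    winners: dict[str, FitResult]

    def to_frame(self) -> pd.DataFrame:
        """Per-variable rRMSE table: rows species, columns model/method/condition."""
        cols = {}
        for r in self.results:
            key = f"{r.model_id}_{r.method}_{r.condition}"
            if r.rrmse_per_variable is None:
                cols[key] = {v: float("nan") for v in _VARIABLES}
            else:
                cols[key] = r.rrmse_per_variable
        return pd.DataFrame(cols).reindex(list(_VARIABLES))


def interaction_grid(
    datasets: dict[str, TimeSeriesDataset],
    conditions: dict[str, dict[str, ReactorConditions]],
    mcmc_configs: dict[str, "object"],
    ga_configs: dict[str, "object"],
) -> InteractionGrid:
    """Fit every model x method x condition cell and rank by summed rRMSE.

    ``datasets`` maps condition name ("LC"/"HC") to data; ``conditions`` maps
    condition name then model id to reactor conditions (the enzyme-load unit
    differs between models); ``mcmc_configs`` / ``ga_configs`` map model id
    to an :class:`~amoxkin.mcmc.MCMCConfig` / :class:`~amoxkin.ga.GAConfig`.
    A failed fit is recorded as a cell with no rRMSE; the grid is still
    returned.  Deterministic given the configs' seeds.
    """
    from .ga import run_ga
    from .mcmc import posterior_summary, run_mcmc

    if set(datasets) != {"LC", "HC"}:
        raise InvalidInputError("datasets must cover exactly the conditions 'LC' and 'HC'")

    results: list[FitResult] = []
    for condition in ("LC", "HC"):
        ds = datasets[condition]
        for model_id in ("model1", "model2"):
            cond = conditions[condition][model_id]
            for method in ("MCMC", "GA"):
                try:
                    if method == "MCMC":
                        chain = run_mcmc(model_id, ds, cond, mcmc_configs[model_id])
                        fr = posterior_summary(chain)
                    else:
                        ga_res = run_ga(model_id, ds, cond, ga_configs[model_id])
                        names = param_names(model_id)
                        fr = FitResult(model_id=model_id, method="GA",
                                       estimates=dict(zip(names, map(float, ga_res.best_params))),
                                       diagnostics={"best_fitness": ga_res.best_fitness})
                    fr.condition = condition
                    per_var, total = evaluate_fit(ds, model_id, fr.theta, cond)
                    fr.rrmse_per_variable, fr.rrmse_sum = per_var, total
                except Exception as exc:  # failed cell: keep the grid complete
                    fr = FitResult(model_id=model_id, method=method, estimates={},
                                   condition=condition, diagnostics={"error": str(exc)})
                results.append(fr)

    winners = {}
    for condition in ("LC", "HC"):
        scored = [r for r in results if r.condition == condition and r.rrmse_sum is not None]
        if scored:
            winners[condition] = min(scored, key=lambda r: r.rrmse_sum)
    return InteractionGrid(results=results, winners=winners)
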