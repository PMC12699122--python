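# amoxkin

Kinetic modelling and calibration of enzymatic amoxicillin synthesis in
batch and semi-batch (fed-batch) reactors.

## The problem

Amoxicillin can be synthesised enzymatically by penicillin G acylase
(PGA, EC 3.5.1.11) from *p*-hydroxyphenylglycine methyl ester (the activated
acyl donor, "ester") and 6-aminopenicillanic acid (6-APA, the β-lactam
nucleus). Under kinetic control the acyl-enzyme intermediate partitions
between nucleophilic attack by adsorbed 6-APA (product) and attack by water
(by-product *p*-hydroxyphenylglycine, POHPG); the product itself is also
hydrolysed. Yield therefore peaks transiently, and reactor design needs a
calibrated dynamic model. `amoxkin` is aimed at biochemical engineers who
want to fit such models to concentration time series and transfer them
across operating modes.

Four species are tracked (mM): ester C_AB, amoxicillin C_AN, 6-APA C_NH,
by-product C_AOH. Two rate laws are implemented:

**Model 1** (semi-empirical, 10 parameters) — Michaelis–Menten kinetics with
competitive inhibition:

```
v_AB = Kcat1·C_AB·C_EZ / (KM1·(1 + C_AN/kAN + C_AOH/kAOH) + C_AB)
v_S  = v_AB·Tmax·C_NH / (KEN + C_NH)
v_AN = Kcat2·C_AN·C_EZ / (KM2·(1 + C_AB/kAB + C_NH/kNH + C_AOH/kAOH) + C_AN)

dC_AB/dt = −v_AB          dC_AN/dt = v_S − v_AN
dC_NH/dt = v_AN − v_S     dC_AOH/dt = v_AB − v_S + v_AN
```

**Model 2** (mechanism-based, 8 parameters) — elementary rate and
equilibrium constants of the acyl-enzyme cycle (k2, k3, k4, k−4, k5, KN,
KS, KP), with amoxicillin production rate

```
R_P = C_EZ·[k2·k4·C_AB·C_NH/KS − k−4·C_AN·(k3·KN + k5·C_NH)/KP]
      / (k3·KN + k4·C_NH + k5·C_NH)
```

Both laws conserve the acyl moiety (C_AB + C_AN + C_AOH) and the nucleus
moiety (C_AN + C_NH) exactly; in semi-batch operation those sums grow
exactly by the integrated ester/6-APA feed.

Calibration is by either of two estimators, exposed as scikit-learn style
regressors of concentration on time:

* `MCMCKineticRegressor` — Metropolis–Hastings sampling of the Bayesian
  posterior (truncated Gaussian prior centred on an initial estimate with
  relative sd 0.6; Gaussian likelihood with fixed error sd). Reports
  posterior means and 99% credible intervals.
* `GAKineticRegressor` — a real-coded genetic algorithm (roulette selection,
  scattered crossover, uniform-resampling mutation, elitism) minimising the
  summed relative RMSE over a bounded box.

Model/method/condition combinations are ranked by per-species relative RMSE
(`amoxkin.selection`), and batch-calibrated parameters transfer to fed-batch
prediction with posterior predictive bands (`amoxkin.semibatch`).

## Worked example

Generate a synthetic low-concentration batch dataset (80 mM ester, 60 mM
6-APA, 13 samples over 240 min, 1 mM measurement noise) from published
Model 1 estimates and re-estimate the parameters:

```python
import numpy as np
from amoxkin import MCMCKineticRegressor, generate_dataset, scenario
from amoxkin.kinetics import MODEL1_PARAM_NAMES, params_from_dict
from amoxkin.reference import MODEL1_LC_MCMC_MEAN

truth = params_from_dict("model1", MODEL1_LC_MCMC_MEAN)
cond = scenario("LC")                      # 80 mM ester, 60 mM 6-APA, 240 min
data = generate_dataset("model1", truth, cond, n_points=13, noise_sd=1.0, seed=1)

est = MCMCKineticRegressor(
    model="model1", conditions=cond, p0=truth.to_array(),
    n_iter=12_000, pilot_tune=True, n_pilot=4_000, noise_sd=1.0, random_state=1,
)
est.fit(data.times.reshape(-1, 1), data.observations)

print(f"acceptance rate: {est.acceptance_rate_:.2f}")
for name, mean, (lo, hi) in zip(MODEL1_PARAM_NAMES, est.params_, est.ci_):
    print(f"{name:>5s}: {mean:7.3f}  99% CI [{lo:7.3f}, {hi:7.3f}]")
```

which prints

```
acceptance rate: 0.10
Kcat1:   0.191  99% CI [  0.162,   0.221]
Kcat2:   0.390  99% CI [  0.113,   0.651]
  KM1:   6.679  99% CI [  2.802,  11.703]
  KM2:   1.866  99% CI [  0.340,   3.774]
 Tmax:   0.811  99% CI [  0.685,   1.000]
  KEN:   8.763  99% CI [  0.272,  19.217]
  kAB:   0.785  99% CI [  0.212,   1.570]
  kAN:   2.315  99% CI [  0.781,   4.401]
 kAOH:  10.654  99% CI [  2.997,  20.735]
  kNH:  10.117  99% CI [  1.352,  24.829]
```

The generating values (Kcat1 = 0.181 µmol/(i.u.·min), KM1 = 5.45 mM,
Tmax = 0.82, …) lie inside every interval: the catalytic constants are
recovered tightly, while the inhibition constants are only weakly
identified from a single 13-point experiment — visible in their wide
credible intervals.

The same workflow is scriptable from the shell (`amoxkin simulate`,
`generate`, `fit-mcmc`, `fit-ga`, `grid`, `validate`, `convert-units`),
driven by a single YAML config per run; every stochastic stage requires an
explicit `--seed` and writes a provenance sidecar.

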