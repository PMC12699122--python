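# Methods

## Reaction network and models

Penicillin G acylase catalyses three coupled conversions of four species
(all concentrations in mM): synthesis of amoxicillin (C_AN) from the
activated ester (C_AB) and 6-APA (C_NH), hydrolysis of the ester, and
hydrolysis of the product, both hydrolyses yielding POHPG (C_AOH). Both
rate laws assume an ideally mixed, isothermal batch reactor, a constant
concentration of immobilised enzyme (no deactivation), and no mass-transfer
limitation in the support gel.

**Model 1** (semi-empirical, 10 parameters, vector order `Kcat1, Kcat2,
KM1, KM2, Tmax, KEN, kAB, kAN, kAOH, kNH`) is Michaelis–Menten kinetics
with competitive inhibition terms in both denominators. `Tmax` is the
maximum fraction of the acyl-enzyme–nucleus complex converted to product
and is therefore constrained to (0, 1]; `KEN` is the 6-APA adsorption
constant. The ester consumption rate v_AB and hydrolysis rate v_AN are
nonnegative for any nonnegative state, so ester is monotone non-increasing
and by-product monotone non-decreasing in batch.

**Model 2** (mechanism-based, 8 parameters, order `k2, k3, k4, km4, k5,
KN, KS, KP`) is built from elementary constants of the acyl-enzyme cycle.
The printed source equations are typographically garbled (missing fraction
bars); the grouping implemented here is the unique arrangement that is
dimensionally consistent (all rates in mM/min with first-order constants in
1/min and equilibrium constants in mM) and satisfies both conservation
identities exactly. Its synthesis rate R_P can be negative only when
product is present (reverse reaction).

Structural identifiability of Model 2 is limited: the parameters enter the
rate laws only through k2/KS, km4/KP, k3·KN, k4 and k5, so at most five
combinations are estimable from concentration data. Calibration studies
therefore hold the five constants without published estimates (k2, km4,
k5, KN, KS) fixed at documented nominal values and sample k3, k4, KP.

**Enzyme-load units.** Model 1 catalytic constants are per activity unit
of immobilised enzyme, so its enzyme load C_EZ is in i.u./mL; Model 2 rate
constants are first order in a molar enzyme concentration (mM).
`ReactorConditions` carries a unit tag and mixing the two is a checked
error. Defaults (2.5 i.u./mL and 1.0 mM) are package choices giving ≥50%
ester conversion within the 240-min default horizon, so that synthetic
experiments are informative.

**Semi-batch operation** adds right-continuous stepwise molar feed rates
F_AB(t), F_NH(t) (mM/min) to the two substrate balances, modelling solid
substrate addition as instantaneous dissolution at constant working volume
(no volume dynamics). The moiety sums then satisfy
d(C_AB+C_AN+C_AOH)/dt = F_AB and d(C_AN+C_NH)/dt = F_NH exactly, which the
tests use as a balance oracle via quadrature of the feed.

## Numerical integration

`simulate` uses LSODA (stiff-capable) with rtol 1e-8 / atol 1e-10 and
retains dense output per integration segment; feed breakpoints are passed
as segment boundaries so discontinuous feeds never straddle an internal
step. `trajectory_at` interpolates with the solver's dense output and is
exact at grid nodes. Inside the right-hand sides, states are clipped at
zero so integrator overshoot cannot generate spurious negative rates.
The estimation hot path (`sample_states`) integrates with ODEPACK's LSODA
at rtol 1e-6 / atol 1e-8 — the induced trajectory error (~1e-4 mM) is far
below any realistic measurement noise — and signals integrator failure by
returning nothing, which the samplers translate into zero likelihood or an
infinite cost rather than an exception. Correctness is checked against an
independent fixed-step RK4 oracle (agreement < 0.01 mM on the
low-concentration scenario) and by tolerance-refinement (endpoint shift
< 1e-4 mM under 10× tighter tolerances).

## Synthetic data

The reference experimental datasets are not deposited, so all estimation
studies run on synthetic data. The generator observes a noiseless model
trajectory at n equispaced times (default 13 on [0, 240] min, emulating
typical sampling density for this reaction) and adds i.i.d. Gaussian noise
per species and time, default sd 1.0 mM — the likelihood's error sd is
treated as known and fixed, and 1.0 mM is a package default since no value
is published. Noise is deliberately not truncated at zero (slightly
negative readings are legal), keeping the Gaussian likelihood unbiased near
zero concentration. Two charge conditions are predefined: LC (80 mM ester,
60 mM 6-APA) and HC (120 mM ester, 30 mM 6-APA), both with zero initial
product and by-product.

What passing recovery tests on these data do *not* show: robustness to
heteroscedastic or multiplicative assay error, to model misspecification
(enzyme deactivation, crystallisation, volume change on feeding), or to
irregular sampling — none of which the generator emulates.

## Bayesian calibration (Metropolis–Hastings)

Posterior ∝ prior × likelihood with no hyperparameter estimation. The
prior is independent Gaussians centred at the initial estimate P0 with
per-component sd `prior_rel_sd · P0_j` (default 0.6 — *relative*, because
the parameters span four orders of magnitude), truncated to the positive
orthant. Because the truncation point sits at −1/0.6 ≈ −1.67 prior sds,
the truncated prior's mean is 6.3% above P0 and its sd is 0.90× the
nominal value; the sampler-validation test therefore compares against exact
truncated-normal moments rather than the untruncated ones. The likelihood
is i.i.d. Gaussian with fixed sd (defaulting to the dataset's recorded
noise sd); missing cells contribute nothing; an integration failure is
treated as zero likelihood.

The default proposal is an additive Gaussian random walk with
per-component scale `w · P0_j` (default w = 6e-3), anchored to P0 rather
than the current state so the proposal is exactly symmetric and plain
Metropolis acceptance applies. Burn-in defaults to 20% of the chain;
the retained count is floor(N·(1−burn_in)). Credible intervals are
equal-tailed empirical quantiles (default 99%).

**Pilot-tuned sampling.** The diagonal P0-anchored walk mixes very slowly
on these posteriors: the data constrain ratios such as Kcat2/KM2, creating
narrow curved ridges, and the per-component posterior scales differ by an
order of magnitude. Measured autocorrelation times reach ~4×10⁴
iterations, so desk-scale chains cannot estimate posterior means reliably.
`run_mcmc_tuned` therefore runs one short pilot chain with the diagonal
walk, then re-estimates a full proposal covariance from the pilot samples
(scaled by the standard 2.38²/d factor), optionally repeats, and finally
runs the production chain with that covariance *frozen*. Every stage is a
plain fixed-proposal Metropolis chain — there is no within-chain
adaptation, so the final chain targets the exact posterior. The tuned
sampler's posterior means were cross-validated against an independent
affine-invariant ensemble sampler during development and agree to well
within Monte-Carlo error; the test suite checks it against the
truncated-prior oracle.

`fixed_mask` freezes selected components at their P0 value (no proposal
step); their prior contribution is a constant and cancels in the ratio.

## Genetic algorithm

Real-coded GA minimising the sum over species of fractional relative RMSE
(see below), on a box [lb, ub]. Defaults follow common practice for this
problem class: population 100, crossover rate 0.90, mutation rate 0.10,
roulette selection, scattered (uniform-mask) crossover, per-gene uniform
resampling mutation, elitism 2 (guaranteeing a monotone best-so-far
fitness), 10⁴ generations by default with a few hundred sufficing at desk
scale. Because the objective is a deviation to *minimise*, roulette weights
are `(f_worst − f) + δ` with δ = 1e-12 — proportional-to-fitness semantics
under minimisation, with δ breaking the all-equal tie uniformly. Crossover
is applied to a `crossover_rate` fraction of offspring, the rest cloned
from a parent; all individuals ever evaluated lie in the box by
construction. Default bounds are [ref/10, ref·10] around literature
estimates, *intersected with physical limits*: Tmax is a conversion
fraction, so its upper bound is clipped at 1.0 (`PARAM_UPPER_CAPS`).
Without this clip the GA can wander along the nearly flat Tmax–KEN ridge —
the data constrain mainly Tmax/(KEN + C_NH) — and return unphysical
Tmax > 1 at equal fitness.

## Model selection

The metric is the per-species relative RMSE, 100·RMSE/mean(measured), in
percent; each species is normalised by its own observed mean (not a pooled
mean), and combinations are ranked by the four-species sum. The full
study design crosses two models × two estimators × two charges into an
eight-cell interaction grid; within each charge the winner is the cell with
the smallest summed rRMSE. A failed fit is recorded as an empty cell and
the grid is still returned. The metric is scale-invariant and zero iff
the sequences coincide; the GA objective is the same quantity as a
fraction (divided by 100).

## Semi-batch validation

Batch-calibrated parameters are applied without re-fitting to fed-batch
prediction. The default validation scenario — LC charge and enzyme load,
constant 0.2 mM/min feed of both substrates for 120 min then zero, 400-min
horizon — is a package choice; the reference fed-batch schedule is not
published. Posterior predictive uncertainty is propagated by simulating an
evenly thinned subsample (default 500 states) of the retained chain and
taking pointwise empirical quantile envelopes per species. Mass-unit
reporting multiplies by molar masses from the molecular formulas: ester
(POHPG methyl ester, C9H11NO3) 181.19, amoxicillin (C16H19N3O5S) 365.40,
6-APA (C8H12N2O3S) 216.26, POHPG (C8H9NO3) 167.16 g/mol.

## Design choices at genuinely open points

* The source text is ambiguous about whether its proposal noise is uniform
  or Gaussian; the symmetric Gaussian walk is adopted (exact Metropolis
  ratio, no Hastings correction).
* `Tmax` is treated as dimensionless (its unit annotation in the source
  nomenclature is inconsistent with its definition as a fraction).
* Burn-in length is unspecified in the source; 20% is the default and the
  tests verify summaries are insensitive to deeper discards.
* The GA fitness functional is unspecified; the summed rRMSE is used for
  consistency with the selection metric.

## Problem sizes

Desk-scale studies use 13-point datasets, tuned MCMC chains of 2×10⁴–6×10⁴
production iterations after 3×10⁴-iteration pilots, and GA budgets of 100
individuals × 300 generations; these sizes were chosen so the recovery
studies and property suites complete in minutes on a single CPU while
keeping Monte-Carlo errors well below the decision margins they feed.

## Known limitations

* Model 2's full parameter vector is not identifiable from concentration
  data alone (five estimable combinations of eight parameters).
* Under the default synthetic design (13 points, 1 mM noise) the posterior
  for the inhibition constants is wide; single-experiment recoveries of
  those parameters are prior-dominated.
* No enzyme deactivation, pH/temperature dependence, crystallisation, or
  volume dynamics; predictions outside the calibrated operating envelope
  inherit these omissions.
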