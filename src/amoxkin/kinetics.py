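"""Reaction-network kinetics of PGA-catalysed amoxicillin synthesis.

The kinetically controlled synthesis of amoxicillin couples three routes on
one enzyme (penicillin G acylase): acylation of 6-APA by the activated ester
(synthesis), hydrolysis of the ester, and hydrolysis of the product.  Four
species are tracked, all in mM:

    C_AB   p-hydroxyphenylglycine methyl ester (acyl donor)
    C_AN   amoxicillin (product)
    C_NH   6-aminopenicillanic acid (beta-lactam nucleus, nucleophile)
    C_AOH  p-hydroxyphenylglycine (hydrolysis by-product)

Two rate laws are implemented:

* **Model 1** — semi-empirical Michaelis–Menten kinetics with competitive
  inhibition by products and by-products, 10 parameters.
* **Model 2** — mechanism-based kinetics built from elementary rate and
  equilibrium constants of the acyl-enzyme cycle, 8 parameters.

Both conserve the two reaction moieties exactly: the acyl moiety
(C_AB + C_AN + C_AOH) and the nucleus moiety (C_AN + C_NH) have zero time
derivative in batch mode, and in semi-batch mode their derivatives equal the
respective molar feed rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

__all__ = [
    "MODEL1_PARAM_NAMES",
    "MODEL2_PARAM_NAMES",
    "SPECIES",
    "ParamsModel1",
    "ParamsModel2",
    "FeedSchedule",
    "ReactorConditions",
    "scenario_state",
    "params_from_dict",
    "params_to_dict",
    "rates_model1",
    "rhs_model1_batch",
    "rhs_model2_batch",
    "rhs_semibatch",
    "rhs_array",
]

#: canonical parameter ordering of the two parameter vectors
MODEL1_PARAM_NAMES = ("Kcat1", "Kcat2", "KM1", "KM2", "Tmax", "KEN", "kAB", "kAN", "kAOH", "kNH")
MODEL2_PARAM_NAMES = ("k2", "k3", "k4", "km4", "k5", "KN", "KS", "KP")

#: canonical state ordering
SPECIES = ("C_AB", "C_AN", "C_NH", "C_AOH")

#: enzyme-load unit tags accepted per model (activity-based vs molar kinetics)
CEZ_UNITS = {"model1": "iu_per_ml", "model2": "mM"}


class InvalidInputError(ValueError):
    """A state or parameter value violates a model precondition."""


class ModelEvaluationError(ValueError):
    """A rate law could not be evaluated (degenerate denominator, non-finite)."""


def _check_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise InvalidInputError(f"parameter {name!r} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class ParamsModel1:
    """Parameters of the semi-empirical (Michaelis–Menten) model.

    Kcat1/Kcat2 are catalytic constants for ester consumption and amoxicillin
    hydrolysis (umol per i.u. per min); KM1/KM2 the matching Michaelis
    constants (mM); Tmax the maximum fraction of the acyl-enzyme–nucleus
    complex converted to product (dimensionless, in (0, 1]); KEN the 6-APA
    adsorption constant (mM); kAB/kAN/kAOH/kNH the competitive inhibition
    constants of ester, product, by-product and nucleus (mM).
    """

    Kcat1: float
    Kcat2: float
    KM1: float
    KM2: float
    Tmax: float
    KEN: float
    kAB: float
    kAN: float
    kAOH: float
    kNH: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_positive(f.name, getattr(self, f.name))
        if self.Tmax > 1:
            raise InvalidInputError(f"Tmax must lie in (0, 1], got {self.Tmax}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MODEL1_PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "ParamsModel1":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (10,):
            raise InvalidInputError(f"Model 1 expects 10 parameters, got shape {theta.shape}")
        return cls(**dict(zip(MODEL1_PARAM_NAMES, theta)))


@dataclass(frozen=True)
class ParamsModel2:
    """Parameters of the mechanism-based model.

    k2 (acyl-enzyme formation), k3 (ester hydrolysis), k4 (synthesis),
    km4 (reverse synthesis, i.e. k_-4) and k5 (by-product via the product
    route) are first-order rate constants (1/min); KN, KS and KP are the
    nucleophile association, enzyme–substrate and product equilibrium
    constants (mM).
    """

    k2: float
    k3: float
    k4: float
    km4: float
    k5: float
    KN: float
    KS: float
    KP: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_positive(f.name, getattr(self, f.name))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MODEL2_PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "ParamsModel2":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (8,):
            raise InvalidInputError(f"Model 2 expects 8 parameters, got shape {theta.shape}")
        return cls(**dict(zip(MODEL2_PARAM_NAMES, theta)))


def param_names(model_id: str) -> tuple[str, ...]:
    """Canonical parameter names for ``"model1"`` or ``"model2"``."""
    if model_id == "model1":
        return MODEL1_PARAM_NAMES
    if model_id == "model2":
        return MODEL2_PARAM_NAMES
    raise InvalidInputError(f"unknown model id {model_id!r}")


def params_to_dict(p: "ParamsModel1 | ParamsModel2") -> dict[str, float]:
    """Flatten a parameter container to a plain ``{name: value}`` mapping."""
    names = MODEL1_PARAM_NAMES if isinstance(p, ParamsModel1) else MODEL2_PARAM_NAMES
    return {n: float(getattr(p, n)) for n in names}


def params_from_dict(model_id: str, d: dict[str, float]) -> "ParamsModel1 | ParamsModel2":
    """Build a typed parameter container from a flat mapping (extra keys rejected)."""
    names = param_names(model_id)
    missing = set(names) - set(d)
    extra = set(d) - set(names)
    if missing or extra:
        raise InvalidInputError(f"bad parameter keys for {model_id}: missing={sorted(missing)}, extra={sorted(extra)}")
    cls = ParamsModel1 if model_id == "model1" else ParamsModel2
    return cls(**{n: float(d[n]) for n in names})


@dataclass(frozen=True)
class FeedSchedule:
    """Right-continuous stepwise molar feed rates for ester and 6-APA.

    ``times`` are the breakpoints (min, first entry 0); ``fab`` / ``fnh``
    give the feed rate (mM/min) that applies on ``[times[i], times[i+1])``,
    the last value extending to the horizon.  Solid substrate addition is
    modelled as a volumetric molar feed at constant working volume.
    """

    times: tuple[float, ...]
    fab: tuple[float, ...]
    fnh: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if t.ndim != 1 or t.size == 0 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise InvalidInputError("feed breakpoints must start at 0 and increase strictly")
        for name in ("fab", "fnh"):
            v = np.asarray(getattr(self, name), float)
            if v.shape != t.shape:
                raise InvalidInputError(f"{name} must have one rate per breakpoint")
            if np.any(~np.isfinite(v)) or np.any(v < 0):
                raise InvalidInputError(f"{name} rates must be finite and >= 0")

    @classmethod
    def constant(cls, fab: float, fnh: float) -> "FeedSchedule":
        return cls(times=(0.0,), fab=(float(fab),), fnh=(float(fnh),))

    @classmethod
    def pulse(cls, fab: float, fnh: float, t_off: float) -> "FeedSchedule":
        """Constant feed on [0, t_off), zero afterwards."""
        return cls(times=(0.0, float(t_off)), fab=(float(fab), 0.0), fnh=(float(fnh), 0.0))

    def _index(self, t: float) -> int:
        return int(np.searchsorted(self.times, t, side="right")) - 1

    def fab_at(self, t: float) -> float:
        return self.fab[self._index(t)]

    def fnh_at(self, t: float) -> float:
        return self.fnh[self._index(t)]

    def breakpoints(self, t_end: float) -> np.ndarray:
        b = [t for t in self.times if 0 < t < t_end]
        return np.asarray(b, float)

    def integral(self, t: float) -> tuple[float, float]:
        """Cumulative fed amount (mM) of ester and 6-APA up to time t."""
        edges = np.append(np.asarray(self.times, float), np.inf)
        widths = np.clip(np.minimum(edges[1:], t) - edges[:-1], 0, None)
        return float(np.dot(widths, self.fab)), float(np.dot(widths, self.fnh))


@dataclass(frozen=True)
class ReactorConditions:
    """Operating conditions of the (ideally mixed, isothermal) reactor.

    ``cez`` is the enzyme load; its unit differs between the models because
    Model 1 catalytic constants are per activity unit of immobilised enzyme
    (so cez is in i.u./mL) while Model 2 rate constants are first order in a
    molar enzyme concentration (cez in mM).  ``cez_unit`` carries the tag and
    mixing the two is a checked error at simulation time.
    """

    cez: float
    initial_state: tuple[float, float, float, float]
    t_end: float = 240.0
    mode: str = "batch"
    feed: FeedSchedule | None = None
    cez_unit: str = "iu_per_ml"

    def __post_init__(self) -> None:
        if not math.isfinite(self.cez) or self.cez < 0:
            raise InvalidInputError(f"cez must be finite and >= 0, got {self.cez}")
        if self.t_end <= 0:
            raise InvalidInputError("t_end must be > 0")
        y0 = np.asarray(self.initial_state, float)
        if y0.shape != (4,) or np.any(~np.isfinite(y0)) or np.any(y0 < 0):
            raise InvalidInputError("initial_state must be four finite nonnegative concentrations")
        if self.mode not in ("batch", "semi-batch"):
            raise InvalidInputError(f"mode must be 'batch' or 'semi-batch', got {self.mode!r}")
        if (self.mode == "semi-batch") != (self.feed is not None):
            raise InvalidInputError("feed must be present iff mode is 'semi-batch'")
        if self.cez_unit not in ("iu_per_ml", "mM"):
            raise InvalidInputError(f"unknown cez_unit {self.cez_unit!r}")

    def check_unit(self, model_id: str) -> None:
        if model_id not in CEZ_UNITS:
            raise InvalidInputError(f"unknown model id {model_id!r}")
        expected = CEZ_UNITS[model_id]
        if self.cez_unit != expected:
            raise InvalidInputError(
                f"{model_id} expects enzyme load in {expected!r}, conditions carry {self.cez_unit!r}"
            )


#: initial charges (mM) of the two experimental conditions: low concentration
#: (80 mM ester, 60 mM 6-APA) and high concentration (120 mM ester, 30 mM 6-APA)
SCENARIO_CHARGES = {
    "LC": (80.0, 0.0, 60.0, 0.0),
    "HC": (120.0, 0.0, 30.0, 0.0),
}


def scenario_state(name: str) -> tuple[float, float, float, float]:
    """Initial state (C_AB, C_AN, C_NH, C_AOH) of the named charge condition."""
    try:
        return SCENARIO_CHARGES[name]
    except KeyError:
        raise InvalidInputError(f"unknown scenario {name!r}; known: {sorted(SCENARIO_CHARGES)}") from None


# ---------------------------------------------------------------------------
# rate laws (array core + typed wrappers)
# ---------------------------------------------------------------------------

def _validate_state(state: Sequence[float]) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.shape != (4,):
        raise InvalidInputError(f"state must have 4 components, got shape {y.shape}")
    for name, v in zip(SPECIES, y):
        if not math.isfinite(v):
            raise InvalidInputError(f"state component {name} is not finite: {v!r}")
        if v < 0:
            raise InvalidInputError(f"state component {name} is negative: {v!r}")
    return y


def _rates1(y: np.ndarray, th: np.ndarray, cez: float) -> tuple[float, float, float]:
    # states clipped at 0 so integrator overshoot cannot yield spurious rates
    cab, can, cnh, caoh = np.clip(y, 0.0, None)
    kcat1, kcat2, km1, km2, tmax, ken, kab, kan, kaoh, knh = th
    v_ab = kcat1 * cab * cez / (km1 * (1.0 + can / kan + caoh / kaoh) + cab)
    v_s = v_ab * tmax * cnh / (ken + cnh)
    v_an = kcat2 * can * cez / (km2 * (1.0 + cab / kab + cnh / knh + caoh / kaoh) + can)
    return v_ab, v_s, v_an


def _rhs1(y: np.ndarray, th: np.ndarray, cez: float) -> np.ndarray:
    v_ab, v_s, v_an = _rates1(y, th, cez)
    return np.array([-v_ab, v_s - v_an, v_an - v_s, v_ab - v_s + v_an])


def _rhs2(y: np.ndarray, th: np.ndarray, cez: float) -> np.ndarray:
    cab, can, cnh, caoh = np.clip(y, 0.0, None)
    k2, k3, k4, km4, k5, kn, ks, kp = th
    hyd = k3 * kn + k5 * cnh            # hydrolytic partition of the acyl-enzyme
    den = hyd + k4 * cnh
    if not (den > 0) or not math.isfinite(den):
        raise ModelEvaluationError(f"degenerate rate denominator {den!r} in Model 2")
    r_p = cez * (k2 * k4 * cab * cnh / ks - km4 * can * hyd / kp) / den
    r_b = cez * hyd * (k2 * cab / ks - km4 * can / kp) / den
    return np.array([-(r_p + r_b), r_p, -r_p, r_b])


def rhs_array(model_id: str, y: np.ndarray, theta: np.ndarray, cez: float) -> np.ndarray:
    """Batch right-hand side on raw arrays (no validation); the hot path."""
    if model_id == "model1":
        return _rhs1(y, theta, cez)
    if model_id == "model2":
        return _rhs2(y, theta, cez)
    raise InvalidInputError(f"unknown model id {model_id!r}")


def rates_model1(state: Sequence[float], p: ParamsModel1, cez: float) -> tuple[float, float, float]:
    """The three Model 1 reaction rates (v_AB, v_S, v_AN) in mM/min.

    v_AB is the ester consumption rate, v_S the synthesis rate (nucleophilic
    attack of adsorbed 6-APA on the acyl-enzyme) and v_AN the amoxicillin
    hydrolysis rate.  All are nonnegative for a nonnegative state.
    """
    y = _validate_state(state)
    if not math.isfinite(cez) or cez < 0:
        raise InvalidInputError(f"cez must be finite and >= 0, got {cez!r}")
    return _rates1(y, p.to_array(), cez)


def rhs_model1_batch(state: Sequence[float], p: ParamsModel1, cez: float) -> np.ndarray:
    """Batch derivative (dC_AB, dC_AN, dC_NH, dC_AOH)/dt for Model 1."""
    v_ab, v_s, v_an = rates_model1(state, p, cez)
    return np.array([-v_ab, v_s - v_an, v_an - v_s, v_ab - v_s + v_an])


def rhs_model2_batch(state: Sequence[float], p: ParamsModel2, cez: float) -> np.ndarray:
    """Batch derivative for Model 2; amoxicillin production rate may be
    negative (reverse synthesis) only when product is present."""
    y = _validate_state(state)
    if not math.isfinite(cez) or cez < 0:
        raise InvalidInputError(f"cez must be finite and >= 0, got {cez!r}")
    return _rhs2(y, p.to_array(), cez)


def rhs_semibatch(
    model_id: str,
    state: Sequence[float],
    p: "ParamsModel1 | ParamsModel2",
    cez: float,
    feed: FeedSchedule,
    t: float,
) -> np.ndarray:
    """Semi-batch derivative: the batch law plus ester / 6-APA feed terms.

    The feed enters only the two substrate balances, so the moiety sums obey
    d(C_AB + C_AN + C_AOH)/dt = F_AB(t) and d(C_AN + C_NH)/dt = F_NH(t).
    """
    if model_id == "model1":
        dy = rhs_model1_batch(state, p, cez)
    elif model_id == "model2":
        dy = rhs_model2_batch(state, p, cez)
    else:
        raise InvalidInputError(f"unknown model id {model_id!r}")
    dy = dy.copy()
    dy[0] += feed.fab_at(t)
    dy[2] += feed.fnh_at(t)
    return dy
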