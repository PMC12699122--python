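"""Literature parameter estimates for PGA-catalysed amoxicillin synthesis.

These are published point estimates and 99% credible intervals for the two
kinetic models, used as prior centres, genetic-algorithm bound anchors and
ground truth for synthetic parameter-recovery studies.  Units follow the
parameter containers in :mod:`amoxkin.kinetics`: catalytic constants in
umol/(i.u. min), rate constants in 1/min, all K's in mM, Tmax dimensionless.
"""

from __future__ import annotations

__all__ = [
    "MODEL1_LITERATURE_INIT",
    "MODEL1_LC_MCMC_MEAN",
    "MODEL1_LC_MCMC_CI99",
    "MODEL1_HC_GA",
    "MODEL2_HC_MCMC_MEAN",
    "MODEL2_HC_MCMC_CI99",
    "MODEL2_NOMINAL",
]

#: deterministic literature estimates used as initial guesses / prior centres
#: for Model 1 (ester and 6-APA batch synthesis, immobilised PGA)
MODEL1_LITERATURE_INIT = {
    "Kcat1": 0.18,
    "Kcat2": 0.33,
    "KM1": 7.91,
    "KM2": 12.5,
    "Tmax": 0.61,
    "KEN": 14.4,
    "kAB": 3.78,
    "kAN": 9.17,
    "kAOH": 10.9,
    "kNH": 62.04,
}

#: posterior means, Model 1, low-concentration charge, Metropolis–Hastings
MODEL1_LC_MCMC_MEAN = {
    "Kcat1": 0.181,
    "Kcat2": 0.39,
    "KM1": 5.45,
    "KM2": 1.69,
    "Tmax": 0.82,
    "KEN": 7.94,
    "kAB": 0.68,
    "kAN": 1.98,
    "kAOH": 9.85,
    "kNH": 9.76,
}

#: matching 99% credible intervals (low, high)
MODEL1_LC_MCMC_CI99 = {
    "Kcat1": (0.153, 0.234),
    "Kcat2": (0.279, 0.656),
    "KM1": (4.113, 6.939),
    "KM2": (1.43, 2.05),
    "Tmax": (0.71, 0.96),
    "KEN": (5.65, 10.41),
    "kAB": (0.43, 1.07),
    "kAN": (1.17, 3.28),
    "kAOH": (6.28, 13.26),
    "kNH": (6.69, 14.47),
}

#: genetic-algorithm point estimates, Model 1, high-concentration charge
MODEL1_HC_GA = {
    "Kcat1": 1.159,
    "Kcat2": 1.785,
    "KM1": 43.48,
    "KM2": 49.22,
    "Tmax": 0.98,
    "KEN": 32.48,
    "kAB": 645.03,
    "kAN": 815.80,
    "kAOH": 21.21,
    "kNH": 273.67,
}

#: Model 2 posterior means published for the high-concentration charge
#: (only these three parameters are reported)
MODEL2_HC_MCMC_MEAN = {"k3": 0.95, "k4": 0.06, "KP": 0.23}

#: matching 99% credible intervals
MODEL2_HC_MCMC_CI99 = {"k3": (0.61, 1.65), "k4": (0.05, 0.08), "KP": (0.19, 0.30)}

#: nominal values for the Model 2 parameters without published estimates,
#: chosen at magnitudes typical for acyl-enzyme cycle kinetics; combined with
#: the published k3, k4, KP they define the reference Model 2 parameter set
MODEL2_NOMINAL = {"k2": 1.0, "km4": 0.05, "k5": 0.5, "KN": 10.0, "KS": 5.0}


def model2_reference() -> dict[str, float]:
    """Full 8-parameter Model 2 reference set (published + nominal values)."""
    out = dict(MODEL2_NOMINAL)
    out.update(MODEL2_HC_MCMC_MEAN)
    return {k: out[k] for k in ("k2", "k3", "k4", "km4", "k5", "KN", "KS", "KP")}
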