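import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amoxkin.datasets import scenario
from amoxkin.kinetics import ParamsModel1, ParamsModel2, params_from_dict
from amoxkin.reference import MODEL1_LC_MCMC_MEAN, MODEL1_HC_GA, model2_reference

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def p1_lc() -> ParamsModel1:
    """Model 1 parameters at the published low-concentration posterior means."""
    return params_from_dict("model1", MODEL1_LC_MCMC_MEAN)


@pytest.fixture(scope="session")
def p1_hc() -> ParamsModel1:
    """Model 1 parameters at the published high-concentration GA estimates."""
    return params_from_dict("model1", MODEL1_HC_GA)


@pytest.fixture(scope="session")
def p2_ref() -> ParamsModel2:
    """Model 2 reference parameter set (published + nominal values)."""
    return params_from_dict("model2", model2_reference())


@pytest.fixture(scope="session")
def lc_conditions():
    return scenario("LC")


@pytest.fixture(scope="session")
def hc_conditions():
    return scenario("HC")


@pytest.fixture(scope="session")
def hc_conditions_m2():
    return scenario("HC", model_id="model2")
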