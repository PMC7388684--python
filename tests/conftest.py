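import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fructolyse.diet import scenario_diets
from fructolyse.parameters import load_parameters
from fructolyse.simulator import run_to_baseline

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def diets():
    return scenario_diets()


@pytest.fixture(scope="session")
def mixed_diet(diets):
    return diets["mixed-100g"]


@pytest.fixture(scope="session")
def baseline_state(params, mixed_diet):
    """Converged 08:00 state after the mixed-diet run-in (shared, heavy)."""
    return run_to_baseline(params, mixed_diet)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
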