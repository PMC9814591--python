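import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from aspsim import ToyModelSpec, toy_integrals  # noqa: E402


@pytest.fixture(scope="session")
def toy_dissociation():
    return toy_integrals(ToyModelSpec.dissociation())


@pytest.fixture(scope="session")
def toy_equilibrium():
    return toy_integrals(ToyModelSpec.equilibrium())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
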