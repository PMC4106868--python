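import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from branchrd.params import GridSpec, ModelParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """The calibrated default parameter set."""
    return ModelParams()


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(nx=16, ny=12)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
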