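import numpy as np
import pytest
from hypothesis import settings

from bolustrack.synthetic import (
    CinePhantomConfig,
    PhantomConfig,
    generate_cine_study,
    generate_first_pass_phantom,
)

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_config() -> PhantomConfig:
    """Default study conditions, no noise, no cardiac modulation."""
    return PhantomConfig(noise_sd=0.0, modulation_depth=0.0)


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    """Default study conditions (noiseless, with cardiac modulation)."""
    return PhantomConfig()


@pytest.fixture(scope="session")
def default_phantom(default_config):
    return generate_first_pass_phantom(default_config)


@pytest.fixture(scope="session")
def cine_study():
    return generate_cine_study(CinePhantomConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
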