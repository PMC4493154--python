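import numpy as np
import pytest
from hypothesis import settings

from twoscale import ModelParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def spot_params() -> ModelParams:
    """Parameter set producing hexagonal hollow-spot patterns (type A)."""
    return ModelParams(
        D0=1e-4, a=1.0, b=4.3e-4, c=3.9e-4, R_s=0.05, R_l=0.1, L=1.0, N=10_000
    )


@pytest.fixture(scope="session")
def labyrinth_params(spot_params) -> ModelParams:
    """Parameter set producing labyrinth patterns (type B)."""
    return spot_params.replace(b=8.5e-4, c=7.0e-4)


@pytest.fixture(scope="session")
def homogeneous_params(spot_params) -> ModelParams:
    """Parameter set where the uniform state is linearly stable."""
    return spot_params.replace(b=3.5e-4, c=7.0e-4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
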