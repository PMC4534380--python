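import numpy as np
import pytest

from battm import (
    BattmConfig,
    HopfieldParams,
    StimulusSpec,
    find_neutral_state,
    find_stable_fixed_points,
)


@pytest.fixture(scope="session")
def params() -> HopfieldParams:
    return HopfieldParams()


@pytest.fixture(scope="session")
def cfg() -> BattmConfig:
    return BattmConfig()


@pytest.fixture(scope="session")
def phi(params) -> np.ndarray:
    return find_stable_fixed_points(params)


@pytest.fixture(scope="session")
def mu0(params) -> np.ndarray:
    return find_neutral_state(params)


@pytest.fixture(scope="session")
def switch_spec() -> StimulusSpec:
    return StimulusSpec(noise_level=4.0, schedule=((0, 800.0), (1, 800.0)))
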