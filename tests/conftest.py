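import numpy as np
import pytest

from ideorice.crop_model import (
    DEFAULT_COEFFICIENTS,
    OPTIMIZED_COEFFICIENTS,
    EnvironmentScenario,
)
from ideorice.sensitivity import default_space
from ideorice.synthetic_data import (
    NORTH_CLIMATE,
    SOIL_TYPE_1,
    SOIL_TYPE_2,
    SOUTH_CLIMATE,
    generate_environment_set,
    generate_weather,
)


@pytest.fixture(scope="session")
def space11():
    return default_space()


@pytest.fixture(scope="session")
def space8():
    return default_space(OPTIMIZED_COEFFICIENTS)


@pytest.fixture(scope="session")
def base_coeffs():
    return DEFAULT_COEFFICIENTS


@pytest.fixture(scope="session")
def wet_env():
    return EnvironmentScenario(
        soil=SOIL_TYPE_1.profile,
        weather=generate_weather(SOUTH_CLIMATE, 170, seed=7),
        label="wet",
    )


@pytest.fixture(scope="session")
def dry_env():
    return EnvironmentScenario(
        soil=SOIL_TYPE_2.profile,
        weather=generate_weather(NORTH_CLIMATE, 170, seed=7),
        label="dry",
    )


@pytest.fixture(scope="session")
def environment_set():
    return generate_environment_set(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
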