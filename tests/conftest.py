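import numpy as np
import pytest

from rapeyield import (
    TrialDesign,
    build_endmember_matrix,
    generate_endmember_library,
    generate_trial,
    uav6,
)


@pytest.fixture(scope="session")
def sensor():
    return uav6()


@pytest.fixture(scope="session")
def library():
    return generate_endmember_library(seed=1)


@pytest.fixture(scope="session")
def endmember_matrix(library, sensor):
    return build_endmember_matrix(library, sensor)


@pytest.fixture(scope="session")
def bundle():
    """Default 24-plot nitrogen-gradient trial, seed 1."""
    return generate_trial(TrialDesign(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
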