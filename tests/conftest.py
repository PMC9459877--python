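import numpy as np
import pytest

from clothgait.config import PipelineConfig
from clothgait.simulate import GaitParams, ImuNoise, generate_session

#: Compact protocol used by most pipeline-level tests: long enough for the
#: calibration preconditions (standing >= 2 s after edge trims, dynamic
#: segments >= 5 s), short enough to keep the suite fast.
SHORT_PROTOCOL = [
    ("standing", 20.0),
    ("sitting", 6.0),
    ("sit_to_stand", 15.0),
    ("leg_raise", 15.0),
    ("walking", None),
]


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_session():
    """A 20-cycle six-sensor session with default noise, plus ground truth."""
    return generate_session(
        protocol=SHORT_PROTOCOL, gait=GaitParams(n_cycles=20), seed=7
    )


@pytest.fixture(scope="session")
def noise_free_session():
    return generate_session(
        protocol=SHORT_PROTOCOL,
        gait=GaitParams(n_cycles=20),
        noise=ImuNoise(0.0, 0.0, 0.0),
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
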