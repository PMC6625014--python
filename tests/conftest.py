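import numpy as np
import pytest

from wbam.body_model import load_anthropometry
from wbam.synthetic_gait import (
    AnthropometricProfile,
    CircuitSpec,
    GaitStyle,
    TaskSegment,
    default_circuit,
    generate_trial,
)


@pytest.fixture(scope="session")
def table():
    return load_anthropometry()


@pytest.fixture(scope="session")
def short_trial():
    """~4 s level walk, enough frames for every pipeline stage."""
    spec = CircuitSpec(tasks=(TaskSegment("level", 4.0),), speed=1.0, cadence=105.0)
    return generate_trial(spec, GaitStyle(), AnthropometricProfile(), seed=7)


@pytest.fixture(scope="session")
def circuit_trial():
    """Full default circuit (stairs, turn, ramp), one traversal."""
    return generate_trial(
        default_circuit(), GaitStyle(), AnthropometricProfile(), seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
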