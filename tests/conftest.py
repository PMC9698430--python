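import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from locomode.labels import ENABL3S_SCHEMA, LocomotionMode
from locomode.simulate import Scenario, generate


@pytest.fixture(scope="session")
def walking_stream():
    """5 s of steady walking at 500 Hz, two IMUs."""
    scenario = Scenario(segments=((LocomotionMode.WALKING, 5.0),), seed=3)
    return generate(scenario, schema=ENABL3S_SCHEMA)


@pytest.fixture(scope="session")
def mixed_stream():
    """Walking -> standing -> sitting chain with allowed transitions."""
    scenario = Scenario(
        segments=(
            (LocomotionMode.WALKING, 4.0),
            (LocomotionMode.STANDING, 3.0),
            (LocomotionMode.SITTING, 3.0),
        ),
        seed=7,
    )
    return generate(scenario, schema=ENABL3S_SCHEMA)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
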