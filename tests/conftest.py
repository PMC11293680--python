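import numpy as np
import pytest

from evobandit import TaskSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def risk_aversion_task():
    """Representative task where the safe option pays more (D = -20)."""
    return TaskSpec(10.0, 20.0, 30.0, 5.0)


@pytest.fixture
def risk_seeking_task():
    """Representative non-exception task where the risky option pays more."""
    return TaskSpec(10.0, 20.0, -10.0, 5.0)
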