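import numpy as np
import pytest

from eqadapt.network import LayeredNetwork, PhaseSchedule


@pytest.fixture
def small_net():
    """Random 3-4-2 sigmoid network with mild feedback."""
    return LayeredNetwork.initialize([3, 4, 2], seed=7, feedback_gain=0.05)


@pytest.fixture
def zero_net():
    """3-4-2 sigmoid network with all weights and biases zero."""
    sizes = [3, 4, 2]
    weights = [np.zeros((3, 4)), np.zeros((4, 2))]
    biases = [np.zeros(4), np.zeros(2)]
    return LayeredNetwork(sizes, weights, biases)


@pytest.fixture
def short_schedule():
    """Reduced-step schedule for fast training smoke tests."""
    return PhaseSchedule(
        n_free=40, n_clamped=40, teach_delay=4, n_adapt=10, h=0.1, c=0.1, clamp_mode="hard"
    )
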