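import numpy as np
import pytest

from gazesim import Params, Protocol, TrialTimeline
from gazesim.synth import protocol_streams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def timeline():
    return TrialTimeline()


@pytest.fixture
def small_protocol():
    """A reduced design (fewer participants/trials) for fast end-to-end runs."""
    return Protocol(
        n_trials=5,
        n_virtual_participants=4,
        params=Params(beta=2.0, gamma=1.0, theta=0.25),
        master_seed=7,
    )


@pytest.fixture
def small_streams(small_protocol):
    return protocol_streams(small_protocol)


def random_distribution(rng, concentration=1.0):
    """A random point on the 4-simplex."""
    return rng.dirichlet(np.full(4, concentration))
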