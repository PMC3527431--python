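import numpy as np
import pytest
from hypothesis import settings

from grnevo import RegulatoryNetwork, develop, random_network, random_stable_seed

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def stable_founder():
    """One developmentally stable (network, s0) pair at standard parameters."""
    rng = np.random.default_rng(11)
    return random_stable_seed(10, 0.75, rng)


@pytest.fixture(scope="session")
def stable_ensemble():
    """25 independent stable founders, the standard initial-network ensemble."""
    rng = np.random.default_rng(42)
    return [random_stable_seed(10, 0.75, rng) for _ in range(25)]


def zero_network(N: int = 10) -> RegulatoryNetwork:
    mask = np.ones((N, N), dtype=bool)
    return RegulatoryNetwork(np.zeros((N, N)), mask)
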