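import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lattice5():
    from sracipd.network import build_lattice

    return build_lattice(5, 5)


@pytest.fixture
def lattice10():
    from sracipd.network import build_lattice

    return build_lattice(10, 10)


@pytest.fixture
def pair_net():
    """Two agents joined by a single edge (dyad fixture)."""
    from sracipd.network import SocialNetwork

    return SocialNetwork.from_edges([(0, 1)], v=2)
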