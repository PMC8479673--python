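import numpy as np
import pytest

from pta.fixtures import FixtureSpec, make_network
from pta.thermo import build_joint


@pytest.fixture(scope="session")
def triangle():
    """Two-step pathway with a redundant shortcut; rank-deficient energies."""
    net, priors = make_network(
        FixtureSpec(topology="triangle", dg0_rank_deficient=True, seed=0)
    )
    space = build_joint(net, priors)
    return net, priors, space


@pytest.fixture(scope="session")
def chain2():
    net, priors = make_network(FixtureSpec(topology="chain", n_reactions=2, seed=4))
    space = build_joint(net, priors)
    return net, priors, space


@pytest.fixture(scope="session")
def chain1():
    net, priors = make_network(FixtureSpec(topology="chain", n_reactions=1, seed=2))
    space = build_joint(net, priors)
    return net, priors, space


def random_fixture(seed: int, n_reactions: int = 6, **kw):
    net, priors = make_network(
        FixtureSpec(topology="random", n_reactions=n_reactions, seed=seed, **kw)
    )
    space = build_joint(net, priors)
    return net, priors, space


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
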