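import numpy as np
import pytest

from pmneo.community import CommunityGame
from pmneo.datasets import TOY_PARTITION_Q, TOY_PARTITION_S, toy_network


@pytest.fixture(scope="session")
def toy_net():
    return toy_network()


@pytest.fixture(scope="session")
def toy_game(toy_net):
    return CommunityGame(toy_net)


@pytest.fixture(scope="session")
def toy_s():
    """Natural split of the 7-node example: triangle vs near-clique."""
    return TOY_PARTITION_S.copy()


@pytest.fixture(scope="session")
def toy_q():
    """Inferior rearrangement moving nodes 3 and 7 across the bridge."""
    return TOY_PARTITION_Q.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_network(rng, n=12, p_edge=0.35):
    """Small Erdos-Renyi test network with at least one edge."""
    from pmneo.community import Network

    while True:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < p_edge
        if mask.sum() >= 1:
            return Network(n, np.column_stack((iu[mask], ju[mask])))
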