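"""Small built-in example networks used in documentation and tests."""

from __future__ import annotations

import numpy as np

from .community import Network

__all__ = ["toy_network", "TOY_PARTITION_S", "TOY_PARTITION_Q", "two_cliques"]

# 7-node network with a triangle {1,2,3} bridged to a near-clique {4,5,6,7};
# the textbook object for checking community payoffs by hand.
_TOY_EDGES = [(1, 2), (1, 3), (2, 3), (3, 4), (4, 5), (4, 6), (4, 7),
              (5, 6), (5, 7), (6, 7)]

# the natural two-community split and an inferior rearrangement of it
TOY_PARTITION_S = np.array([1, 1, 1, 2, 2, 2, 2])
TOY_PARTITION_Q = np.array([1, 1, 2, 2, 2, 2, 1])


def toy_network() -> Network:
    """The 7-node two-community example network (node IDs 1..7)."""
    return Network.from_edges(_TOY_EDGES)


def two_cliques(k: int = 5) -> tuple[Network, np.ndarray]:
    """Two k-cliques joined by a single bridge edge, plus the clique labels."""
    if k < 2:
        raise ValueError("cliques need at least two nodes")
    edges = []
    for block in (0, 1):
        off = block * k
        edges.extend((off + i, off + j) for i in range(k) for j in range(i + 1, k))
    edges.append((k - 1, k))  # bridge
    labels = np.repeat([0, 1], k)
    return Network(2 * k, edges), labels
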