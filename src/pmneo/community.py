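"""The community-structure detection game on an undirected network.

Nodes are players; each strategy is a community label, so a strategy
profile is a partition of the node set.  The payoff of node ``i`` is its
marginal contribution to the fitness of its own community ``C``:

    u_i = f(C | i in C) - f(C \\ {i}),
    f(C) = sum_j k_in(j) / (sum_j (k_in(j) + k_out(j)))**alpha,

where ``k_in(j)``/``k_out(j)`` count links of member ``j`` inside/outside
``C`` and ``alpha`` (default 1) penalises community size.  For ``alpha=1``
the fitness is the fraction of the community's total degree that stays
internal, so ``f`` lies in [0, 1].

Empty communities and communities of isolated nodes have fitness 0 (the
numerator vanishes).  Node indices are 0-based throughout the library;
file formats and the CLI use the conventional 1-based IDs at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .games import Game

__all__ = [
    "Network",
    "CommunityGame",
    "community_fitness",
    "node_payoff",
    "deviation_payoff",
    "all_node_payoffs",
    "community_aggregates",
    "modularity",
    "improving_players",
]


class Network:
    """Simple undirected graph with contiguous 0-based node indices.

    Stores the edge list and a CSR adjacency (``indptr``/``indices``) for
    fast vectorised sweeps.  ``node_ids`` keeps the external labels the
    graph was built from (defaults to ``1..n`` when constructed directly).
    """

    def __init__(self, n_nodes: int, edges: Iterable[tuple[int, int]],
                 node_ids: Sequence | None = None):
        if n_nodes < 1:
            raise ValueError("network needs at least one node")
        seen: set[tuple[int, int]] = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise ValueError(f"edge ({u},{v}) out of range for n={n_nodes}")
            if u == v:
                raise ValueError(f"self-loop at node {u} not allowed")
            seen.add((min(u, v), max(u, v)))
        self.n_nodes = int(n_nodes)
        self.edges = np.array(sorted(seen), dtype=np.int64).reshape(-1, 2)
        self.m = len(self.edges)
        if node_ids is None:
            node_ids = np.arange(1, n_nodes + 1)
        self.node_ids = np.asarray(node_ids)
        if len(self.node_ids) != n_nodes:
            raise ValueError("node_ids length must equal n_nodes")
        # CSR adjacency
        deg = np.zeros(n_nodes, dtype=np.int64)
        if self.m:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        self.deg = deg
        self.indptr = np.zeros(n_nodes + 1, dtype=np.int64)
        np.cumsum(deg, out=self.indptr[1:])
        self.indices = np.zeros(2 * self.m, dtype=np.int64)
        fill = self.indptr[:-1].copy()
        for u, v in self.edges:
            self.indices[fill[u]] = v
            fill[u] += 1
            self.indices[fill[v]] = u
            fill[v] += 1
        self._edge_set = seen

    # -- queries ---------------------------------------------------------
    def degree(self, i: int) -> int:
        return int(self.deg[i])

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]:self.indptr[i + 1]]

    def has_edge(self, u: int, v: int) -> bool:
        return (min(u, v), max(u, v)) in self._edge_set

    def index_of(self, node_id) -> int:
        """Internal index of an external node ID."""
        hits = np.nonzero(self.node_ids == node_id)[0]
        if not len(hits):
            raise KeyError(f"unknown node id {node_id!r}")
        return int(hits[0])

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable[tuple, ], nodes: Sequence | None = None
                   ) -> "Network":
        """Build from edges over arbitrary (e.g. 1-based) integer node IDs."""
        edges = [(u, v) for u, v in edges]
        ids = set(nodes) if nodes is not None else set()
        for u, v in edges:
            ids.add(u)
            ids.add(v)
        order = sorted(ids)
        lookup = {nid: k for k, nid in enumerate(order)}
        return cls(len(order), [(lookup[u], lookup[v]) for u, v in edges],
                   node_ids=order)

    @classmethod
    def from_networkx(cls, graph) -> "Network":
        nodes = sorted(graph.nodes())
        lookup = {nid: k for k, nid in enumerate(nodes)}
        edges = [(lookup[u], lookup[v]) for u, v in graph.edges() if u != v]
        return cls(len(nodes), edges, node_ids=nodes)

    def to_networkx(self):
        import networkx as nx

        graph = nx.Graph()
        graph.add_nodes_from(self.node_ids.tolist())
        graph.add_edges_from(
            (self.node_ids[u], self.node_ids[v]) for u, v in self.edges
        )
        return graph

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network(n={self.n_nodes}, m={self.m})"


# ---------------------------------------------------------------------------
# fitness, payoffs and modularity
# ---------------------------------------------------------------------------

def _as_labels(profile: Sequence, n: int) -> np.ndarray:
    labels = np.asarray(profile, dtype=np.int64)
    if labels.shape != (n,):
        raise ValueError(f"profile must have length {n}, got shape {labels.shape}")
    if labels.min(initial=0) < 0:
        raise ValueError("community labels must be non-negative")
    return labels


def community_fitness(members: Iterable[int], network: Network,
                      alpha: float = 1.0) -> float:
    """Fitness ``f(C)`` of a node set: internal degree over total degree**alpha.

    The empty set and sets whose total degree is zero have fitness 0.
    """
    members = set(int(i) for i in members)
    for i in members:
        if not 0 <= i < network.n_nodes:
            raise ValueError(f"member {i} outside network of size {network.n_nodes}")
    if not members:
        return 0.0
    k_in = 0
    k_tot = 0
    for i in members:
        k_tot += network.degree(i)
        k_in += sum(1 for j in network.neighbors(i) if int(j) in members)
    if k_tot == 0:
        return 0.0
    return k_in / k_tot ** alpha


def internal_degrees(labels: np.ndarray, network: Network) -> np.ndarray:
    """Per-node count of neighbours sharing the node's community label."""
    if network.m == 0:
        return np.zeros(network.n_nodes, dtype=np.int64)
    owner = np.repeat(np.arange(network.n_nodes), network.deg)
    same = labels[network.indices] == labels[owner]
    return np.bincount(owner[same], minlength=network.n_nodes)


def community_aggregates(labels: Sequence, network: Network
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-community totals ``(sum of internal degrees, sum of degrees)``.

    Arrays are indexed by community label (length ``max(labels) + 1``).
    """
    labels = _as_labels(labels, network.n_nodes)
    d_in = internal_degrees(labels, network)
    size = int(labels.max()) + 1
    lin = np.bincount(labels, weights=d_in, minlength=size)
    dtot = np.bincount(labels, weights=network.deg, minlength=size)
    return lin, dtot


def all_node_payoffs(labels: Sequence, network: Network,
                     alpha: float = 1.0) -> np.ndarray:
    """Vector of payoffs ``u_i = f(C_i) - f(C_i \\ {i})`` for every node."""
    labels = _as_labels(labels, network.n_nodes)
    d_in = internal_degrees(labels, network)
    size = int(labels.max()) + 1
    lin = np.bincount(labels, weights=d_in, minlength=size)
    dtot = np.bincount(labels, weights=network.deg, minlength=size)
    lin_i = lin[labels]
    dtot_i = dtot[labels]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_with = np.where(dtot_i > 0, lin_i / dtot_i ** alpha, 0.0)
        lin_wo = lin_i - 2 * d_in
        dtot_wo = dtot_i - network.deg
        f_wo = np.where(dtot_wo > 0, lin_wo / np.where(dtot_wo > 0, dtot_wo, 1) ** alpha, 0.0)
    return f_with - f_wo


def node_payoff(i: int, profile: Sequence, network: Network,
                alpha: float = 1.0) -> float:
    """Payoff of a single node under the given community assignment."""
    labels = _as_labels(profile, network.n_nodes)
    if not 0 <= i < network.n_nodes:
        raise ValueError(f"node {i} outside network")
    w = labels[i]
    members = set(np.nonzero(labels == w)[0].tolist())
    return community_fitness(members, network, alpha) - community_fitness(
        members - {i}, network, alpha
    )


def _deviation_from_aggregates(i: int, new_label: int, labels: np.ndarray,
                               network: Network, lin: np.ndarray,
                               dtot: np.ndarray, alpha: float) -> float:
    """Payoff of ``i`` after moving to ``new_label``; only the target
    community's aggregates are touched, so the move is O(deg(i))."""
    neigh = network.neighbors(i)
    c = int(np.count_nonzero(labels[neigh] == new_label))
    lv = float(lin[new_label]) if new_label < len(lin) else 0.0
    dv = float(dtot[new_label]) if new_label < len(dtot) else 0.0
    d_i = network.degree(i)
    denom_with = dv + d_i
    f_with = (lv + 2 * c) / denom_with ** alpha if denom_with > 0 else 0.0
    f_wo = lv / dv ** alpha if dv > 0 else 0.0
    return f_with - f_wo


def deviation_payoff(i: int, new_label: int, profile: Sequence,
                     network: Network, alpha: float = 1.0) -> float:
    """Payoff of node ``i`` after it unilaterally joins community ``new_label``.

    Equals ``node_payoff`` on the relabelled profile but is computed
    incrementally from the target community's aggregates.
    """
    labels = _as_labels(profile, network.n_nodes)
    if new_label == labels[i]:
        return node_payoff(i, labels, network, alpha)
    lin, dtot = community_aggregates(labels, network)
    return _deviation_from_aggregates(i, int(new_label), labels, network,
                                      lin, dtot, alpha)


def modularity(profile: Sequence, network: Network) -> float:
    """Newman modularity Q of a partition.

    ``Q = (1/2m) * sum_ij (A_ij - d_i d_j / 2m) delta(C_i, C_j)`` with the
    sum over ordered pairs including ``i = j``; equivalently
    ``sum_w [L_in(w)/2m - (D(w)/2m)^2]``.
    """
    if network.m == 0:
        raise ValueError("modularity undefined for an edgeless network")
    labels = _as_labels(profile, network.n_nodes)
    lin, dtot = community_aggregates(labels, network)
    two_m = 2.0 * network.m
    return float(np.sum(lin / two_m - (dtot / two_m) ** 2))


def improving_players(profile: Sequence, network: Network, alpha: float = 1.0,
                      strict: bool = True) -> np.ndarray:
    """Nodes with a payoff-improving unilateral community change.

    Candidate moves per node: every label present in the profile plus one
    fresh (empty) community, excluding the node's current label.  Joining
    an empty community always pays 0, so a node with negative payoff is
    improving by that move alone.
    """
    labels = _as_labels(profile, network.n_nodes)
    lin, dtot = community_aggregates(labels, network)
    payoffs = all_node_payoffs(labels, network, alpha)
    present = np.unique(labels)
    out = []
    for i in range(network.n_nodes):
        base = payoffs[i]
        best = 0.0  # the fresh-community move
        for v in present:
            if v == labels[i]:
                continue
            dev = _deviation_from_aggregates(i, int(v), labels, network,
                                             lin, dtot, alpha)
            if dev > best:
                best = dev
        if (best > base) if strict else (best >= base):
            out.append(i)
    return np.array(out, dtype=np.int64)


class CommunityGame(Game):
    """Game adapter exposing the community payoffs through the generic
    :class:`~pmneo.games.Game` interface (profiles are label sequences)."""

    def __init__(self, network: Network, alpha: float = 1.0):
        self.network = network
        self.alpha = alpha

    @property
    def n_players(self) -> int:
        return self.network.n_nodes

    def payoff(self, i: int, profile: Sequence) -> float:
        return node_payoff(i, profile, self.network, self.alpha)

    def deviation_payoff(self, i: int, alt, profile: Sequence) -> float:
        return deviation_payoff(i, int(alt), profile, self.network, self.alpha)

    def enumerate_deviations(self, i: int, profile: Sequence) -> list[int]:
        labels = _as_labels(profile, self.network.n_nodes)
        fresh = int(labels.max()) + 1
        alts = [int(v) for v in np.unique(labels) if v != labels[i]]
        alts.append(fresh)
        return alts
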