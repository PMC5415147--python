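"""Reading and writing networks and partitions.

Edge lists are whitespace-separated pairs of integer node IDs, one edge
per line, with ``#`` comments; Pajek ``.net`` and GML files are handled
through networkx.  Partitions are two-column ``node community`` text.
External files use whatever integer node IDs they declare (conventionally
1-based); the in-memory :class:`~pmneo.community.Network` is 0-based and
keeps the original IDs for round-tripping.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .community import Network

__all__ = [
    "read_network",
    "write_network",
    "read_partition",
    "write_partition",
]

_FORMATS = ("edgelist", "gml", "pajek")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".gml":
        return "gml"
    if suffix == ".net":
        return "pajek"
    return "edgelist"


def _read_edgelist(path: Path) -> Network:
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    nodes: set[int] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) == 1:
                # isolated node declaration
                try:
                    nodes.add(int(parts[0]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad node id {parts[0]!r}") from exc
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two node ids, got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer node id in {line!r}") from exc
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop at node {u}")
            key = (min(u, v), max(u, v))
            if key in seen:
                warnings.warn(f"{path}:{lineno}: duplicate edge {u}-{v} ignored")
                continue
            seen.add(key)
            edges.append((u, v))
            nodes.update(key)
    if not nodes:
        raise ValueError(f"{path}: no nodes found")
    return Network.from_edges(edges, nodes=nodes)


def _as_int_ids(graph) -> "nx.Graph":
    simple = nx.Graph()
    mapping = {}
    for node in graph.nodes():
        try:
            mapping[node] = int(node)
        except (TypeError, ValueError):
            mapping = {n: k + 1 for k, n in enumerate(graph.nodes())}
            break
    simple.add_nodes_from(mapping[n] for n in graph.nodes())
    simple.add_edges_from(
        (mapping[u], mapping[v]) for u, v in graph.edges() if u != v
    )
    return simple


def read_network(path, fmt: str | None = None) -> Network:
    """Read a network from an edge list, GML or Pajek file."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "edgelist":
        return _read_edgelist(path)
    if fmt == "gml":
        graph = nx.read_gml(path, label="id")
    else:
        graph = _as_int_ids(nx.read_pajek(path))
    return Network.from_networkx(_as_int_ids(graph))


def write_network(network: Network, path, fmt: str | None = None) -> None:
    """Write a network; losslessly round-trips node IDs and edges."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            for u, v in network.edges:
                fh.write(f"{network.node_ids[u]} {network.node_ids[v]}\n")
    elif fmt == "gml":
        nx.write_gml(network.to_networkx(), path)
    elif fmt == "pajek":
        nx.write_pajek(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def read_partition(path, network: Network | None = None) -> np.ndarray:
    """Read a two-column ``node community`` file into a label vector.

    Labels are ordered by the node order of ``network`` when given,
    otherwise by sorted node ID.
    """
    path = Path(path)
    assignment: dict[int, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'node community', got {line!r}")
            try:
                node, label = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer entry in {line!r}") from exc
            if node in assignment:
                raise ValueError(f"{path}:{lineno}: node {node} assigned twice")
            assignment[node] = label
    if network is not None:
        try:
            return np.array([assignment[int(i)] for i in network.node_ids])
        except KeyError as exc:
            raise ValueError(f"{path}: missing community for node {exc}") from exc
    return np.array([assignment[k] for k in sorted(assignment)])


def write_partition(labels: Sequence, path, network: Network | None = None) -> None:
    """Write a label vector as ``node community`` lines (1-based labels)."""
    labels = np.asarray(labels)
    if network is not None:
        ids = network.node_ids
        if len(labels) != network.n_nodes:
            raise ValueError("label vector length does not match network size")
    else:
        ids = np.arange(1, len(labels) + 1)
    # renumber labels to consecutive 1..k in order of first appearance
    mapping: dict[int, int] = {}
    with open(path, "w") as fh:
        for nid, lab in zip(ids, labels):
            lab = int(lab)
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            fh.write(f"{nid} {mapping[lab]}\n")
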