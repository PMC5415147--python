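"""Planted-partition benchmarks and partition quality metrics.

The GN (Girvan–Newman) benchmark family: 128 nodes in four planted
communities of 32, expected node degree 16, parameterised by ``z_out``,
the expected number of links a node has outside its own community.  It is
realised here as an independent-edge planted-partition model with

    p_in  = (16 - z_out) / 31,     p_out = z_out / 96,

so intra- and inter-community degrees have the prescribed expectations.
Recovered partitions are scored against the planted one with normalised
mutual information (NMI); solution stability is assessed by the fraction
of nodes with a payoff-improving unilateral community change (zero for a
Nash equilibrium of the community game).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .community import Network, improving_players, modularity

__all__ = [
    "GNParams",
    "BatchSummary",
    "generate_gn",
    "nmi",
    "improving_fraction_batch",
    "summarize",
    "ranksum_compare",
]


@dataclass(frozen=True)
class GNParams:
    """Planted-partition benchmark parameters (classic values by default)."""

    n_nodes: int = 128
    n_communities: int = 4
    community_size: int = 32
    expected_degree: int = 16
    z_out: int = 3

    def __post_init__(self):
        if self.n_communities * self.community_size != self.n_nodes:
            raise ValueError("n_communities * community_size must equal n_nodes")
        if not 0 <= self.z_out < self.expected_degree:
            raise ValueError("z_out must lie in [0, expected_degree)")

    @property
    def p_in(self) -> float:
        return (self.expected_degree - self.z_out) / (self.community_size - 1)

    @property
    def p_out(self) -> float:
        return self.z_out / (self.n_nodes - self.community_size)


def generate_gn(params: GNParams, rng: np.random.Generator
                ) -> tuple[Network, np.ndarray]:
    """Sample one planted-partition network; returns (network, planted labels).

    Labels are 0-based community indices in equal consecutive blocks.
    """
    n = params.n_nodes
    labels = np.repeat(np.arange(params.n_communities), params.community_size)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    prob = np.where(same, params.p_in, params.p_out)
    mask = rng.random(len(prob)) < prob
    edges = np.column_stack((iu[mask], ju[mask]))
    return Network(n, edges), labels


def nmi(partition_a: Sequence, partition_b: Sequence,
        normalization: str = "mean") -> float:
    """Normalised mutual information between two partitions, in [0, 1].

    Computed from the confusion matrix ``N`` of the two labelings:
    ``NMI = -2 sum_ij N_ij log(N_ij N / (N_i. N_.j)) /
    [sum_i N_i. log(N_i./N) + sum_j N_.j log(N_.j/N)]`` (the mean-entropy
    normalisation); ``normalization="max"`` divides the mutual information
    by the larger of the two entropies instead.  Two single-community
    partitions are identical, so the degenerate 0/0 case is defined as 1.
    """
    a = np.asarray(partition_a)
    b = np.asarray(partition_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be 1-d sequences of equal length")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    conf = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(conf, (ai, bi), 1.0)
    row = conf.sum(axis=1)
    col = conf.sum(axis=0)
    nz = conf > 0
    mi = float(np.sum(conf[nz] / n * np.log(conf[nz] * n / np.outer(row, col)[nz])))
    h_a = -float(np.sum(row / n * np.log(row / n)))
    h_b = -float(np.sum(col / n * np.log(col / n)))
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if normalization == "mean":
        denom = (h_a + h_b) / 2
    elif normalization == "max":
        denom = max(h_a, h_b)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom == 0.0:
        return 0.0
    return mi / denom


@dataclass
class BatchSummary:
    """Per-run records plus summary statistics of the improving fraction.

    ``cl_low``/``cl_high`` are normal-approximation 95% confidence limits
    of the mean.  All aggregates are recomputable from ``records``.
    """

    records: list[dict] = field(default_factory=list)
    mean: float = 0.0
    sd: float = 0.0
    minimum: float = 0.0
    cl_low: float = 0.0
    cl_high: float = 0.0


def summarize(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """(mean, sample sd, min, CL low, CL high) of a sample."""
    x = np.asarray(values, dtype=float)
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    half = 1.96 * sd / math.sqrt(len(x)) if len(x) > 1 else 0.0
    return mean, sd, float(x.min()), mean - half, mean + half


def improving_fraction_batch(runs: Iterable[tuple[Network, Sequence]],
                             alpha: float = 1.0, strict: bool = True
                             ) -> BatchSummary:
    """Equilibrium check over a batch of (network, partition) solutions.

    For each run, counts the nodes with a strictly improving unilateral
    community change (candidate moves: labels present plus one empty
    community) and divides by the network size; aggregates the fractions.
    """
    records = []
    for network, labels in runs:
        imp = improving_players(labels, network, alpha=alpha, strict=strict)
        records.append({
            "fraction": len(imp) / network.n_nodes,
            "n_improving": len(imp),
            "n_nodes": network.n_nodes,
            "q": modularity(labels, network) if network.m else float("nan"),
        })
    if not records:
        raise ValueError("empty batch")
    mean, sd, minimum, lo, hi = summarize([r["fraction"] for r in records])
    return BatchSummary(records=records, mean=mean, sd=sd, minimum=minimum,
                        cl_low=lo, cl_high=hi)


def ranksum_compare(sample_a: Sequence[float], sample_b: Sequence[float]
                    ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two score samples.

    Thin wrapper over ``scipy.stats.ranksums`` (external statistics, not a
    bespoke implementation); returns (statistic, p-value).
    """
    res = stats.ranksums(sample_a, sample_b)
    return float(res.statistic), float(res.pvalue)
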