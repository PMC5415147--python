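"""pMNEO: population-based extremal optimization guided by p-Nash ascendancy.

The search evolves a population ``P`` of community assignments together
with an archive ``A`` of the same size.  Each generation, every explorer
``P_j`` has its ``l`` lowest-payoff nodes reassigned to random different
communities (the extremal-optimization move); the offspring replaces the
corresponding archive member ``A_j`` only when it p-Nash ascends it with
respect to a freshly sampled player subset, and unconditionally becomes
the new ``P_j``.  ``l`` decays linearly from ``n/10`` to 1 over the run.

Diversity is maintained by *network mixing*: every ``lambda_big``
generations the search temporarily moves to a degree-preserving random
rewiring of the network for ``lambda_small`` generations, re-initialising
the archive at every switch.  Payoffs are always evaluated on the active
(possibly mixed) network; the final answer is the archive member with the
highest modularity on the original network.  Modularity never guides the
search itself — it only selects the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .community import (
    Network,
    _deviation_from_aggregates,
    internal_degrees,
    modularity,
)
from .games import subset_size

__all__ = [
    "EOParams",
    "EOState",
    "PMNEOResult",
    "ell_schedule",
    "mix_network",
    "initialize_populations",
    "eo_iteration",
    "run_pmneo",
]


@dataclass
class EOParams:
    """Search knobs for the extremal-optimization run.

    ``p`` is the fraction of players sampled for each ascendancy test
    (``[p*n]`` must be at least 1).  ``c_min``/``c_max`` bound the number
    of communities an individual may use; each individual draws a fixed
    budget in that range at initialisation, except for a ``pinned_fraction``
    share that is assigned ``pinned_count`` when provided (the usual way to
    inject a believed community count into part of the population).
    """

    pop_size: int = 50
    max_gen: int = 500
    p: float = 0.25
    rho: float = 0.02
    lambda_big: int = 30
    lambda_small: int = 10
    c_min: int = 2
    c_max: int = 8
    pinned_fraction: float = 0.25
    pinned_count: int | None = None
    tie_mode: str = "weak"
    subset_with_replacement: bool = False
    ell: Callable[[int, int, int], int] | None = None

    def validate(self, n_nodes: int) -> None:
        if not 1 <= self.c_min <= self.c_max <= n_nodes:
            raise ValueError(
                f"need 1 <= c_min <= c_max <= n, got ({self.c_min}, {self.c_max}) "
                f"with n={n_nodes}"
            )
        if not 0 <= self.pinned_fraction <= 1:
            raise ValueError("pinned_fraction must lie in [0, 1]")
        if subset_size(n_nodes, self.p) < 1:
            raise ValueError(
                f"p={self.p} gives an empty player subset on n={n_nodes} "
                "(n_p = [p*n] must be > 0)"
            )
        if self.pop_size < 1 or self.max_gen < 0:
            raise ValueError("pop_size must be >= 1 and max_gen >= 0")


@dataclass
class EOState:
    """Evolving populations plus phase bookkeeping.

    ``population[j]`` and ``archive[j]`` are label vectors with values in
    ``{0, .., counts[j]-1}``.  ``phase`` alternates between ``"original"``
    and ``"mixed"``; ``phase_iters`` counts generations spent in the
    current phase.  ``payoff_evals`` counts the payoff-function calls made
    inside the ascendancy comparisons (four per tested differing node).
    """

    population: list[np.ndarray]
    archive: list[np.ndarray]
    counts: np.ndarray
    active_network: Network
    original_network: Network
    alpha: float = 1.0
    generation: int = 0
    phase: str = "original"
    phase_iters: int = 0
    payoff_evals: int = 0
    # caches, valid for the current active network only
    _pop_payoffs: list = field(default_factory=list, repr=False)
    _arch_stats: list = field(default_factory=list, repr=False)

    def invalidate_caches(self) -> None:
        m = len(self.population)
        self._pop_payoffs = [None] * m
        self._arch_stats = [None] * m


def ell_schedule(n: int, nr_gen: int, max_gen: int) -> int:
    """Number of worst nodes to mutate: linear decay from ``n/10`` to 1.

    ``max(1, round(0.1 * n * (1 - nr_gen / max_gen)))``; ``max_gen = 0``
    degenerates to the floor value 1.
    """
    if max_gen <= 0:
        return 1
    frac = 1.0 - nr_gen / max_gen
    return max(1, round(0.1 * n * frac))


def mix_network(network: Network, rho: float, rng: np.random.Generator) -> Network:
    """Degree-preserving random rewiring used as the diversity mechanism.

    Performs ``round(rho * m)`` double-edge-swap attempts: two distinct
    edges (a,b), (c,d) are removed and reconnected as (a,d), (c,b) or
    (a,c), (b,d); attempts that would create self-loops or duplicate edges
    are rejected.  Degrees are preserved exactly; zero successful swaps is
    a legal outcome (e.g. on complete graphs every attempt is rejected).
    """
    attempts = int(round(rho * network.m))
    if attempts == 0 or network.m < 2:
        return network
    edges = [tuple(e) for e in network.edges]
    edge_set = set(edges)
    for _ in range(attempts):
        i1, i2 = rng.choice(network.m, size=2, replace=False)
        a, b = old1 = edges[i1]
        c, d = old2 = edges[i2]
        if rng.random() < 0.5:
            new1, new2 = (a, d), (c, b)
        else:
            new1, new2 = (a, c), (b, d)
        new1 = (min(new1), max(new1))
        new2 = (min(new2), max(new2))
        if new1[0] == new1[1] or new2[0] == new2[1] or new1 == new2:
            continue
        if new1 in edge_set and new1 != old1 and new1 != old2:
            continue
        if new2 in edge_set and new2 != old1 and new2 != old2:
            continue
        edge_set.discard(old1)
        edge_set.discard(old2)
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i1] = new1
        edges[i2] = new2
    return Network(network.n_nodes, edges, node_ids=network.node_ids)


def _random_individuals(n: int, counts: np.ndarray, rng: np.random.Generator
                        ) -> list[np.ndarray]:
    return [rng.integers(0, c, size=n) for c in counts]


def initialize_populations(network: Network, params: EOParams,
                           rng: np.random.Generator, alpha: float = 1.0) -> EOState:
    """Random population and archive; each individual draws its community
    budget uniformly in [c_min, c_max] except the pinned share."""
    params.validate(network.n_nodes)
    m = params.pop_size
    counts = rng.integers(params.c_min, params.c_max + 1, size=m)
    if params.pinned_count is not None:
        if not params.c_min <= params.pinned_count <= params.c_max:
            raise ValueError("pinned_count must lie within [c_min, c_max]")
        n_pin = int(params.pinned_fraction * m)
        counts[:n_pin] = params.pinned_count
    n = network.n_nodes
    state = EOState(
        population=_random_individuals(n, counts, rng),
        archive=_random_individuals(n, counts, rng),
        counts=counts,
        active_network=network,
        original_network=network,
        alpha=alpha,
    )
    state.invalidate_caches()
    return state


def _profile_stats(labels: np.ndarray, net: Network, alpha: float):
    """(lin, dtot, payoffs) of a label vector on a network, one O(m) sweep."""
    d_in = internal_degrees(labels, net)
    size = int(labels.max()) + 1
    lin = np.bincount(labels, weights=d_in, minlength=size)
    dtot = np.bincount(labels, weights=net.deg, minlength=size)
    lin_i = lin[labels]
    dtot_i = dtot[labels]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_with = np.where(dtot_i > 0, lin_i / dtot_i ** alpha, 0.0)
        dtot_wo = dtot_i - net.deg
        safe = np.where(dtot_wo > 0, dtot_wo, 1)
        f_wo = np.where(dtot_wo > 0, (lin_i - 2 * d_in) / safe ** alpha, 0.0)
    return lin, dtot, f_with - f_wo


def eo_iteration(state: EOState, params: EOParams, rng: np.random.Generator) -> EOState:
    """One extremal-optimization generation (in place).

    For every paired (P_j, A_j): mutate the ``l`` lowest-payoff nodes of
    P_j to different random communities within the individual's budget,
    compare offspring and archive member with the reduced ascendancy
    relation over one fresh player subset, replace A_j only on an
    "ascends" verdict, and always advance P_j to the offspring.
    """
    net = state.active_network
    n = net.n_nodes
    schedule = params.ell or ell_schedule
    ell = schedule(n, state.generation, params.max_gen)
    n_p = subset_size(n, params.p)
    weak = params.tie_mode == "weak"
    for j in range(len(state.population)):
        parent = state.population[j]
        if state._pop_payoffs[j] is None:
            _, _, u_parent = _profile_stats(parent, net, state.alpha)
        else:
            u_parent = state._pop_payoffs[j]
        # worst-l nodes, ties broken uniformly at random
        order = np.lexsort((rng.random(n), u_parent))
        targets = order[:ell]
        offspring = parent.copy()
        budget = int(state.counts[j])
        if budget > 1:
            draws = rng.integers(0, budget - 1, size=len(targets))
            draws = np.where(draws >= offspring[targets], draws + 1, draws)
            offspring[targets] = draws
        lin_o, dtot_o, u_off = _profile_stats(offspring, net, state.alpha)

        archive = state.archive[j]
        if params.subset_with_replacement:
            subset = rng.choice(n, size=n_p, replace=True)
        else:
            subset = rng.choice(n, size=n_p, replace=False)
        diff = subset[offspring[subset] != archive[subset]]
        if len(diff):
            if state._arch_stats[j] is None:
                state._arch_stats[j] = _profile_stats(archive, net, state.alpha)
            lin_a, dtot_a, u_arch = state._arch_stats[j]
            k_fwd = 0
            k_back = 0
            for i in diff:
                i = int(i)
                dev_fwd = _deviation_from_aggregates(
                    i, int(archive[i]), offspring, net, lin_o, dtot_o, state.alpha)
                dev_back = _deviation_from_aggregates(
                    i, int(offspring[i]), archive, net, lin_a, dtot_a, state.alpha)
                if weak:
                    k_fwd += u_off[i] <= dev_fwd
                    k_back += u_arch[i] <= dev_back
                else:
                    k_fwd += u_off[i] < dev_fwd
                    k_back += u_arch[i] < dev_back
            state.payoff_evals += 4 * len(diff)
            if k_fwd < k_back:
                state.archive[j] = offspring.copy()
                state._arch_stats[j] = (lin_o, dtot_o, u_off)
        state.population[j] = offspring
        state._pop_payoffs[j] = u_off
    state.generation += 1
    state.phase_iters += 1
    return state


@dataclass
class PMNEOResult:
    """Best archive member (by modularity on the original network) plus
    run diagnostics."""

    labels: np.ndarray
    modularity: float
    payoff_evals: int
    generations: int
    history: list[float] | None = None
    phase_history: list[str] | None = None

    def n_communities(self) -> int:
        return len(np.unique(self.labels))


def run_pmneo(network: Network, params: EOParams, rng: np.random.Generator,
              alpha: float = 1.0, track_history: bool = True) -> PMNEOResult:
    """Full pMNEO run: alternating original/mixed phases, archive restarts
    at every phase switch, modularity-based output selection."""
    params.validate(network.n_nodes)
    state = initialize_populations(network, params, rng, alpha=alpha)
    history: list[float] = []
    phases: list[str] = []
    for gen in range(params.max_gen):
        phases.append(state.phase)
        eo_iteration(state, params, rng)
        if track_history:
            history.append(max(modularity(a, network) for a in state.archive))
        if gen == params.max_gen - 1:
            break  # never restart the archive after the final generation
        if state.phase == "original" and state.phase_iters >= params.lambda_big:
            state.active_network = mix_network(network, params.rho, rng)
            state.phase = "mixed"
            state.phase_iters = 0
            state.archive = _random_individuals(network.n_nodes, state.counts, rng)
            state.invalidate_caches()
        elif state.phase == "mixed" and state.phase_iters >= params.lambda_small:
            state.active_network = network
            state.phase = "original"
            state.phase_iters = 0
            state.archive = _random_individuals(network.n_nodes, state.counts, rng)
            state.invalidate_caches()
    qs = [modularity(a, network) for a in state.archive]
    best = int(np.argmax(qs))
    return PMNEOResult(
        labels=state.archive[best].copy(),
        modularity=float(qs[best]),
        payoff_evals=state.payoff_evals,
        generations=state.generation,
        history=history if track_history else None,
        phase_history=phases,
    )
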