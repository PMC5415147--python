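"""Cournot oligopoly benchmark with a known closed-form Nash equilibrium.

``n`` firms simultaneously choose production quantities ``q_i``; the
market price is linear, ``P(Q) = max(a - Q, 0)`` with ``Q = sum q_i``, and
each firm has constant marginal cost ``c < a``, so the profit is

    u_i = q_i * P(Q) - c * q_i .

The game has the unique symmetric equilibrium ``q_i = (a - c)/(n + 1)``,
which makes it a convenient scalable test bed for equilibrium-seeking
search: the distance of a candidate profile to the analytic equilibrium
is an exact progress measure.  The extremal-optimization variant used
here (``run_pmneo_minus``) drops the network-mixing diversity mechanism —
strategies are continuous, so there is no network to mix — and mutates
the lowest-profit firms with fresh uniform draws from the strategy box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .games import Game, subset_size
from .search import EOParams, ell_schedule

__all__ = [
    "CournotParams",
    "CournotGame",
    "CournotResult",
    "cournot_payoffs",
    "cournot_ne",
    "run_pmneo_minus",
]


@dataclass(frozen=True)
class CournotParams:
    """Market parameters: firm count, demand intercept ``a``, marginal
    cost ``c < a`` and the per-firm strategy interval."""

    n_firms: int
    a: float = 24.0
    c: float = 9.0
    strategy_bounds: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self):
        if self.n_firms < 1:
            raise ValueError("need at least one firm")
        if not self.c < self.a:
            raise ValueError("marginal cost c must be below the intercept a")
        lo, hi = self.strategy_bounds
        if not lo < hi:
            raise ValueError("strategy bounds must be a nonempty interval")


def cournot_payoffs(quantities: Sequence[float], params: CournotParams) -> np.ndarray:
    """Profit vector ``u_i = q_i * max(a - Q, 0) - c * q_i``."""
    q = np.asarray(quantities, dtype=float)
    if q.shape != (params.n_firms,):
        raise ValueError(f"expected {params.n_firms} quantities, got shape {q.shape}")
    if np.any(q < 0):
        raise ValueError("quantities must be non-negative")
    price = max(params.a - float(q.sum()), 0.0)
    return q * price - params.c * q


def cournot_ne(params: CournotParams) -> np.ndarray:
    """The symmetric Nash equilibrium ``q_i = (a - c)/(n + 1)`` for all firms."""
    return np.full(params.n_firms, (params.a - params.c) / (params.n_firms + 1))


class CournotGame(Game):
    """Generic-game adapter; supplies the analytic best response
    ``max(0, (a - c - Q_-i)/2)`` clipped to the strategy bounds."""

    def __init__(self, params: CournotParams):
        self.params = params

    @property
    def n_players(self) -> int:
        return self.params.n_firms

    def payoff(self, i: int, profile: Sequence[float]) -> float:
        return float(cournot_payoffs(profile, self.params)[i])

    def deviation_payoff(self, i: int, alt: float, profile: Sequence[float]) -> float:
        q = np.asarray(profile, dtype=float)
        total = float(q.sum()) - float(q[i]) + float(alt)
        price = max(self.params.a - total, 0.0)
        return float(alt) * price - self.params.c * float(alt)

    def best_response(self, i: int, profile: Sequence[float]) -> float:
        q = np.asarray(profile, dtype=float)
        rest = float(q.sum()) - float(q[i])
        br = (self.params.a - self.params.c - rest) / 2.0
        lo, hi = self.params.strategy_bounds
        return float(np.clip(br, lo, hi))


@dataclass
class CournotResult:
    """Final best archive profile and the per-generation distance trace."""

    quantities: np.ndarray
    distance_trace: np.ndarray
    payoff_evals: int


def _distance(profiles: np.ndarray, ne: np.ndarray) -> float:
    return float(np.min(np.linalg.norm(profiles - ne, axis=1)))


def run_pmneo_minus(params: CournotParams, eo: EOParams,
                    rng: np.random.Generator, mutation: str = "uniform",
                    sigma: float | None = None) -> CournotResult:
    """Extremal optimization on continuous quantities, no mixing phases.

    Each generation the ``l`` lowest-profit firms of every explorer get
    fresh uniform draws from the strategy box (``mutation="gaussian"``
    perturbs them instead, sd ``sigma`` defaulting to a tenth of the box
    width); the paired archive member is replaced when the offspring
    p-Nash ascends it over one freshly sampled firm subset.  The trace
    records, per generation, the Euclidean distance of the closest archive
    member to the analytic equilibrium (entry 0 is the initialisation).
    """
    if mutation not in ("uniform", "gaussian"):
        raise ValueError("mutation must be 'uniform' or 'gaussian'")
    n = params.n_firms
    n_p = subset_size(n, eo.p)
    if n_p < 1:
        raise ValueError(f"p={eo.p} gives an empty subset on n={n}")
    lo, hi = params.strategy_bounds
    if sigma is None:
        sigma = 0.1 * (hi - lo)
    m = eo.pop_size
    population = rng.uniform(lo, hi, size=(m, n))
    archive = rng.uniform(lo, hi, size=(m, n))
    ne = cournot_ne(params)
    a_par, c_par = params.a, params.c
    weak = eo.tie_mode == "weak"
    schedule = eo.ell or ell_schedule
    trace = [_distance(archive, ne)]
    payoff_evals = 0

    def payoffs(q: np.ndarray) -> np.ndarray:
        return q * max(a_par - q.sum(), 0.0) - c_par * q

    def dev(alt: float, i: int, q: np.ndarray, total: float) -> float:
        t = total - q[i] + alt
        return alt * max(a_par - t, 0.0) - c_par * alt

    for gen in range(eo.max_gen):
        ell = schedule(n, gen, eo.max_gen)
        for j in range(m):
            parent = population[j]
            u_parent = payoffs(parent)
            order = np.lexsort((rng.random(n), u_parent))
            targets = order[:ell]
            offspring = parent.copy()
            if mutation == "uniform":
                offspring[targets] = rng.uniform(lo, hi, size=len(targets))
            else:
                offspring[targets] = np.clip(
                    offspring[targets] + rng.normal(0.0, sigma, size=len(targets)),
                    lo, hi)
            arch = archive[j]
            subset = rng.choice(n, size=n_p,
                                replace=eo.subset_with_replacement)
            diff = subset[offspring[subset] != arch[subset]]
            if len(diff):
                u_off = payoffs(offspring)
                u_arch = payoffs(arch)
                tot_off = float(offspring.sum())
                tot_arch = float(arch.sum())
                k_fwd = 0
                k_back = 0
                for i in diff:
                    i = int(i)
                    fwd = dev(float(arch[i]), i, offspring, tot_off)
                    back = dev(float(offspring[i]), i, arch, tot_arch)
                    if weak:
                        k_fwd += u_off[i] <= fwd
                        k_back += u_arch[i] <= back
                    else:
                        k_fwd += u_off[i] < fwd
                        k_back += u_arch[i] < back
                payoff_evals += 4 * len(diff)
                if k_fwd < k_back:
                    archive[j] = offspring.copy()
            population[j] = offspring
        trace.append(_distance(archive, ne))
    best = int(np.argmin(np.linalg.norm(archive - ne, axis=1)))
    return CournotResult(
        quantities=archive[best].copy(),
        distance_trace=np.asarray(trace),
        payoff_evals=payoff_evals,
    )
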