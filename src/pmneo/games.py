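"""Finite-game primitives: Nash ascendancy operators and equilibrium checks.

A game with players ``N = {1..n}`` is compared at the level of *strategy
profiles* rather than individual strategies.  The quality operator

    k(s, q) = card{ i in N : u_i(s) <= u_i(q_i, s_-i), s_i != q_i }

counts the players who would not lose by unilaterally switching from their
strategy in ``s`` to the one they hold in ``q``.  Profile ``s`` *Nash
ascends* ``q`` when ``k(s, q) < k(q, s)``; if a Nash equilibrium exists, the
set of non-ascended profiles coincides with the equilibrium set, which makes
the relation usable as a selection rule inside heuristic search.

The *reduced* operator ``k_p`` applies the same counting rule to a random
subset ``I_p`` of ``[p * n]`` players only, trading exactness per comparison
for fewer payoff evaluations.  Averaged over all subsets of a given size the
reduced count is proportional to the full one, so equilibria remain exactly
the non-ascended profiles under the reduced relation as well.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Game",
    "TabularGame",
    "PlayerSubset",
    "AscendancyResult",
    "EquilibriumReport",
    "k_operator",
    "kp_operator",
    "p_nash_compare",
    "sample_player_subset",
    "verify_equilibrium",
    "enumerate_profiles",
    "brute_force_nash",
]


class Game(ABC):
    """A finite- or continuous-strategy game in normal form.

    Subclasses provide the player count, per-player payoffs on a full
    strategy profile and payoffs under unilateral deviation.  Discrete games
    additionally enumerate the alternative strategies of a player;
    continuous games supply a best response instead.
    """

    @property
    @abstractmethod
    def n_players(self) -> int: ...

    @abstractmethod
    def payoff(self, i: int, profile: Sequence) -> float:
        """Payoff of player ``i`` under ``profile`` (deterministic)."""

    def deviation_payoff(self, i: int, alt, profile: Sequence) -> float:
        """Payoff of ``i`` after unilaterally switching to strategy ``alt``.

        Deviating to one's own strategy is a no-op:
        ``deviation_payoff(i, profile[i], profile) == payoff(i, profile)``.
        """
        mutated = list(profile)
        mutated[i] = alt
        return self.payoff(i, mutated)

    def enumerate_deviations(self, i: int, profile: Sequence) -> Iterable:
        """Alternative strategies of player ``i`` (discrete games only)."""
        raise NotImplementedError(
            f"{type(self).__name__} does not enumerate deviations"
        )

    def best_response(self, i: int, profile: Sequence):
        """Best reply of player ``i`` to ``profile`` (continuous games only)."""
        raise NotImplementedError(
            f"{type(self).__name__} does not provide a best response"
        )

    def _check_profile(self, profile: Sequence) -> None:
        if len(profile) != self.n_players:
            raise ValueError(
                f"profile length {len(profile)} != n_players {self.n_players}"
            )


class TabularGame(Game):
    """Discrete game given by explicit payoff tensors.

    ``tensors[i]`` has one axis per player; entry ``tensors[i][s]`` is the
    payoff of player ``i`` under the pure-strategy profile ``s``.
    """

    def __init__(self, tensors: Sequence[np.ndarray]):
        tensors = [np.asarray(t, dtype=float) for t in tensors]
        shape = tensors[0].shape
        if len(shape) != len(tensors):
            raise ValueError("need one tensor axis per player")
        for t in tensors:
            if t.shape != shape:
                raise ValueError("all payoff tensors must share a shape")
        self.tensors = tensors
        self.n_strategies = shape

    @property
    def n_players(self) -> int:
        return len(self.tensors)

    def payoff(self, i: int, profile: Sequence) -> float:
        self._check_profile(profile)
        return float(self.tensors[i][tuple(profile)])

    def enumerate_deviations(self, i: int, profile: Sequence) -> Iterable[int]:
        return [a for a in range(self.n_strategies[i]) if a != profile[i]]

    @classmethod
    def random(cls, n_players: int, n_strategies: int | Sequence[int],
               rng: np.random.Generator) -> "TabularGame":
        if isinstance(n_strategies, int):
            shape = (n_strategies,) * n_players
        else:
            shape = tuple(n_strategies)
        return cls([rng.random(shape) for _ in range(n_players)])


@dataclass(frozen=True)
class PlayerSubset:
    """A set ``I_p`` of player indices used by the reduced operator.

    ``indices`` is kept as a tuple so that the with-replacement reading of
    the sampling loop (repeated indices counted with multiplicity) can be
    represented; the default sampling draws without replacement, matching
    the set-based definition under which the proportionality identities are
    proved.
    """

    indices: tuple[int, ...]

    def __post_init__(self):
        if len(self.indices) == 0:
            raise ValueError("player subset must be non-empty (n_p > 0)")

    @property
    def size(self) -> int:
        return len(self.indices)

    def validate(self, n_players: int) -> None:
        for i in self.indices:
            if not 0 <= i < n_players:
                raise ValueError(f"player index {i} out of range 0..{n_players - 1}")


@dataclass(frozen=True)
class AscendancyResult:
    """The two reduced counts for an ordered profile pair and the verdict.

    ``verdict`` is ``"ascends"`` when ``k_forward < k_backward`` (the first
    profile p-Nash ascends the second), ``"ascended"`` for the reverse
    inequality and ``"indifferent"`` on equality.
    """

    k_forward: int
    k_backward: int

    @property
    def verdict(self) -> str:
        if self.k_forward < self.k_backward:
            return "ascends"
        if self.k_forward > self.k_backward:
            return "ascended"
        return "indifferent"


@dataclass(frozen=True)
class EquilibriumReport:
    """Players with a strictly improving unilateral deviation."""

    improving_players: frozenset[int]
    n_players: int

    @property
    def fraction(self) -> float:
        return len(self.improving_players) / self.n_players

    @property
    def is_equilibrium(self) -> bool:
        return not self.improving_players


def _count(s: Sequence, q: Sequence, indices: Iterable[int], game: Game,
           tie_mode: str) -> int:
    if tie_mode not in ("weak", "strict"):
        raise ValueError(f"tie_mode must be 'weak' or 'strict', got {tie_mode!r}")
    count = 0
    for i in indices:
        if s[i] == q[i]:
            continue  # equal strategies are never payoff-compared
        us = game.payoff(i, s)
        ud = game.deviation_payoff(i, q[i], s)
        if (us <= ud) if tie_mode == "weak" else (us < ud):
            count += 1
    return count


def k_operator(s: Sequence, q: Sequence, game: Game, tie_mode: str = "weak") -> int:
    """Full quality operator ``k(s, q)`` over all players.

    Counts players ``i`` with ``s_i != q_i`` whose payoff under ``s`` does
    not exceed (``tie_mode="weak"``, the definitional reading) or is
    strictly below (``"strict"``) their payoff after unilaterally adopting
    ``q_i``.  No payoffs are evaluated for players with identical strategies.
    """
    game._check_profile(s)
    game._check_profile(q)
    return _count(s, q, range(game.n_players), game, tie_mode)


def kp_operator(s: Sequence, q: Sequence, subset: PlayerSubset, game: Game,
                tie_mode: str = "weak") -> int:
    """Reduced operator ``k_p(s, q, I_p)``: the same count restricted to ``I_p``."""
    game._check_profile(s)
    game._check_profile(q)
    subset.validate(game.n_players)
    return _count(s, q, subset.indices, game, tie_mode)


def p_nash_compare(s: Sequence, q: Sequence, subset: PlayerSubset, game: Game,
                   tie_mode: str = "weak") -> AscendancyResult:
    """Compare two profiles with the p-Nash ascendancy relation.

    Both directed counts are taken over the *same* subset (a single pass in
    the search loop), and payoffs are evaluated only at positions where the
    profiles differ.
    """
    game._check_profile(s)
    game._check_profile(q)
    subset.validate(game.n_players)
    k_fwd = 0
    k_back = 0
    for i in subset.indices:
        if s[i] == q[i]:
            continue
        us = game.payoff(i, s)
        us_dev = game.deviation_payoff(i, q[i], s)
        uq = game.payoff(i, q)
        uq_dev = game.deviation_payoff(i, s[i], q)
        if tie_mode == "weak":
            k_fwd += us <= us_dev
            k_back += uq <= uq_dev
        else:
            k_fwd += us < us_dev
            k_back += uq < uq_dev
    return AscendancyResult(k_forward=k_fwd, k_backward=k_back)


def subset_size(n: int, p: float) -> int:
    """``n_p = [p * n]`` (integer part, guarded against float round-off)."""
    return int(math.floor(p * n + 1e-9))


def sample_player_subset(n: int, p: float, rng: np.random.Generator,
                         with_replacement: bool = False) -> PlayerSubset:
    """Draw a uniform random subset ``I_p`` of ``[p * n]`` of the ``n`` players.

    Raises if ``[p * n] = 0``: the reduced relation requires ``n_p > 0``.
    ``with_replacement=True`` reproduces the literal reading of the sampling
    loop in which the same player may be drawn twice (repeats then count
    with multiplicity).
    """
    n_p = subset_size(n, p)
    if n_p < 1:
        raise ValueError(
            f"p={p} with n={n} gives n_p=[p*n]={n_p}; the reduced relation "
            "requires n_p > 0"
        )
    idx = rng.choice(n, size=n_p, replace=with_replacement)
    return PlayerSubset(tuple(int(i) for i in idx))


def verify_equilibrium(s: Sequence, game: Game, strict: bool = True) -> EquilibriumReport:
    """Exhaustively test ``s`` for unilateral improvement opportunities.

    A player is *improving* when some enumerated deviation (or the best
    response, for continuous games) yields a strictly greater payoff;
    ``strict=False`` counts ties as improvements for sensitivity analysis.
    The profile is a Nash equilibrium w.r.t. the tested deviation set iff
    the improving fraction is zero.
    """
    game._check_profile(s)
    improving: set[int] = set()
    for i in range(game.n_players):
        base = game.payoff(i, s)
        try:
            alts = list(game.enumerate_deviations(i, s))
        except NotImplementedError:
            alts = [game.best_response(i, s)]  # raises if unsupported too
        for alt in alts:
            dev = game.deviation_payoff(i, alt, s)
            if (dev > base) if strict else (dev >= base):
                improving.add(i)
                break
    return EquilibriumReport(frozenset(improving), game.n_players)


def enumerate_profiles(game: TabularGame) -> Iterator[tuple[int, ...]]:
    """All pure-strategy profiles of a tabular game."""
    return product(*(range(k) for k in game.n_strategies))


def brute_force_nash(game: TabularGame) -> list[tuple[int, ...]]:
    """All pure Nash equilibria of a small tabular game, by enumeration."""
    return [
        s for s in enumerate_profiles(game)
        if verify_equilibrium(s, game).is_equilibrium
    ]
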