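"""Nash ascendancy operators: worked-example counts, reduction identities
and equilibrium characterisation on exhaustively solvable games."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmneo.games import (
    AscendancyResult,
    PlayerSubset,
    TabularGame,
    brute_force_nash,
    enumerate_profiles,
    k_operator,
    kp_operator,
    p_nash_compare,
    sample_player_subset,
    verify_equilibrium,
)

# ---------------------------------------------------------------------------
# independent oracles (coded from the definitions, no shared code paths)
# ---------------------------------------------------------------------------


def oracle_k(s, q, game):
    """Quality operator recomputed by full-profile substitution."""
    count = 0
    for i in range(game.n_players):
        if s[i] == q[i]:
            continue
        mutated = list(s)
        mutated[i] = q[i]
        if game.payoff(i, s) <= game.payoff(i, mutated):
            count += 1
    return count


def oracle_verdict(s, q, game):
    """Full Nash-ascendancy verdict from the raw definition."""
    fwd, back = oracle_k(s, q, game), oracle_k(q, s, game)
    if fwd < back:
        return "ascends"
    if fwd > back:
        return "ascended"
    return "indifferent"


def oracle_nash_equilibria(game):
    """All pure NEs by direct payoff-tensor enumeration."""
    out = []
    for s in itertools.product(*(range(k) for k in game.n_strategies)):
        is_ne = True
        for i in range(game.n_players):
            base = game.tensors[i][s]
            for alt in range(game.n_strategies[i]):
                mutated = list(s)
                mutated[i] = alt
                if game.tensors[i][tuple(mutated)] > base:
                    is_ne = False
                    break
            if not is_ne:
                break
        if is_ne:
            out.append(s)
    return out


class CountingGame(TabularGame):
    """Tabular game that records which players had payoffs evaluated."""

    def __init__(self, tensors):
        super().__init__(tensors)
        self.evaluated = []

    def payoff(self, i, profile):
        self.evaluated.append(i)
        return super().payoff(i, profile)


# ---------------------------------------------------------------------------
# worked example and basic operator behaviour
# ---------------------------------------------------------------------------


def test_worked_example_k_counts(toy_game, toy_s, toy_q):
    assert k_operator(toy_s, toy_q, toy_game) == 0
    assert k_operator(toy_q, toy_s, toy_game) == 2
    assert k_operator(toy_s, toy_s, toy_game) == 0


def test_worked_example_reduced_counts(toy_game, toy_s, toy_q):
    subset = PlayerSubset((0, 2, 4))  # nodes 1, 3, 5
    assert kp_operator(toy_s, toy_q, subset, toy_game) == 0
    assert kp_operator(toy_q, toy_s, subset, toy_game) == 1
    result = p_nash_compare(toy_s, toy_q, subset, toy_game)
    assert (result.k_forward, result.k_backward) == (0, 1)
    assert result.verdict == "ascends"


def test_profile_length_mismatch_rejected(toy_game, toy_s):
    with pytest.raises(ValueError, match="length"):
        k_operator(toy_s[:5], toy_s, toy_game)


def test_subset_index_out_of_range_rejected(toy_game, toy_s, toy_q):
    with pytest.raises(ValueError, match="out of range"):
        kp_operator(toy_s, toy_q, PlayerSubset((0, 99)), toy_game)


def test_equal_strategy_players_never_evaluated(rng):
    game = CountingGame([rng.random((2, 2, 2)) for _ in range(3)])
    s, q = (0, 1, 0), (0, 1, 1)  # players 0 and 1 agree
    k_operator(s, q, game)
    assert set(game.evaluated) <= {2}
    game.evaluated.clear()
    k_operator(s, s, game)
    assert game.evaluated == []


def test_full_subset_equals_full_operator(rng):
    """p = 1 reduces the relation to the plain Nash ascendancy."""
    for _ in range(30):
        game = TabularGame.random(4, 3, rng)
        s = tuple(rng.integers(0, 3, size=4))
        q = tuple(rng.integers(0, 3, size=4))
        full = PlayerSubset(tuple(range(4)))
        assert kp_operator(s, q, full, game) == k_operator(s, q, game)


def test_compare_matches_independent_oracle(rng):
    """Full-subset verdicts agree with a separately coded routine."""
    for _ in range(50):
        game = TabularGame.random(4, 2, rng)
        s = tuple(rng.integers(0, 2, size=4))
        q = tuple(rng.integers(0, 2, size=4))
        full = PlayerSubset(tuple(range(4)))
        assert p_nash_compare(s, q, full, game).verdict == oracle_verdict(s, q, game)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_verdict_antisymmetry(seed):
    """Swapping the profile order flips (or preserves indifferent) verdicts."""
    rng = np.random.default_rng(seed)
    game = TabularGame.random(3, 3, rng)
    s = tuple(rng.integers(0, 3, size=3))
    q = tuple(rng.integers(0, 3, size=3))
    subset = sample_player_subset(3, 0.67, rng)
    fwd = p_nash_compare(s, q, subset, game).verdict
    back = p_nash_compare(q, s, subset, game).verdict
    assert {fwd, back} in ({"ascends", "ascended"}, {"indifferent"})


# ---------------------------------------------------------------------------
# subset sampling
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n, p, expected", [(7, 0.5, 3), (10, 1.0, 10), (10, 0.25, 2)])
def test_subset_sizes_take_integer_part(n, p, expected, rng):
    subset = sample_player_subset(n, p, rng)
    assert subset.size == expected
    assert len(set(subset.indices)) == expected
    assert all(0 <= i < n for i in subset.indices)


def test_empty_subset_rejected(rng):
    with pytest.raises(ValueError, match="n_p > 0"):
        sample_player_subset(3, 0.1, rng)


def test_with_replacement_sampling_may_repeat(rng):
    sizes = {
        len(set(sample_player_subset(5, 1.0, rng, with_replacement=True).indices))
        for _ in range(50)
    }
    assert min(sizes) < 5  # some draw repeated a player


# ---------------------------------------------------------------------------
# reduction identities (proportionality of the reduced operator)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n, n_p", [(4, 2), (5, 2), (5, 3), (6, 4)])
def test_subset_sum_proportionality(n, n_p, rng):
    """Sum of k_p over all subsets of size n_p is C(n-1, n_p-1) * k."""
    game = TabularGame.random(n, 2, rng)
    for _ in range(5):
        s = tuple(rng.integers(0, 2, size=n))
        q = tuple(rng.integers(0, 2, size=n))
        total = sum(
            kp_operator(s, q, PlayerSubset(c), game)
            for c in itertools.combinations(range(n), n_p)
        )
        assert total == math.comb(n - 1, n_p - 1) * k_operator(s, q, game)


@pytest.mark.parametrize("n, n_r, n_p", [(5, 4, 2), (6, 4, 2), (6, 5, 3)])
def test_nested_subset_proportionality(n, n_r, n_p, rng):
    """k_r over a fixed larger subset equals the normalised sum of k_p over
    its contained smaller subsets."""
    game = TabularGame.random(n, 2, rng)
    for _ in range(3):
        s = tuple(rng.integers(0, 2, size=n))
        q = tuple(rng.integers(0, 2, size=n))
        i_r = tuple(sorted(rng.choice(n, size=n_r, replace=False)))
        k_r = kp_operator(s, q, PlayerSubset(i_r), game)
        total = sum(
            kp_operator(s, q, PlayerSubset(c), game)
            for c in itertools.combinations(i_r, n_p)
        )
        assert total == math.comb(n_r - 1, n_p - 1) * k_r


# ---------------------------------------------------------------------------
# equilibrium characterisation on exhaustively solvable games
# ---------------------------------------------------------------------------


def _pnnd_set(game, n_p):
    """Profiles never p-ascended by any other profile, any subset of size n_p."""
    profiles = list(enumerate_profiles(game))
    out = []
    for s in profiles:
        ascended = False
        for q in profiles:
            for c in itertools.combinations(range(game.n_players), n_p):
                subset = PlayerSubset(c)
                if kp_operator(q, s, subset, game) < kp_operator(s, q, subset, game):
                    ascended = True
                    break
            if ascended:
                break
        if not ascended:
            out.append(s)
    return out


def _nnd_set(game):
    profiles = list(enumerate_profiles(game))
    return [
        s for s in profiles
        if not any(k_operator(q, s, game) < k_operator(s, q, game) for q in profiles)
    ]


def test_equilibria_are_never_p_ascended(rng):
    """Every brute-forced NE survives the reduced relation for every subset."""
    found_ne = 0
    for _ in range(20):
        game = TabularGame.random(3, 3, rng)
        for ne in oracle_nash_equilibria(game):
            found_ne += 1
            for n_p in (1, 2, 3):
                for c in itertools.combinations(range(3), n_p):
                    subset = PlayerSubset(c)
                    for q in enumerate_profiles(game):
                        assert not (
                            kp_operator(q, ne, subset, game)
                            < kp_operator(ne, q, subset, game)
                        )
    assert found_ne > 0  # the sample of random games must exercise the claim


def test_reduced_nondominated_set_within_full_one(rng):
    for _ in range(10):
        game = TabularGame.random(3, 2, rng)
        nnd = set(_nnd_set(game))
        for n_p in (1, 2):
            assert set(_pnnd_set(game, n_p)) <= nnd


def test_brute_force_nash_matches_oracle(rng):
    for _ in range(20):
        game = TabularGame.random(3, 3, rng)
        assert brute_force_nash(game) == oracle_nash_equilibria(game)


def test_verify_equilibrium_reports_improvers():
    # player 0 strictly prefers strategy 1 whatever the opponent does
    u0 = np.array([[0.0, 0.0], [1.0, 1.0]])
    u1 = np.array([[0.5, 0.5], [0.5, 0.5]])
    game = TabularGame([u0, u1])
    report = verify_equilibrium((0, 0), game)
    assert 0 in report.improving_players
    assert report.fraction == 0.5
    assert verify_equilibrium((1, 0), game).fraction == 0.0


def test_verify_equilibrium_on_toy_partition(toy_game, toy_s):
    """The natural two-community split of the example network is a Nash
    equilibrium: no node gains by any community change."""
    report = verify_equilibrium(toy_s, toy_game)
    assert report.fraction == 0.0
    assert report.is_equilibrium


def test_ascendancy_result_verdicts():
    assert AscendancyResult(0, 1).verdict == "ascends"
    assert AscendancyResult(2, 1).verdict == "ascended"
    assert AscendancyResult(1, 1).verdict == "indifferent"
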