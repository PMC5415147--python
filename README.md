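# pmneo — game-theoretic community detection

`pmneo` detects community structure in undirected networks by treating the
problem as a non-cooperative game: every node is a player whose strategy is
the community it joins, and a community structure is *good* when it is a
Nash equilibrium — no single node can improve its payoff by switching
community on its own.  This equilibrium view is aimed at network scientists
(and systems biologists working with interaction networks) who want
partitions that are stable against individual reassignment rather than
merely optimal under a global score.

## The model

For a graph `G = (V, E)` and a community `C ⊆ V`, the community fitness is

```
f(C) = Σ_{j∈C} k_in(j) / ( Σ_{j∈C} (k_in(j) + k_out(j)) )^α ,
```

where `k_in(j)` / `k_out(j)` count the links of member `j` inside/outside
`C` and `α = 1` by default.  The payoff of node `i` in its community `C` is
its marginal contribution `u_i = f(C) − f(C \ {i})`.

Profiles (label vectors) are compared with the **Nash ascendancy** quality
operator

```
k(s, q) = card{ i : u_i(s) ≤ u_i(q_i, s_−i), s_i ≠ q_i } ,
```

`s` ascends `q` when `k(s, q) < k(q, s)`; non-ascended profiles coincide
with the Nash equilibria whenever an equilibrium exists.  The **reduced**
operator `k_p` applies the same count to a random subset of `[p·n]` players
only, cutting payoff evaluations per comparison while (provably) preserving
the equilibrium characterisation — summed over all subsets of a fixed size,
the reduced counts are exactly proportional to the full ones.

The search itself (**pMNEO**) is extremal optimization: a population of
candidate partitions paired with an archive of best-so-far solutions.  Each
generation the `ℓ` lowest-payoff nodes of every candidate are reassigned to
random communities; the offspring replaces its archive partner only when it
p-Nash ascends it.  Diversity comes from temporarily running on a
degree-preserving random rewiring of the network, and the final answer is
the archive member with the highest modularity `Q` on the original network
(modularity selects the output; it never guides the search).

## Worked example

The 7-node network with edges
`1-2 1-3 2-3 3-4 4-5 4-6 4-7 5-6 5-7 6-7` has a triangle `{1,2,3}` bridged
to a near-clique `{4,5,6,7}`:

```python
import numpy as np
from pmneo import (CommunityGame, EOParams, GNParams, PlayerSubset,
                   community_fitness, generate_gn, k_operator, nmi,
                   p_nash_compare, run_pmneo)
from pmneo.community import improving_players
from pmneo.datasets import toy_network

net = toy_network()
game = CommunityGame(net)
s = np.array([1, 1, 1, 2, 2, 2, 2])   # triangle {1,2,3} vs cluster {4,5,6,7}
q = np.array([1, 1, 2, 2, 2, 2, 1])   # nodes 3 and 7 swapped across the bridge

print("f({1,2,3})      =", community_fitness({0, 1, 2}, net))
print("f({4,5,6,7})    =", community_fitness({3, 4, 5, 6}, net))
print("k(s, q), k(q, s) =", k_operator(s, q, game), k_operator(q, s, game))
r = p_nash_compare(s, q, PlayerSubset((0, 2, 4)), game)
print("reduced counts  =", (r.k_forward, r.k_backward), "->", r.verdict)

rng = np.random.default_rng(0)
network, truth = generate_gn(GNParams(z_out=3), rng)
params = EOParams(pop_size=50, max_gen=500, p=0.25, c_min=2, c_max=8,
                  pinned_count=4)
result = run_pmneo(network, params, rng, track_history=False)
print("NMI vs planted  =", nmi(result.labels, truth))
print("modularity Q    =", round(result.modularity, 4))
print("improving nodes =", len(improving_players(result.labels, network)))
```

prints

```
f({1,2,3})      = 0.8571428571428571
f({4,5,6,7})    = 0.9230769230769231
k(s, q), k(q, s) = 0 2
reduced counts  = (0, 1) -> ascends
NMI vs planted  = 1.0
modularity Q    = 0.5647
improving nodes = 0
```

Reading the numbers: the natural split `s` keeps 6/7 and 12/13 of each
community's degree internal; no player gains by deviating from `s` towards
`q` (`k(s,q) = 0`) while two players (nodes 3 and 7) would gain by moving
back (`k(q,s) = 2`), so `s` Nash-ascends `q` — and the reduced comparison
over the subset `{1, 3, 5}` reaches the same verdict from a single payoff
comparison.  On a 128-node planted-partition benchmark (four communities of
32, degree 16, three inter-community links per node) the search recovers
the planted structure exactly (NMI 1) and the result is a Nash equilibrium:
zero nodes can improve by switching community.

The same runs are available from the shell:

```
pmneo gn --zout 3 --seed 0 --out net.txt --truth truth.txt
pmneo detect --network net.txt --p 0.25 --pop 50 --maxgen 500 \
             --cmin 2 --cmax 8 --pinned-count 4 --seed 0 \
             --out part.txt --truth truth.txt
pmneo eval --network net.txt --pred part.txt --truth truth.txt
pmneo cournot --n 10 --a 24 --c 9 --p 0.25 --maxgen 2000 --seed 1 --out trace.tsv
```

The `cournot` subcommand runs the no-mixing variant on a Cournot oligopoly
(linear demand `P(Q) = a − Q`, constant marginal cost `c`), whose analytic
equilibrium `q_i = (a − c)/(n + 1)` provides an exact distance measure for
convergence studies; the trace file lists distance-to-equilibrium per
generation.

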