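# Methods

## The community game

Given an undirected simple graph `G = (V, E)` with `n = |V|` nodes and `m`
edges, each node chooses a community label; a label vector
`s = (C_1, …, C_n)` is simultaneously a strategy profile of an `n`-player
game and a partition of `V`.  Node `i`'s payoff is its marginal
contribution to the fitness of its community `C` (`C_i = w`):

    u_i(s) = f(C ∪ {i}) − f(C \ {i}),
    f(C)   = Σ_{j∈C} k_in(j) / ( Σ_{j∈C} (k_in(j) + k_out(j)) )^α .

`α > 0` (default 1, the only value exercised here) discourages large
communities for `α > 1` and rewards them for `α < 1`.  Since
`k_in + k_out = deg`, for `α = 1` the fitness is the internally retained
fraction of the community's degree, bounded by [0, 1] and equal to 1
exactly on unions of whole connected components.  Conventions for the
degenerate cases the payoff difference can reach: `f(∅) = 0` and `f` of any
set with zero total degree is 0 (the numerator vanishes first; this is the
continuous limit).  With these conventions a node alone in its community
has payoff 0, which also makes "open a fresh community" a well-defined
deviation whose payoff is always 0.

Payoff evaluation is incremental: per-community aggregates
`(Σ k_in, Σ deg)` make a single-node move O(deg(i)), and whole-profile
payoff vectors are computed in one O(n + m) vectorised sweep.  Payoff
comparisons are exact floating point — payoffs are ratios of small
integers and an epsilon would silently change the ascendancy counts.

## Nash ascendancy and its reduced form

The quality operator `k(s, q) = card{ i : u_i(s) ≤ u_i(q_i, s_−i),
s_i ≠ q_i }` counts players that would not lose by unilaterally switching
from `s` toward `q`; `s` *ascends* `q` iff `k(s,q) < k(q,s)`.  The reduced
operator `k_p` restricts the count to a subset `I_p` of `n_p = [p·n]`
players (`n_p > 0` required), drawn fresh for every comparison.  Summed
over all subsets of size `n_p`, reduced counts are proportional to the full
ones (each counted player lies in `C(n−1, n_p−1)` subsets), which is why
equilibria are exactly the profiles never ascended under either relation;
the test suite verifies the proportionality identities by exhaustive subset
enumeration on games with up to six players, and verifies on brute-forced
small games that equilibria are never p-ascended.

Two deliberately exposed choices:

* **Tie semantics.**  The defining count uses `≤` (ties counted); the
  pseudocode formulation of the comparison loop uses strict `<`.  Default
  is `≤`, on which the proportionality identities rest; `tie_mode="strict"`
  reproduces the literal loop.
* **Subset sampling.**  Default is without replacement (a subset is a set,
  as the identities require); `subset_with_replacement=True` reproduces the
  reading in which the same player can be drawn twice and then counts with
  multiplicity.

Within one profile comparison a single subset is drawn and used for both
directed counts (one pass), and payoffs are only evaluated at positions
where the two profiles differ — the source of the evaluation savings that
motivates the reduced relation.

## The search (pMNEO)

Extremal optimization over a population `P` and archive `A`, both of size
`M` (default 50).  Each individual fixes a community budget drawn uniformly
from `[c_min, c_max]`; when a believed community count is supplied
(`pinned_count`), a `pinned_fraction` (default 25%) of individuals use it
instead.  Per generation and individual: the `ℓ` lowest-payoff nodes (ties
broken uniformly at random — payoffs coincide often on regular graphs) are
each reassigned a random *different* label within the budget; the offspring
replaces the archive partner only if it p-Nash ascends it, and always
replaces the explorer.

The mutation size decays linearly, `ℓ = max(1, round(0.1·n·(1 −
NrGen/MaxGen)))` — large early moves, single-node refinement late.  The
printed source for this schedule is typographically corrupted; the leading
`n/10` factor and the `max{1, ·}` floor are preserved and the schedule is
injectable (`EOParams.ell`) for experimentation.

Diversity mechanism: after every `Λ` generations (default 30) on the
original network the search runs `λ` generations (default 10) on a mixed
network obtained by `round(ρ·m)` degree-preserving double-edge-swap
attempts (`ρ = 0.02`; swaps creating self-loops or duplicate edges are
rejected, so degrees are preserved exactly and complete graphs are
unmixable).  At every phase switch the archive is randomly re-initialised
and all cached payoffs are recomputed on the newly active network; the
population is kept (it carries the structure across the perturbation).  The
final answer is the archive member with the highest modularity

    Q = (1/2m) Σ_ij (A_ij − d_i d_j / 2m) δ(C_i, C_j)

computed on the *original* network (ordered pairs including `i = j`, the
standard convention under which published benchmark values are computed).
Modularity is never used to guide the search.  No archive restart is
performed after the final generation, so the reported archive always
reflects search effort.

The payoff-evaluation counter increments by four per tested differing
player inside the ascendancy procedure (two payoffs per direction),
independent of caching, so counts are comparable across `p` values.

## Cournot benchmark

`n` firms choose quantities in `[0, 10]`; price `P(Q) = max(a − Q, 0)`,
profit `u_i = q_i P(Q) − c q_i`, unique symmetric equilibrium
`q_i = (a − c)/(n + 1)`.  Defaults `a = 24`, `c = 9` give `q_i = 15/11` at
`n = 10`.  The continuous-strategy variant (`run_pmneo_minus`) drops the
mixing phases (there is no network) and mutates the `ℓ` lowest-profit
firms with fresh uniform draws from the strategy box; a Gaussian
perturbation is available behind a flag (`mutation="gaussian"`,
`sigma` defaulting to a tenth of the box width).  The per-generation trace
records the Euclidean distance of the closest archive member to the
analytic equilibrium; the returned profile is that closest member (an
acceptable convention only because the equilibrium is known — this is a
benchmark, not an application mode).

## Synthetic benchmark generator

The planted-partition family: 128 nodes, four planted communities of 32,
expected degree 16, `z_out ∈ {1..8}` expected inter-community links per
node.  Realised as independent Bernoulli edges with `p_in = (16 − z_out)/31`
and `p_out = z_out/96`, which reproduces the degree expectations; degrees
therefore fluctuate binomially around 16 rather than being exactly 16, and
generated graphs may (rarely, at small `z_out`) be disconnected.  These are
the standard properties of the independent-edge realisation; exact-degree
rewired variants are intentionally out of scope.  What recovery on this
family demonstrates: the search finds planted structure when communities
are dense and balanced; it does not by itself say anything about networks
with heterogeneous degrees or community sizes (externally generated
benchmarks of that kind can be read through the edge-list reader).

Partitions are scored with normalised mutual information computed from the
confusion matrix, normalised by the mean of the two entropies (max-entropy
normalisation behind a flag); two all-one-community partitions score 1 by
convention.  Batch equilibrium summaries report mean ± sample standard
deviation, minimum and normal-approximation 95% confidence limits of the
mean.  Wilcoxon rank-sum comparisons are delegated to scipy.

## Default problem sizes

Library defaults are the standard study conditions (`M = 50`, `ρ = 0.02`,
`Λ = 30`, `λ = 10`, `p = 0.25`).  The test suite and the acceptance script
run the 128-node benchmark at `MaxGen = 500` with `c_min = 2`, `c_max = 8`
and `pinned_count = 4` — at `z_out = 3` the planted structure is recovered
exactly (NMI 1, zero improving nodes) well within this budget, and a run
takes a few seconds — and the Cournot benchmark at `n = 10`, `MaxGen =
2000` with 10 individuals.  These are the package's chosen desk-scale
presets; nothing prevents running the full-scale settings (`MaxGen` up to
10^4, thousands of nodes) through the same interfaces.

## Known limitations

* The archive-update dynamics depend mildly but systematically on `p` in
  the continuous Cournot setting: smaller subsets accept partial
  improvements more often, so the archive explores more and attains a
  slightly lower minimum distance to equilibrium (≈0.403 at `p = 0.25` vs
  ≈0.409 at `p = 1` over 2000 generations at `n = 10`; both are a ~30-fold
  reduction from initialisation).  The difference is scientifically
  negligible but statistically detectable, because the within-run spread of
  a minimum-over-2000-generations statistic is tiny (sd ≈ 0.004): pairwise
  rank-sum tests at 10 runs flag the `p = 1` contrasts.  The corresponding
  acceptance check is left failing rather than masked; see the distance
  traces from `pmneo cournot` to judge the effect directly.
* The equilibrium-verification deviation set (labels present plus one
  fresh community) covers all materially distinct single moves given the
  current partition, not moves into communities that exist only in other
  individuals' encodings.
* `α ≠ 1` is implemented but untuned and untested beyond unit level;
  weighted, directed and overlapping-community variants are out of scope.
* Runs are single-threaded and reproducible from `(seed, params)`; there
  is no parallel population evaluation.
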