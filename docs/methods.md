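# Methods

## Model and procedure

The detector partitions a simple undirected graph `G = (V, E)` into a
user-supplied number `K` of communities. `K` is an input, never
estimated: the method addresses initialisation and clustering, not model
selection.

**Node density.** For hop count `h`, the BFS ball of `v` is the set of
nodes at shortest-path distance ≤ `h` from `v`, including `v` itself.
With `V'` the ball and `E'` the edges of its induced subgraph, the node
density is `|E'| / (|V'|(|V'|−1)/2)` — the edge density of the ball,
in `[0, 1]`. The motivating identity is informational: a node whose
ball lies inside one community has zero Shannon entropy of community
belongingness, and ball density is a proxy for that certainty which is
computable *before* any communities are known. A ball with a single
node (isolated node) gets density 0 by convention, so isolated nodes
have `DD = density × degree = 0` and cannot outrank any connected node
in seeding.

**Seed selection.** Nodes are ranked by `DD` descending (ties by
ascending node id). The first seed is the top of the ranking. Each
subsequent seed is chosen by computing, for every remaining candidate
`p`, the mean entry `R_p` of the correlation matrix
`DDJ = (D Dᵀ) ∘ Jaccard(G)` between `p` and the current seeds; the
candidates attaining the minimal `R_p` form a tie set, from which the
maximum-DD node (ties again by ascending id) is added. Zero correlation
is a legitimate minimum — it is exactly what drives seeds into
different connected components or far-apart communities.

One guard departs from the plain loop: candidates are restricted to
`DD > 0` nodes while any remain. Without it, isolated nodes — whose
correlation to every seed is exactly zero — would alone form the
minimal tie set and be seeded despite their zero DD, the opposite of the
scheme's intent. `DD > 0` coincides exactly with "non-isolated", so the
guard changes nothing on graphs without isolated nodes; isolated nodes
become eligible only when `K` exceeds the number of connected nodes.

**Clustering.** Feature vector of node `i` = row `i` of the Jaccard
matrix (raw, no normalisation; diagonal set to 1 so every node is
maximally similar to itself). Lloyd iterations with Euclidean distance:
assign each row to the nearest centroid (ties to the lowest cluster
index), recompute centroids as member-row means, repeat. Stopping: the
assignment is unchanged between consecutive iterations, or the maximal
centroid displacement (`MaxDist`) falls below `tol`, or `max_iter` is
reached. An empty cluster is repaired deterministically by reseeding
its centroid at the row of the node farthest from its current centroid,
so the output always has exactly `K` non-empty blocks.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `h` | 3 | BFS radius for density; beyond the typical small-world distance scale, larger `h` saturates balls to whole components and erases the density signal |
| `max_iter` | 100 | k-means iteration cap; observed convergence is nearly always below 20 iterations on the benchmark families |
| `tol` | 1e-9 | `MaxDist` threshold; effectively "assignment fixed" at double precision |
| `K` | — | number of communities, required |

## Evaluation metrics

NMI is computed from the confusion matrix in the ratio form whose log
base cancels; natural logs are used. The degenerate case (both
partitions a single block, denominator 0) is defined as 1 — two trivial
partitions of the same node set are identical — with a logged warning.
The bidirectional F1 matches each reference community to its best
harmonic-mean precision/recall partner among the detected communities
and averages the two directional means; zero-overlap pairs contribute 0.
NMI is cross-checked in the test suite against scikit-learn's
implementation (arithmetic normalisation, which equals the confusion
form above) to 1e-9.

## Synthetic benchmarks

`generate_lfr` emulates LFR-style benchmarks: degrees from a discrete
power law with exponent τ₁ truncated to `[kmin, kmax]`, with `kmin`
solved numerically so that the expected mean degree matches `⟨k⟩`
(fractional cutoff, floored sampling); community sizes from a power law
with exponent τ₂ truncated to `[cmin, cmax]` (τ₂ = 1 is proper on the
truncated domain), tiled to sum exactly to `n` by shaving oversampled
sizes down to `cmin`; each node splits its degree into an internal part
`(1−μ)k` (stochastic rounding) and an external part. Nodes are placed
into communities largest-internal-degree first under the constraint
`d_int ≤ size − 1`, capping `d_int` when no community can host it.
Internal edges realise each community's degree sequence exactly via
Havel–Hakimi construction randomised by double-edge swaps (≈5 per edge);
external stubs are matched globally with rejection of self, intra-
community and duplicate pairs over bounded re-shuffling passes, and a
residual of unmatched stubs is dropped. At μ = 0 no external matching
runs at all, so every edge is intra-community by construction.

What this generator does *not* reproduce: the original LFR program's
exact rewiring schedule, hence no bit-level equivalence with graphs from
that program; degree-community correlations beyond the size constraint;
overlapping or weighted variants. Realised mixing (node-averaged
external-edge fraction) and realised mean degree are attached to every
instance; across the parameter ranges used here they track the targets
within a few percent. Passing benchmark results therefore show that the
detector works on graphs with heterogeneous power-law degree and
community-size structure at a given mixing — not that it reproduces any
particular published graph instance, and not that it performs equally on
real networks, whose degree correlations, clustering and community
shapes differ from any generator.

`generate_planted_partition` (equal blocks, Bernoulli `p_in`/`p_out`)
and `ring_of_cliques` (deterministic cliques with single bridges) are
small controllable fixtures for unit and recovery tests.

## Numerical and design choices

- **Neighbourhoods in Jaccard:** open (a node is not its own
  neighbour); the diagonal is forced to 1. The diagonal choice shifts
  all feature vectors uniformly and does not affect relative distances.
- **Density at `|V'| ≤ 1`:** 0 (degenerate-input convention, see above).
- **Entropy:** base-2 logs, `0·log 0 := 0`.
- **Canonical node order:** sorted node ids; every matrix row order,
  ranking tie-break and "lowest id" rule refers to this order, so
  results are invariant to input-file line order.
- **Bulk density computation:** an iterative CSR-based BFS per source
  node (numba-compiled) returning ball sizes and internal edge counts;
  a boolean matrix-power fallback exists, and both are tested against
  the explicit per-node BFS reference.
- **Determinism:** the detector contains no randomness whatsoever; the
  generators and the random-init baseline take explicit integer seeds.

## Benchmark problem sizes

The replication sweep in the acceptance script uses the 5000-node
family (τ₁ = 2, τ₂ = 1, sizes 20–100, `⟨k⟩` = 15, `kmax` = 75,
≈ 100 planted communities) with five replicate instances per mixing
value μ ∈ {0.1, …, 0.5}, and the test suite adds the 1000-node family
(sizes 20–50, `⟨k⟩` = 20) for the baseline comparison at μ ≤ 0.6 (ten
replicates) and the degradation sweep at μ ∈ {0.6, …, 0.9} (six
replicates). Five-replicate means on the 5000-node family have a
standard error of roughly 0.005–0.01 NMI, comfortably inside the
stochastic tolerances the acceptance checks use.

## Known limitations

- `K` must be supplied; a wrong `K` forces splits or merges and the
  method offers no goodness-of-`K` diagnostic beyond inertia.
- The Jaccard feature space is `n`-dimensional; memory is fine for the
  sparse matrix, but dense centroids cost `K × n` doubles, which limits
  very large `K · n` products.
- Radius-`h` density assumes communities are locally dense at scale
  `h`; elongated or very small communities (size ≲ 4) blur at `h = 3`.
- At high mixing (μ > 0.6) accuracy degrades quickly — an inherent
  property of the regime, reproduced rather than solved here.
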