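# ddjkm — density-degree seeded k-means community detection

`ddjkm` detects communities in undirected, unweighted networks with a
k-means clustering whose initial centers are chosen deterministically
instead of at random. It is aimed at anyone partitioning an interaction
network — protein interaction maps, co-expression graphs, social or
collaboration networks — into a known number `K` of communities, and at
anyone benchmarking such methods: the package ships the evaluation
metrics (NMI, bidirectional F1) and an LFR-style benchmark generator
alongside the detector.

## The method

For a graph `G = (V, E)` with `n = |V|` nodes, the method builds on three
per-node quantities:

- **node density** `Density(v) = |E'| / (|V'|(|V'|−1)/2)`, the edge
  density of the subgraph induced by the `h`-hop BFS ball of `v`
  (the ball includes `v`; `h = 3` by default). A node buried inside one
  community has a dense ball; a node straddling communities does not.
  Density quantifies the certainty of a node's community belongingness —
  formally, low density corresponds to high Shannon entropy of the
  ball's distribution over communities.
- **DD score** `DD(v) = Density(v) × Degree(v)`, which balances that
  certainty against degree centrality. Isolated nodes have `DD = 0`.
- **Jaccard similarity** `JacSim(u, v) = |N(u) ∩ N(v)| / |N(u) ∪ N(v)|`
  of neighbourhoods, assembled into the `n × n` matrix `Jaccard(G)`
  whose rows are the clustering feature vectors.

Seeding picks the maximum-DD node first, then repeatedly adds the
candidate minimising the average correlation to the current seeds in
`DDJ(G) = (D Dᵀ) ∘ Jaccard(G)` (ties: maximal DD, then lowest node id) —
spreading the `K` initial centers across structurally dissimilar, dense
regions. Standard k-means then runs on the Jaccard rows (Euclidean
distance, centroid = mean member row) until the assignment stabilises or
an iteration cap (default 100) is reached. The whole pipeline is
deterministic: the same graph and `K` always give the same partition.

## Worked example

```python
from ddjkm import DDJKM, ring_of_cliques

inst = ring_of_cliques(3, 5)          # 3 five-cliques joined by bridges
res = DDJKM(inst.graph, n_communities=3).fit()
print(res.summary(truth=inst.partition))
```

prints

```
DDJKM community detection results
========================================
method:            ddjkm
nodes, edges:      15, 33
communities (K):   3
hops (h):          3
iterations:        1 (converged: True)
final MaxDist:     5.523e-01
inertia:           3.21422
seed nodes:        [0, 6, 10]
community sizes:   min 5, median 5, max 5
NMI vs truth:      1.0000
F1 vs truth:       1.0000
```

One seed lands in each clique (nodes 0, 6 and 10 sit in the three
different cliques), k-means converges immediately, and the planted
three-clique partition is recovered exactly (NMI = F1 = 1).

The same pipeline is available from the shell:

```sh
ddjkm generate --model lfr --n 1000 --mu 0.2 --seed 4 --out bench
ddjkm detect --graph bench.edgelist --k 32 --out pred.tsv
ddjkm eval --truth bench.truth.tsv --pred pred.tsv
ddjkm benchmark --out sweep.tsv --seed 2 --n 1000 --replicates 5 --baseline
```

Each writing command also emits a JSON manifest sufficient to reproduce
the run.

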