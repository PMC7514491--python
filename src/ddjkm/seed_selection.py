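"""Deterministic selection of the K initial cluster centers.

The first seed is the node with the globally maximal DD score
(density x degree).  Each subsequent seed is picked by a spreading
rule: among all non-seed nodes, find those whose average correlation
to the current seeds -- read from the DDJ matrix -- is minimal, and of
those take the one with the largest DD score.  Zero correlation (e.g.
a candidate in a different component from every seed) is a valid and
winning average, which is what pushes seeds into distinct communities.

All ties break by ascending node id, making the procedure fully
deterministic: no randomness enters anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, List, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .graph_core import canonical_node_order
from .node_measures import dd_vector, ddj_matrix, density_vector, jaccard_matrix

__all__ = ["SeedSet", "dd_sequence", "average_correlation", "select_seeds"]


@dataclass(frozen=True)
class SeedSet:
    """Ordered list of the chosen initial-center node ids."""

    nodes: tuple
    k: int

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("seed set contains duplicates")
        if len(self.nodes) != self.k:
            raise ValueError("seed set size differs from K")

    def __iter__(self):
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    def __getitem__(self, i: int):
        return self.nodes[i]


def dd_sequence(G: nx.Graph, h: int, order: Sequence[Hashable] | None = None) -> List[Hashable]:
    """All nodes sorted by DD score descending, ties by ascending node id."""
    if order is None:
        order = canonical_node_order(G)
    dd = dd_vector(G, h, order)
    # order is sorted ascending, so a stable sort on -dd realises the tie-break
    idx = np.argsort(-dd, kind="stable")
    return [order[i] for i in idx]


def average_correlation(
    DDJ: sp.spmatrix, seed_indices: Sequence[int], p: int
) -> float:
    """Mean DDJ correlation between candidate index ``p`` and the seeds."""
    if len(seed_indices) == 0:
        raise ValueError("seed set is empty")
    col = DDJ[:, p]
    return float(sum(col[q, 0] for q in seed_indices)) / len(seed_indices)


def _select_seed_indices(
    dd: np.ndarray, DDJ: sp.csr_matrix, K: int
) -> List[int]:
    """Core selection loop over positional indices (canonical order)."""
    n = dd.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    # first seed: max DD, ties to the lowest index
    first = int(np.lexsort((np.arange(n), -dd))[0])
    seeds = [first]
    in_seed = np.zeros(n, dtype=bool)
    in_seed[first] = True
    # running column sum of DDJ over the seed rows; DDJ is symmetric so
    # row extraction serves for columns
    corr_sum = np.asarray(DDJ.getrow(first).todense()).ravel()
    # DD > 0 exactly characterises non-isolated nodes (degree > 0 forces a
    # ball with >= 2 nodes and >= 1 edge, hence positive density); isolated
    # nodes are only eligible once every connected candidate is used up,
    # which keeps them out of the seed set whenever K allows it
    eligible = dd > 0
    while len(seeds) < K:
        r = corr_sum / len(seeds)
        r[in_seed] = np.inf
        if np.any(eligible & ~in_seed):
            r[~eligible] = np.inf
        min_r = r.min()
        candidates = np.flatnonzero(r == min_r)
        # max-DD member of the minimal set; ties by ascending index
        best = int(candidates[np.lexsort((candidates, -dd[candidates]))[0]])
        seeds.append(best)
        in_seed[best] = True
        corr_sum += np.asarray(DDJ.getrow(best).todense()).ravel()
    return seeds


def select_seeds(
    G: nx.Graph,
    K: int,
    h: int = 3,
    *,
    order: Sequence[Hashable] | None = None,
    J: sp.spmatrix | None = None,
    D: np.ndarray | None = None,
) -> SeedSet:
    """Choose the K initial cluster centers for a graph.

    Parameters
    ----------
    G
        Simple undirected graph.
    K
        Number of communities / seeds, ``1 <= K <= |V|``.
    h
        BFS hop count for node density (default 3).
    order, J, D
        Optional precomputed canonical node order, Jaccard matrix and
        density vector, to avoid recomputation inside the pipeline.
    """
    if order is None:
        order = canonical_node_order(G)
    if D is None:
        D = density_vector(G, h, order)
    if J is None:
        J = jaccard_matrix(G, order)
    degs = np.array([G.degree(v) for v in order], dtype=float)
    dd = D * degs
    DDJ = ddj_matrix(D, J)
    idx = _select_seed_indices(dd, DDJ, K)
    return SeedSet(tuple(order[i] for i in idx), K)
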