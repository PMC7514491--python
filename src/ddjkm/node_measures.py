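"""Per-node structural measures and the matrices built from them.

The measures come in two layers:

* per-node reference functions (``density``, ``uncertainty``,
  ``jaccard_similarity``, ...) built on explicit BFS balls -- clear,
  slow, used for small graphs and as ground truth in tests;
* vectorised whole-graph computations (``density_vector``,
  ``jaccard_matrix``, ``ddj_matrix``) built on a CSR adjacency
  representation, used by the detection pipeline on benchmark-sized
  networks.

Central quantities
------------------
For a node ``v`` and hop count ``h``, let ``S`` be the BFS ball
(all nodes within distance ``h``, including ``v``) and ``G'`` its
induced subgraph with ``|V'|`` nodes and ``|E'|`` edges.

* node density:  ``|E'| / (|V'| (|V'|-1) / 2)`` -- the edge density of
  the ball; 0 by convention when the ball has a single node.
* DD score: ``density(v) * degree(v)`` -- the seed-ranking criterion
  balancing centrality against community-belongingness certainty.
* Jaccard similarity of two nodes: shared neighbours over union of
  neighbourhoods (open neighbourhoods; the self-pair is defined as 1).
"""

from __future__ import annotations

import math
from typing import Hashable, List, Sequence, Tuple

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .graph_core import Partition, bfs_ball, canonical_node_order, induced_subgraph

__all__ = [
    "membership_distribution",
    "uncertainty",
    "density",
    "degree",
    "dd_score",
    "density_vector",
    "dd_vector",
    "jaccard_similarity",
    "jaccard_matrix",
    "ddj_matrix",
    "adjacency_csr",
    "measure_table",
]


# ---------------------------------------------------------------------------
# per-node reference layer
# ---------------------------------------------------------------------------

def membership_distribution(
    G: nx.Graph, v: Hashable, h: int, P: Partition
) -> Tuple[np.ndarray, List[Hashable]]:
    """Distribution of a node's h-hop ball over the communities of ``P``.

    Returns ``(p, labels)`` where ``p[q]`` is the fraction of ball
    members carrying ``labels[q]``; the components sum to 1.  Labels
    are all communities of ``P`` in sorted order, so communities the
    ball never touches contribute explicit zeros.
    """
    if not P.covers(G):
        raise ValueError("partition does not cover the graph")
    ball = bfs_ball(G, v, h)
    labels = sorted(set(P.assignment.values()), key=repr)
    index = {lab: q for q, lab in enumerate(labels)}
    counts = np.zeros(len(labels))
    for u in ball:
        counts[index[P[u]]] += 1
    return counts / len(ball), labels


def uncertainty(G: nx.Graph, v: Hashable, h: int, P: Partition) -> float:
    """Community-belongingness uncertainty: base-2 Shannon entropy of the
    ball membership distribution.  ``0 log 0`` is taken as 0; the value
    lies in ``[0, log2(number of communities)]``.
    """
    p, _ = membership_distribution(G, v, h, P)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)) + 0.0)  # +0.0 avoids -0.0


def density(G: nx.Graph, v: Hashable, h: int) -> float:
    """Edge density of the induced subgraph of the h-hop BFS ball of ``v``."""
    if h < 1:
        raise ValueError("density requires h >= 1")
    ball = bfs_ball(G, v, h)
    n = len(ball)
    if n <= 1:
        return 0.0  # isolated-node convention
    m = induced_subgraph(G, ball).number_of_edges()
    return m / (n * (n - 1) / 2)


def degree(G: nx.Graph, v: Hashable) -> int:
    return int(G.degree(v))


def dd_score(G: nx.Graph, v: Hashable, h: int) -> float:
    """Density-degree balance score ``density(v) * degree(v)``.

    Isolated nodes score 0 and therefore never win a seed-selection
    round against any node with positive density and degree.
    """
    return density(G, v, h) * G.degree(v)


# ---------------------------------------------------------------------------
# vectorised whole-graph layer
# ---------------------------------------------------------------------------

def adjacency_csr(G: nx.Graph, order: Sequence[Hashable] | None = None) -> sp.csr_matrix:
    """Boolean CSR adjacency in canonical (sorted) node order."""
    if order is None:
        order = canonical_node_order(G)
    A = nx.to_scipy_sparse_array(G, nodelist=list(order), weight=None, format="csr")
    A = sp.csr_matrix(A, dtype=np.float64)
    return A


try:  # pragma: no cover - exercised indirectly through density_vector
    from numba import njit

    @njit(cache=True)
    def _ball_stats(indptr, indices, h, n):
        """Per-node (ball size, internal edge count) via iterative BFS.

        For each source, runs an h-bounded BFS over the CSR structure,
        then counts adjacency pairs internal to the ball; each internal
        edge is seen from both endpoints, hence the final halving.
        """
        sizes = np.zeros(n, dtype=np.int64)
        edges = np.zeros(n, dtype=np.int64)
        mark = np.full(n, -1, dtype=np.int64)
        queue = np.empty(n, dtype=np.int64)
        dist = np.zeros(n, dtype=np.int64)  # entries valid only for current ball
        for s in range(n):
            head = 0
            tail = 0
            queue[tail] = s
            tail += 1
            mark[s] = s
            dist[s] = 0
            while head < tail:
                u = queue[head]
                head += 1
                if dist[u] == h:
                    continue
                for ptr in range(indptr[u], indptr[u + 1]):
                    w = indices[ptr]
                    if mark[w] != s:
                        mark[w] = s
                        dist[w] = dist[u] + 1
                        queue[tail] = w
                        tail += 1
            sizes[s] = tail
            cnt = 0
            for qi in range(tail):
                u = queue[qi]
                for ptr in range(indptr[u], indptr[u + 1]):
                    if mark[indices[ptr]] == s:
                        cnt += 1
            edges[s] = cnt // 2
        return sizes, edges

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _ball_stats_python(A: sp.csr_matrix, h: int) -> Tuple[np.ndarray, np.ndarray]:
    """Sparse-matrix fallback: reachability within h hops by boolean powers."""
    n = A.shape[0]
    B = (A + sp.identity(n, format="csr")).astype(bool).astype(np.float64)
    R = B.copy()
    for _ in range(h - 1):
        R = (R @ B).astype(bool).astype(np.float64)
    sizes = np.asarray(R.sum(axis=1)).ravel().astype(np.int64)
    inner = R.multiply(R @ A)  # (i,j) -> #ball(i) neighbours of j, j in ball(i)
    edges = (np.asarray(inner.sum(axis=1)).ravel() / 2).astype(np.int64)
    return sizes, edges


def density_vector(
    G: nx.Graph, h: int, order: Sequence[Hashable] | None = None
) -> np.ndarray:
    """Node densities for every node, in canonical node order."""
    if h < 1:
        raise ValueError("density requires h >= 1")
    if order is None:
        order = canonical_node_order(G)
    A = adjacency_csr(G, order)
    n = A.shape[0]
    if n == 0:
        return np.zeros(0)
    if _HAVE_NUMBA:
        sizes, edges = _ball_stats(A.indptr, A.indices.astype(np.int64), h, n)
    else:
        sizes, edges = _ball_stats_python(A, h)
    dens = np.zeros(n)
    big = sizes > 1
    dens[big] = edges[big] / (sizes[big] * (sizes[big] - 1) / 2)
    return dens


def dd_vector(
    G: nx.Graph, h: int, order: Sequence[Hashable] | None = None
) -> np.ndarray:
    """DD scores (density x degree) for every node, canonical order."""
    if order is None:
        order = canonical_node_order(G)
    degs = np.array([G.degree(v) for v in order], dtype=float)
    return density_vector(G, h, order) * degs


def jaccard_similarity(G: nx.Graph, a: Hashable, b: Hashable) -> float:
    """Neighbourhood Jaccard index of two nodes.

    Open neighbourhoods (a node is not its own neighbour); the self-pair
    is 1 by definition, and two distinct nodes with empty neighbourhoods
    score 0.
    """
    if a not in G or b not in G:
        raise KeyError("both nodes must be in the graph")
    if a == b:
        return 1.0
    Na, Nb = set(G[a]), set(G[b])
    union = Na | Nb
    if not union:
        return 0.0
    return len(Na & Nb) / len(union)


def jaccard_matrix(
    G: nx.Graph, order: Sequence[Hashable] | None = None
) -> sp.csr_matrix:
    """The n x n node-similarity matrix ``J[i, j] = JacSim(v_i, v_j)``.

    Rows of this matrix are the feature vectors the k-means stage
    clusters.  Stored sparse: ``J[i, j]`` is non-zero only for the
    diagonal and for pairs sharing at least one neighbour.
    """
    if order is None:
        order = canonical_node_order(G)
    A = adjacency_csr(G, order)
    n = A.shape[0]
    common = (A @ A).tocoo()  # (i,j) -> |N(i) ∩ N(j)|
    deg = np.asarray(A.sum(axis=1)).ravel()
    mask = (common.row != common.col) & (common.data > 0)
    i, j, c = common.row[mask], common.col[mask], common.data[mask]
    union = deg[i] + deg[j] - c
    vals = c / union
    J = sp.coo_matrix((vals, (i, j)), shape=(n, n)).tocsr()
    J = J + sp.identity(n, format="csr")
    return J.tocsr()


def ddj_matrix(D: np.ndarray, J: sp.spmatrix) -> sp.csr_matrix:
    """Seed-correlation matrix: Hadamard product of the density outer
    product with the Jaccard matrix, ``DDJ[i, j] = D[i] D[j] J[i, j]``.

    High entries mark node pairs that are both individually dense and
    structurally similar -- exactly the pairs that should not both
    become initial cluster centers.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if J.shape != (n, n):
        raise ValueError(f"dimension mismatch: D has {n}, J is {J.shape}")
    S = sp.diags(D)
    return (S @ J @ S).tocsr()


def write_matrix_coo(M: sp.spmatrix, path) -> None:
    """Write a sparse matrix as 'i j value' coordinate-format text."""
    coo = sp.coo_matrix(M)
    idx = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        fh.write(f"# {coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        for i, j, v in zip(coo.row[idx], coo.col[idx], coo.data[idx]):
            fh.write(f"{i} {j} {v:.12g}\n")


def measure_table(G: nx.Graph, h: int) -> "pandas.DataFrame":  # noqa: F821
    """Per-node measures as a DataFrame: node_id, degree, density, dd."""
    import pandas as pd

    order = canonical_node_order(G)
    dens = density_vector(G, h, order)
    degs = np.array([G.degree(v) for v in order], dtype=float)
    return pd.DataFrame(
        {"node_id": order, "degree": degs.astype(int), "density": dens, "dd": dens * degs}
    )
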