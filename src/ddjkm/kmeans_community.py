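"""K-means clustering over Jaccard-row feature vectors.

Each node's feature vector is its row of the n x n Jaccard similarity
matrix, so two nodes are close when they relate to the *rest of the
network* in the same way.  Cluster centers are initialised at the rows
of the selected seed nodes, then standard Lloyd iterations run:
assign every node to its nearest centroid (Euclidean distance on the
rows), recompute each centroid as the mean of its members' rows, and
stop when the assignment stabilises, the maximal centroid displacement
(MaxDist) falls below ``tol``, or the iteration cap is hit.

An empty cluster, should one arise, is repaired deterministically by
reseeding its centroid at the row of the node currently farthest from
its assigned centroid, so the output always has exactly K non-empty
blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, List, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .graph_core import Partition, canonical_node_order
from .node_measures import density_vector, jaccard_matrix
from .seed_selection import SeedSet, select_seeds

__all__ = [
    "ClusteringResult",
    "jaccard_row_distance",
    "assign_clusters",
    "update_centroids",
    "kmeans_cluster",
    "ddjkm_detect",
    "random_init_kmeans",
]

DEFAULT_HOPS = 3
DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-9


@dataclass
class ClusteringResult:
    """Outcome of a community-detection run."""

    partition: Partition
    iterations: int
    converged: bool
    seeds: tuple
    max_dist: float
    inertia: float
    max_dist_trace: List[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.partition.k


def jaccard_row_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two similarity-row vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def _distance_sq_matrix(X: sp.csr_matrix, C: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between sparse rows and dense centroids."""
    x_sq = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    c_sq = np.einsum("ij,ij->i", C, C)
    cross = X @ C.T
    d2 = x_sq[:, None] - 2 * np.asarray(cross) + c_sq[None, :]
    np.maximum(d2, 0.0, out=d2)
    return d2


def _assign(X: sp.csr_matrix, C: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels; equidistant ties go to the lowest index."""
    return np.argmin(_distance_sq_matrix(X, C), axis=1)


def assign_clusters(
    J: sp.spmatrix, C: np.ndarray, order: Sequence[Hashable]
) -> Partition:
    """Assign every node's Jaccard row to its nearest centroid."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[1] != J.shape[0]:
        raise ValueError("centroid length must equal the node count")
    labels = _assign(sp.csr_matrix(J), C)
    return Partition.from_labels(list(order), [int(l) for l in labels])


def update_centroids(
    J: sp.spmatrix, labels: np.ndarray, K: int
) -> np.ndarray:
    """Component-wise mean of member rows, per cluster.

    Clusters with no members get a zero centroid here; the caller is
    responsible for repair.
    """
    X = sp.csr_matrix(J)
    n = X.shape[0]
    M = sp.coo_matrix(
        (np.ones(n), (labels, np.arange(n))), shape=(K, n)
    ).tocsr()
    counts = np.asarray(M.sum(axis=1)).ravel()
    sums = np.asarray((M @ X).todense())
    safe = np.maximum(counts, 1.0)
    return sums / safe[:, None]


def _repair_empty(
    X: sp.csr_matrix, C: np.ndarray, labels: np.ndarray, empty: np.ndarray
) -> np.ndarray:
    """Reseed each empty centroid at the row of the node farthest from its
    current centroid (ties to the lowest node index)."""
    d2 = _distance_sq_matrix(X, C)
    own = d2[np.arange(X.shape[0]), labels].copy()
    for j in empty:
        far = int(np.lexsort((np.arange(len(own)), -own))[0])
        C[j] = np.asarray(X.getrow(far).todense()).ravel()
        labels[far] = j
        own[far] = 0.0
    return C


def kmeans_cluster(
    J: sp.spmatrix,
    seed_indices: Sequence[int],
    order: Sequence[Hashable],
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> ClusteringResult:
    """Lloyd iterations from seed-row initial centroids.

    Parameters
    ----------
    J
        n x n similarity matrix whose rows are the feature vectors.
    seed_indices
        Positional indices (into ``order``) of the K seed nodes.
    order
        Node ids in matrix row order.
    max_iter, tol
        Iteration cap and MaxDist convergence threshold.
    """
    X = sp.csr_matrix(J, dtype=np.float64)
    n = X.shape[0]
    K = len(seed_indices)
    if K > n:
        raise ValueError("more seeds than nodes")
    if len(set(seed_indices)) != K:
        raise ValueError("seed indices must be distinct")
    C = np.asarray(X[list(seed_indices), :].todense(), dtype=float)
    labels = _assign(X, C)
    iterations = 0
    converged = False
    max_dist = np.inf
    trace: List[float] = []
    for it in range(1, max_iter + 1):
        iterations = it
        C_new = update_centroids(X, labels, K)
        counts = np.bincount(labels, minlength=K)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            C_new = _repair_empty(X, C_new, labels, empty)
            C_new = update_centroids(X, labels, K)
        max_dist = float(np.max(np.linalg.norm(C_new - C, axis=1)))
        trace.append(max_dist)
        C = C_new
        new_labels = _assign(X, C)
        if np.array_equal(new_labels, labels) or max_dist < tol:
            labels = new_labels
            converged = True
            break
        labels = new_labels
    # final empty-cluster repair so the K-block contract always holds
    counts = np.bincount(labels, minlength=K)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        C = _repair_empty(X, C, labels, empty)
    d2 = _distance_sq_matrix(X, C)
    inertia = float(d2[np.arange(n), labels].sum())
    partition = Partition.from_labels(list(order), [int(l) for l in labels])
    return ClusteringResult(
        partition=partition,
        iterations=iterations,
        converged=converged,
        seeds=tuple(order[i] for i in seed_indices),
        max_dist=max_dist if np.isfinite(max_dist) else 0.0,
        inertia=inertia,
        max_dist_trace=trace,
    )


def ddjkm_detect(
    G: nx.Graph,
    K: int,
    h: int = DEFAULT_HOPS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> ClusteringResult:
    """End-to-end density-degree-Jaccard k-means community detection.

    Pipeline: node densities -> DD ranking -> Jaccard matrix -> DDJ
    correlation matrix -> deterministic seed selection -> k-means on the
    Jaccard rows.  Fully deterministic: the same graph, K and h always
    produce the identical partition.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if not 1 <= K <= G.number_of_nodes():
        raise ValueError(f"K must be in [1, {G.number_of_nodes()}]")
    order = canonical_node_order(G)
    D = density_vector(G, h, order)
    J = jaccard_matrix(G, order)
    seeds = select_seeds(G, K, h, order=order, J=J, D=D)
    pos = {v: i for i, v in enumerate(order)}
    seed_indices = [pos[v] for v in seeds]
    return kmeans_cluster(J, seed_indices, order, max_iter=max_iter, tol=tol)


def random_init_kmeans(
    G: nx.Graph,
    K: int,
    rng_seed: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> ClusteringResult:
    """Baseline: identical k-means but with uniformly random initial centers.

    K distinct nodes are drawn with a seeded generator and their Jaccard
    rows become the initial centroids; everything else matches
    :func:`kmeans_cluster`.
    """
    if not 1 <= K <= G.number_of_nodes():
        raise ValueError(f"K must be in [1, {G.number_of_nodes()}]")
    order = canonical_node_order(G)
    J = jaccard_matrix(G, order)
    rng = np.random.default_rng(rng_seed)
    seed_indices = rng.choice(len(order), size=K, replace=False).tolist()
    return kmeans_cluster(J, seed_indices, order, max_iter=max_iter, tol=tol)
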