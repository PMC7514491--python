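"""Model/Results facade over the detection pipeline.

`DDJKM` is constructed from a graph and the number of communities, and
`fit()` runs the full pipeline -- node densities, DD-ranked seed
selection, k-means on Jaccard rows -- returning a :class:`DDJKMResults`
carrying the partition, the seeds, convergence diagnostics and
agreement metrics against an optional ground truth.

Example
-------
>>> from ddjkm import DDJKM, synthetic_networks
>>> inst = synthetic_networks.ring_of_cliques(3, 5)
>>> res = DDJKM(inst.graph, n_communities=3).fit()
>>> res.nmi(inst.partition)
1.0
"""

from __future__ import annotations

from typing import Hashable, Iterable, Optional, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd

from . import metrics as _metrics
from .graph_core import Partition, read_edge_list, read_gml
from .kmeans_community import (
    DEFAULT_HOPS,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    ClusteringResult,
    ddjkm_detect,
    random_init_kmeans,
)

__all__ = ["DDJKM", "DDJKMResults"]


class DDJKM:
    """Density-degree-Jaccard k-means community detection model.

    Parameters
    ----------
    graph
        Simple undirected graph (self-loops are rejected).
    n_communities
        K, the number of communities to divide the network into.  K is
        an input of the method, not estimated.
    hops
        BFS radius for node density (default 3).
    max_iter
        K-means iteration cap (default 100).
    tol
        Convergence threshold on the maximal centroid displacement.
    """

    def __init__(
        self,
        graph: nx.Graph,
        n_communities: int,
        hops: int = DEFAULT_HOPS,
        max_iter: int = DEFAULT_MAX_ITER,
        tol: float = DEFAULT_TOL,
    ) -> None:
        if graph.number_of_nodes() == 0:
            raise ValueError("graph is empty")
        if any(u == v for u, v in nx.selfloop_edges(graph)):
            raise ValueError("graph contains self-loops; simplify it first")
        if not 1 <= n_communities <= graph.number_of_nodes():
            raise ValueError("n_communities must be in [1, |V|]")
        self.graph = graph
        self.n_communities = int(n_communities)
        self.hops = int(hops)
        self.max_iter = int(max_iter)
        self.tol = float(tol)

    @classmethod
    def from_edge_list(cls, path, n_communities: int, **kwargs) -> "DDJKM":
        return cls(read_edge_list(path), n_communities, **kwargs)

    @classmethod
    def from_gml(cls, path, n_communities: int, **kwargs) -> "DDJKM":
        return cls(read_gml(path), n_communities, **kwargs)

    def fit(self) -> "DDJKMResults":
        """Run the deterministic pipeline and return the results object."""
        raw = ddjkm_detect(
            self.graph,
            self.n_communities,
            h=self.hops,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        return DDJKMResults(self, raw, method="ddjkm")

    def fit_random_init(self, rng_seed: int) -> "DDJKMResults":
        """Baseline fit: same k-means but with random initial centers."""
        raw = random_init_kmeans(
            self.graph,
            self.n_communities,
            rng_seed,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        return DDJKMResults(self, raw, method=f"kmeans-random(seed={rng_seed})")


class DDJKMResults:
    """Fitted community structure with diagnostics."""

    def __init__(self, model: DDJKM, raw: ClusteringResult, method: str) -> None:
        self.model = model
        self._raw = raw
        self.method = method
        self.partition: Partition = raw.partition
        self.seeds = raw.seeds
        self.n_iter = raw.iterations
        self.converged = raw.converged
        self.max_dist = raw.max_dist
        self.inertia = raw.inertia

    @property
    def labels_(self) -> np.ndarray:
        order = sorted(self.model.graph.nodes)
        return np.array([self.partition[v] for v in order])

    def communities(self):
        return self.partition.communities()

    def community_sizes(self) -> pd.Series:
        blocks = self.partition.blocks()
        return pd.Series(
            {lab: len(mem) for lab, mem in blocks.items()}, name="size"
        ).sort_index()

    def nmi(self, truth: Partition) -> float:
        """Normalised mutual information against a reference partition."""
        return _metrics.nmi(truth, self.partition)

    def f1(self, truth: Partition | Iterable[Set[Hashable]]) -> float:
        """Bidirectional best-match F1 against reference communities."""
        return _metrics.f1_score(truth, self.partition)

    def summary(self, truth: Optional[Partition] = None) -> str:
        """Human-readable run summary, optionally with agreement metrics."""
        G = self.model.graph
        sizes = self.community_sizes()
        lines = [
            "DDJKM community detection results",
            "=" * 40,
            f"method:            {self.method}",
            f"nodes, edges:      {G.number_of_nodes()}, {G.number_of_edges()}",
            f"communities (K):   {self.partition.k}",
            f"hops (h):          {self.model.hops}",
            f"iterations:        {self.n_iter} (converged: {self.converged})",
            f"final MaxDist:     {self.max_dist:.3e}",
            f"inertia:           {self.inertia:.6g}",
            f"seed nodes:        {list(self.seeds)}",
            f"community sizes:   min {sizes.min()}, median {sizes.median():.0f}, "
            f"max {sizes.max()}",
        ]
        if truth is not None:
            lines += [
                f"NMI vs truth:      {self.nmi(truth):.4f}",
                f"F1 vs truth:       {self.f1(truth):.4f}",
            ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Node-to-community table (node_id, community)."""
        order = sorted(self.model.graph.nodes)
        return pd.DataFrame(
            {"node_id": order, "community": [self.partition[v] for v in order]}
        )
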