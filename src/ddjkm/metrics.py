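"""Partition-agreement metrics: NMI and bidirectional best-match F1.

Normalised mutual information is computed from the confusion matrix C
between two partitions A and B of the same N nodes:

    I(A, B) = -2 * sum_ij C_ij log(C_ij N / (C_i. C_.j))
              / ( sum_i C_i. log(C_i./N) + sum_j C_.j log(C_.j/N) )

The log base cancels between numerator and denominator; natural logs
are used internally.  I(A, B) = 1 when the partitions are identical up
to relabelling and 0 when they are independent.

The bidirectional F1 score matches each ground-truth community to its
best-F1 detected community and vice versa, and averages the two
directional means; it applies to any two collections of node sets, not
only disjoint partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .graph_core import Partition

logger = logging.getLogger(__name__)

__all__ = ["ConfusionMatrix", "confusion_matrix", "nmi", "f1_score"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Cross-tabulation of two partitions of the same node set."""

    counts: np.ndarray  # shape (C_A, C_B), non-negative integers
    row_labels: tuple
    col_labels: tuple

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def confusion_matrix(A: Partition, B: Partition) -> ConfusionMatrix:
    """Entry (i, j) counts nodes in community i of A and community j of B."""
    if A.nodes != B.nodes:
        raise ValueError("partitions cover different node sets")
    row_labels = tuple(sorted(set(A.assignment.values()), key=repr))
    col_labels = tuple(sorted(set(B.assignment.values()), key=repr))
    ri = {lab: i for i, lab in enumerate(row_labels)}
    cj = {lab: j for j, lab in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    for v in A.assignment:
        counts[ri[A[v]], cj[B[v]]] += 1
    return ConfusionMatrix(counts, row_labels, col_labels)


def nmi(A: Partition, B: Partition) -> float:
    """Normalised mutual information between two partitions, in [0, 1]."""
    cm = confusion_matrix(A, B)
    C = cm.counts.astype(float)
    N = float(cm.n)
    a = cm.row_sums.astype(float)
    b = cm.col_sums.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = C * N / np.outer(a, b)
        num_terms = np.where(C > 0, C * np.log(np.where(C > 0, ratio, 1.0)), 0.0)
    numerator = -2.0 * num_terms.sum()
    denom = float(np.sum(a * np.log(a / N)) + np.sum(b * np.log(b / N)))
    if denom == 0.0:
        # both partitions are a single block: identical iff labels align trivially
        logger.warning("NMI denominator is zero (both partitions trivial)")
        same = np.array_equal(cm.counts.shape, (1, 1))
        return 1.0 if same else 0.0
    return float(numerator / denom)


def _as_community_sets(part: Partition | Iterable[Set[Hashable]]) -> List[Set[Hashable]]:
    if isinstance(part, Partition):
        return part.communities()
    out = [set(c) for c in part]
    return out


def _pairwise_f1(S: Set[Hashable], T: Set[Hashable]) -> float:
    """Harmonic mean of precision and recall of node set S against T."""
    inter = len(S & T)
    if inter == 0:
        return 0.0
    precision = inter / len(S)
    recall = inter / len(T)
    return 2 * precision * recall / (precision + recall)


def f1_score(
    T: Partition | Iterable[Set[Hashable]],
    D: Partition | Iterable[Set[Hashable]],
) -> float:
    """Bidirectional best-match F1 between two community collections.

    Each community of T is scored by its best pairwise F1 over the
    communities of D; the directional mean is averaged with the reverse
    direction.  Zero-overlap pairs contribute 0.
    """
    Ts = _as_community_sets(T)
    Ds = _as_community_sets(D)
    if not Ts or not Ds:
        raise ValueError("community collections must be non-empty")
    fwd = np.mean([max(_pairwise_f1(t, d) for d in Ds) for t in Ts])
    bwd = np.mean([max(_pairwise_f1(d, t) for t in Ts) for d in Ds])
    return float(0.5 * (fwd + bwd))
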