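"""Graph data model, file I/O, and BFS-ball extraction.

Graphs are simple (no self-loops, no parallel edges), undirected and
unweighted, held as :class:`networkx.Graph` instances with hashable node
ids.  All downstream measures index nodes through a canonical order --
sorted node ids -- so that tie-breaking rules ("ascending order of node
number") are well defined even for graphs read from files with arbitrary
labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Hashable, Iterable, List, Sequence, Set

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "read_edge_list",
    "read_gml",
    "write_edge_list",
    "read_partition",
    "write_partition",
    "canonical_node_order",
    "bfs_ball",
    "induced_subgraph",
    "simplify_graph",
]


class GraphFormatError(ValueError):
    """Raised for malformed or unsupported graph input files."""


@dataclass(frozen=True)
class Partition:
    """A hard assignment of every node to exactly one community.

    Parameters
    ----------
    assignment
        Mapping from node id to an (arbitrary, hashable) community label.

    Attributes
    ----------
    k
        The number of distinct community labels (all blocks non-empty by
        construction).
    """

    assignment: Dict[Hashable, Hashable]
    k: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", len(set(self.assignment.values())))

    def __len__(self) -> int:
        return len(self.assignment)

    def __getitem__(self, node: Hashable) -> Hashable:
        return self.assignment[node]

    def label_of(self, node: Hashable) -> Hashable:
        return self.assignment[node]

    @property
    def nodes(self) -> Set[Hashable]:
        return set(self.assignment)

    def blocks(self) -> Dict[Hashable, Set[Hashable]]:
        """Return the communities as ``label -> node set``."""
        out: Dict[Hashable, Set[Hashable]] = {}
        for node, lab in self.assignment.items():
            out.setdefault(lab, set()).add(node)
        return out

    def communities(self) -> List[Set[Hashable]]:
        """Return the communities as a list of node sets (label-sorted)."""
        blocks = self.blocks()
        return [blocks[lab] for lab in sorted(blocks, key=repr)]

    def labels(self, order: Sequence[Hashable]) -> List[Hashable]:
        """Community labels in a given node order."""
        return [self.assignment[v] for v in order]

    def restricted_to(self, nodes: Iterable[Hashable]) -> "Partition":
        keep = set(nodes)
        return Partition({v: c for v, c in self.assignment.items() if v in keep})

    @classmethod
    def from_labels(cls, order: Sequence[Hashable], labels: Sequence[Hashable]) -> "Partition":
        if len(order) != len(labels):
            raise ValueError("node order and label sequence differ in length")
        return cls(dict(zip(order, labels)))

    def covers(self, G: nx.Graph) -> bool:
        return set(G.nodes) == set(self.assignment)


def canonical_node_order(G: nx.Graph) -> List:
    """Sorted node ids -- the row/column order of every matrix built here."""
    return sorted(G.nodes)


def simplify_graph(G: nx.Graph) -> nx.Graph:
    """Drop self-loops (and, via the nx.Graph container, parallel edges)."""
    loops = list(nx.selfloop_edges(G))
    if loops:
        logger.warning("dropped %d self-loop(s)", len(loops))
        G.remove_edges_from(loops)
    return G


def _coerce_int_labels(G: nx.Graph) -> nx.Graph:
    """Map node labels to integers where possible, preserving numeric ids."""
    try:
        mapping = {v: int(v) for v in G.nodes}
    except (TypeError, ValueError):
        # non-numeric labels: stable alphabetical relabelling, table retained
        ordered = sorted(G.nodes, key=str)
        mapping = {v: i for i, v in enumerate(ordered)}
    if len(set(mapping.values())) != G.number_of_nodes():
        raise GraphFormatError("node labels collide after integer coercion")
    H = nx.relabel_nodes(G, mapping, copy=True)
    H.graph["label_table"] = {i: v for v, i in mapping.items()}
    return H


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a whitespace-delimited ``u v`` edge list into a simple graph.

    Lines starting with ``#`` are comments.  Duplicate edges and
    self-loops are dropped with a logged count; a self-loop's node is
    retained as an isolated node.
    """
    path = Path(path)
    G: nx.Graph = nx.Graph()
    n_dup = n_loop = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) == 1:
                # single-token line: isolated-node declaration
                try:
                    G.add_node(int(tokens[0]))
                except ValueError as exc:
                    raise GraphFormatError(
                        f"{path}:{lineno}: non-integer node id {tokens[0]!r}"
                    ) from exc
                continue
            if len(tokens) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected two tokens, got {len(tokens)}"
                )
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except ValueError as exc:
                raise GraphFormatError(
                    f"{path}:{lineno}: non-integer node id in {tokens!r}"
                ) from exc
            if u == v:
                n_loop += 1
                G.add_node(u)
                continue
            if G.has_edge(u, v):
                n_dup += 1
                continue
            G.add_edge(u, v)
    if G.number_of_nodes() == 0:
        raise GraphFormatError(f"{path}: no nodes found (empty edge list)")
    if n_dup or n_loop:
        logger.warning(
            "%s: dropped %d duplicate edge(s) and %d self-loop(s)", path, n_dup, n_loop
        )
    return G


def read_gml(path: str | Path) -> nx.Graph:
    """Read an undirected simple graph from a GML file.

    GML ``id`` fields become the node ids.  Directed graphs are rejected.
    """
    path = Path(path)
    try:
        G = nx.read_gml(path, label="id")
    except Exception as exc:  # networkx raises several parser error types
        raise GraphFormatError(f"{path}: GML parse failure: {exc}") from exc
    if G.is_directed():
        raise GraphFormatError(f"{path}: directed graphs are not supported")
    if G.is_multigraph():
        G = nx.Graph(G)  # collapse parallel edges
    G = simplify_graph(G)
    G = _coerce_int_labels(G)
    if G.number_of_nodes() == 0:
        raise GraphFormatError(f"{path}: empty graph")
    return G


def write_edge_list(G: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted((min(u, v), max(u, v)) for u, v in G.edges):
            fh.write(f"{u} {v}\n")
        # single-token lines declare isolated nodes (round-trip safety)
        for v in (v for v in sorted(G.nodes) if G.degree(v) == 0):
            fh.write(f"{v}\n")


def read_partition(path: str | Path) -> Partition:
    """Read a two-column ``node_id community_label`` TSV."""
    path = Path(path)
    assignment: Dict[Hashable, Hashable] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'node label', got {raw!r}"
                )
            node = int(tokens[0])
            try:
                label: Hashable = int(tokens[1])
            except ValueError:
                label = tokens[1]
            if node in assignment:
                raise GraphFormatError(f"{path}:{lineno}: node {node} listed twice")
            assignment[node] = label
    if not assignment:
        raise GraphFormatError(f"{path}: empty partition file")
    return Partition(assignment)


def write_partition(P: Partition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for node in sorted(P.assignment):
            fh.write(f"{node}\t{P.assignment[node]}\n")


def bfs_ball(G: nx.Graph, v: Hashable, h: int) -> Set[Hashable]:
    """All nodes within shortest-path distance ``h`` of ``v``, inclusive.

    The ball always contains ``v`` itself (``h = 0`` gives ``{v}``).
    """
    if v not in G:
        raise KeyError(f"node {v!r} not in graph")
    if h < 0:
        raise ValueError("hop count must be non-negative")
    return set(nx.single_source_shortest_path_length(G, v, cutoff=h))


def induced_subgraph(G: nx.Graph, S: Iterable[Hashable]) -> nx.Graph:
    """Subgraph on node set ``S`` with every edge internal to ``S``."""
    S = set(S)
    missing = S - set(G.nodes)
    if missing:
        raise KeyError(f"nodes not in graph: {sorted(missing, key=repr)[:5]}")
    return G.subgraph(S).copy()
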