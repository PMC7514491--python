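"""Benchmark-network generators with planted community structure.

Three families:

* :func:`generate_lfr` -- LFR-style benchmarks: power-law degree and
  community-size distributions with a tunable mixing parameter ``mu``
  (the fraction of each node's edges that leave its community).  The
  generator draws a degree sequence from a truncated power law whose
  lower cutoff is solved numerically to hit the requested mean degree,
  tiles the node set with power-law community sizes, realises each
  community's internal degree sequence as a simple graph (Havel-Hakimi
  construction randomised by double-edge swaps), and matches the
  remaining stubs across communities.  Exact edge-level equivalence
  with the original LFR program is not claimed; the distributions and
  mixing are emulated and the realised values are reported on the
  instance.
* :func:`generate_planted_partition` -- equal-sized blocks with
  independent Bernoulli edges (p_in within, p_out between).
* :func:`ring_of_cliques` -- deterministic fixture: c cliques of size
  s joined consecutively by single bridging edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import networkx as nx
import numpy as np

from .graph_core import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "LFRParams",
    "BenchmarkInstance",
    "generate_lfr",
    "generate_planted_partition",
    "ring_of_cliques",
]


@dataclass(frozen=True)
class LFRParams:
    """Parameter bundle of an LFR-style benchmark.

    Attributes
    ----------
    n : node count
    tau1 : degree power-law exponent
    tau2 : community-size power-law exponent
    cmin, cmax : community-size bounds
    avg_k : target mean degree
    kmax : maximum degree
    mu : mixing parameter in [0, 1]
    rng_seed : generator seed
    """

    n: int
    tau1: float = 2.0
    tau2: float = 1.0
    cmin: int = 20
    cmax: int = 100
    avg_k: float = 15.0
    kmax: int = 75
    mu: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if not self.cmin <= self.cmax <= self.n:
            raise ValueError("need cmin <= cmax <= n")
        if not self.avg_k <= self.kmax < self.n:
            raise ValueError("need avg_k <= kmax < n")


@dataclass
class BenchmarkInstance:
    """A generated graph together with its planted ground truth."""

    graph: nx.Graph
    partition: Partition
    realized_mixing: float
    realized_mean_degree: float
    params: Optional[LFRParams] = None

    @property
    def k(self) -> int:
        return self.partition.k


# ---------------------------------------------------------------------------
# power-law sampling helpers
# ---------------------------------------------------------------------------

def _powerlaw_cdf(x: np.ndarray, a: float, b: float, tau: float) -> np.ndarray:
    """CDF of the continuous truncated power law p(x) ~ x^-tau on [a, b]."""
    x = np.asarray(x, dtype=float)
    if abs(tau - 1.0) < 1e-12:
        return np.log(x / a) / np.log(b / a)
    e = 1.0 - tau
    return (x**e - a**e) / (b**e - a**e)


def _powerlaw_ppf(u: np.ndarray, a: float, b: float, tau: float) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if abs(tau - 1.0) < 1e-12:
        return a * (b / a) ** u
    e = 1.0 - tau
    return (a**e + u * (b**e - a**e)) ** (1.0 / e)


def _sample_powerlaw_ints(
    rng: np.random.Generator, size: int, a: float, b: int, tau: float
) -> np.ndarray:
    """Integer samples: floor of continuous truncated power-law draws."""
    x = _powerlaw_ppf(rng.random(size), a, b + 1 - 1e-9, tau)
    return np.minimum(np.floor(x).astype(np.int64), b)


def _floored_mean(a: float, b: int, tau: float) -> float:
    """Expected value of the floored truncated power-law variable."""
    ks = np.arange(int(np.floor(a)), b + 1)
    upper = np.minimum(ks + 1, b + 1 - 1e-9)
    lower = np.maximum(ks.astype(float), a)
    probs = _powerlaw_cdf(upper, a, b + 1 - 1e-9, tau) - _powerlaw_cdf(
        lower, a, b + 1 - 1e-9, tau
    )
    probs = np.clip(probs, 0.0, None)
    return float(np.sum(ks * probs))


def _solve_kmin(avg_k: float, kmax: int, tau: float) -> float:
    """Lower cutoff of the degree law giving the requested mean degree."""
    lo, hi = 1.0, float(kmax)
    if _floored_mean(lo, kmax, tau) > avg_k:
        return lo
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _floored_mean(mid, kmax, tau) < avg_k:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# LFR-style generation
# ---------------------------------------------------------------------------

class GenerationError(RuntimeError):
    """Raised when a parameter set cannot be realised after bounded retries."""


def _draw_community_sizes(
    rng: np.random.Generator, n: int, cmin: int, cmax: int, tau2: float
) -> np.ndarray:
    """Power-law community sizes tiling exactly n nodes."""
    for _ in range(200):
        sizes: List[int] = []
        total = 0
        while total < n:
            s = int(_sample_powerlaw_ints(rng, 1, cmin, cmax, tau2)[0])
            sizes.append(s)
            total += s
        excess = total - n
        # shave the excess off communities with headroom above cmin
        i = len(sizes) - 1
        while excess > 0 and any(s > cmin for s in sizes):
            room = sizes[i] - cmin
            take = min(room, excess)
            sizes[i] -= take
            excess -= take
            i = (i - 1) % len(sizes)
        if excess == 0 and len(sizes) >= 2:
            return np.array(sizes, dtype=np.int64)
    raise GenerationError("could not tile the node set with community sizes")


def _assign_communities(
    rng: np.random.Generator, d_int: np.ndarray, sizes: np.ndarray
) -> np.ndarray:
    """Assign nodes to communities so that every node's internal degree
    fits its community (d_int <= size - 1); caps d_int when forced."""
    n = d_int.shape[0]
    K = sizes.shape[0]
    capacity = sizes.copy()
    membership = np.full(n, -1, dtype=np.int64)
    # place high-internal-degree nodes first, under the size constraint
    node_order = np.argsort(-d_int, kind="stable")
    comm_ids = np.arange(K)
    for v in node_order:
        feasible = comm_ids[(capacity > 0) & (sizes - 1 >= d_int[v])]
        if feasible.size:
            weights = capacity[feasible].astype(float)
            c = int(rng.choice(feasible, p=weights / weights.sum()))
        else:
            open_comms = comm_ids[capacity > 0]
            c = int(open_comms[np.argmax(sizes[open_comms])])
            d_int[v] = sizes[c] - 1  # cap; excess becomes external stubs
        membership[v] = c
        capacity[c] -= 1
    return membership


def _make_graphical(seq: np.ndarray) -> np.ndarray:
    """Trim a degree sequence (within one community) until graphical."""
    seq = seq.copy()
    while seq.sum() % 2 == 1 or not nx.is_graphical(seq.tolist()):
        j = int(np.argmax(seq))
        if seq[j] == 0:
            break
        seq[j] -= 1
    return seq


def _wire_internal(
    rng: np.random.Generator, members: np.ndarray, d_int: np.ndarray
) -> List[tuple]:
    """Simple graph on one community realising its internal degrees:
    Havel-Hakimi construction, randomised by double-edge swaps."""
    seq = _make_graphical(d_int[members])
    if seq.sum() == 0:
        return []
    H = nx.havel_hakimi_graph(seq.tolist())
    m = H.number_of_edges()
    s = len(members)
    if s >= 4 and 2 <= m < s * (s - 1) // 2:
        nswap = 5 * m
        try:
            nx.double_edge_swap(
                H, nswap=nswap, max_tries=100 * nswap, seed=int(rng.integers(2**31))
            )
        except nx.NetworkXException:
            pass  # dense or tiny community: construction order stands
    return [
        (min(int(members[u]), int(members[v])), max(int(members[u]), int(members[v])))
        for u, v in H.edges
    ]


def _match_external_stubs(
    rng: np.random.Generator,
    stubs: np.ndarray,
    membership: np.ndarray,
    existing: set,
    max_passes: int = 60,
) -> List[tuple]:
    """Pair inter-community stubs, rejecting self/intra/duplicate pairs."""
    edges: List[tuple] = []
    pool = stubs.copy()
    for _ in range(max_passes):
        if pool.size < 2:
            break
        rng.shuffle(pool)
        if pool.size % 2 == 1:
            pool = pool[:-1]
        a, b = pool[0::2], pool[1::2]
        leftovers: List[int] = []
        for u, v in zip(a, b):
            u, v = int(u), int(v)
            key = (min(u, v), max(u, v))
            if u == v or membership[u] == membership[v] or key in existing:
                leftovers.extend((u, v))
            else:
                existing.add(key)
                edges.append(key)
        if not leftovers:
            pool = np.empty(0, dtype=np.int64)
            break
        pool = np.array(leftovers, dtype=np.int64)
    if pool.size:
        logger.debug("dropped %d unmatched external stubs", pool.size)
    return edges


def generate_lfr(params: LFRParams) -> BenchmarkInstance:
    """Generate one LFR-style benchmark instance.

    Reproducible for a fixed ``params.rng_seed``; the realised mixing
    (node-averaged external-edge fraction) and mean degree are attached
    to the returned instance.
    """
    rng = np.random.default_rng(params.rng_seed)
    n = params.n
    kmin = _solve_kmin(params.avg_k, params.kmax, params.tau1)
    degrees = _sample_powerlaw_ints(rng, n, kmin, params.kmax, params.tau1)

    sizes = _draw_community_sizes(rng, n, params.cmin, params.cmax, params.tau2)

    # split each degree into internal / external with stochastic rounding
    target_int = (1.0 - params.mu) * degrees
    d_int = np.floor(target_int).astype(np.int64)
    frac = target_int - d_int
    d_int += (rng.random(n) < frac).astype(np.int64)

    membership = _assign_communities(rng, d_int, sizes)

    edges: List[tuple] = []
    for c in range(sizes.shape[0]):
        members = np.flatnonzero(membership == c)
        edges.extend(_wire_internal(rng, members, d_int))

    existing = set(edges)
    realized_int = np.zeros(n, dtype=np.int64)
    for u, v in edges:
        realized_int[u] += 1
        realized_int[v] += 1
    if params.mu > 0.0:
        d_ext = degrees - realized_int
        np.maximum(d_ext, 0, out=d_ext)
        stubs = np.repeat(np.arange(n), d_ext)
        edges.extend(_match_external_stubs(rng, stubs, membership, existing))
    # mu = 0: any shortfall from the graphical trim is dropped rather than
    # rewired across communities, keeping every edge intra-community

    G: nx.Graph = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(edges)

    partition = Partition({v: int(membership[v]) for v in range(n)})
    mixing, mean_deg = _realized_stats(G, partition)
    return BenchmarkInstance(G, partition, mixing, mean_deg, params)


def _realized_stats(G: nx.Graph, P: Partition) -> tuple:
    """Node-averaged external-edge fraction and mean degree."""
    fracs = []
    for v in G.nodes:
        deg = G.degree(v)
        if deg == 0:
            continue
        ext = sum(1 for u in G[v] if P[u] != P[v])
        fracs.append(ext / deg)
    mixing = float(np.mean(fracs)) if fracs else 0.0
    mean_deg = 2 * G.number_of_edges() / max(G.number_of_nodes(), 1)
    return mixing, float(mean_deg)


# ---------------------------------------------------------------------------
# small controllable fixtures
# ---------------------------------------------------------------------------

def generate_planted_partition(
    blocks: int, block_size: int, p_in: float, p_out: float, rng_seed: int
) -> BenchmarkInstance:
    """Planted-partition graph: Bernoulli(p_in) edges within each of
    ``blocks`` equal blocks, Bernoulli(p_out) between blocks."""
    if not 0.0 <= p_out <= p_in <= 1.0:
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    G = nx.planted_partition_graph(blocks, block_size, p_in, p_out, seed=rng_seed)
    G = nx.Graph(G)  # drop block metadata container semantics
    assignment = {v: v // block_size for v in G.nodes}
    P = Partition(assignment)
    mixing, mean_deg = _realized_stats(G, P)
    return BenchmarkInstance(G, P, mixing, mean_deg)


def ring_of_cliques(c: int, s: int) -> BenchmarkInstance:
    """c cliques of size s, consecutive cliques joined by one bridge edge.

    Nodes are numbered consecutively by clique; the planted partition is
    the cliques themselves.
    """
    if c < 2 or s < 3:
        raise ValueError("need at least 2 cliques of size >= 3")
    G: nx.Graph = nx.Graph()
    for i in range(c):
        base = i * s
        members = range(base, base + s)
        for u in members:
            for v in members:
                if u < v:
                    G.add_edge(u, v)
    for i in range(c):
        j = (i + 1) % c
        if c == 2 and i == 1:
            break  # a single bridge between two cliques
        # bridge: second node of clique i to first node of clique j,
        # avoiding reuse of the same endpoint for in- and out-bridges
        G.add_edge(i * s + 1, j * s)
    P = Partition({v: v // s for v in G.nodes})
    mixing, mean_deg = _realized_stats(G, P)
    return BenchmarkInstance(G, P, mixing, mean_deg)
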