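"""Reusable benchmark-replication harness.

Bundles the two benchmark configurations used throughout the package's
evaluation suite -- the 5000-node and 1000-node LFR-style families --
together with a deterministic per-replicate seed derivation, so that a
sweep is fully specified by (base seed, mu grid, replicate count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .kmeans_community import ddjkm_detect, random_init_kmeans
from .metrics import nmi
from .synthetic_networks import LFRParams, generate_lfr

__all__ = [
    "lfr_5000_params",
    "lfr_1000_params",
    "replicate_seed",
    "SweepResult",
    "ddjkm_nmi_sweep",
    "random_init_nmi_sweep",
]


def lfr_5000_params(mu: float, rng_seed: int) -> LFRParams:
    """The 5000-node benchmark family: tau1=2, tau2=1, community sizes
    20-100, mean degree 15, max degree 75."""
    return LFRParams(
        n=5000, tau1=2.0, tau2=1.0, cmin=20, cmax=100, avg_k=15.0, kmax=75,
        mu=mu, rng_seed=rng_seed,
    )


def lfr_1000_params(mu: float, rng_seed: int) -> LFRParams:
    """The 1000-node benchmark family: tau1=2, tau2=1, community sizes
    20-50, mean degree 20, max degree 50."""
    return LFRParams(
        n=1000, tau1=2.0, tau2=1.0, cmin=20, cmax=50, avg_k=20.0, kmax=50,
        mu=mu, rng_seed=rng_seed,
    )


def replicate_seed(base_seed: int, mu: float, replicate: int) -> int:
    """Deterministic sub-seed for one (mu, replicate) cell, below 2**31."""
    ss = np.random.SeedSequence((base_seed, round(mu * 10), replicate))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SweepResult:
    mu: float
    nmis: List[float]
    n_nodes: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.nmis))

    @property
    def se(self) -> float:
        if len(self.nmis) < 2:
            return 0.0
        return float(np.std(self.nmis, ddof=1) / np.sqrt(len(self.nmis)))


def _sweep(
    mus: Sequence[float],
    replicates: int,
    base_seed: int,
    params_fn,
    detect_fn,
) -> Dict[float, SweepResult]:
    out: Dict[float, SweepResult] = {}
    for mu in mus:
        vals: List[float] = []
        n_nodes = 0
        for rep in range(replicates):
            seed = replicate_seed(base_seed, mu, rep)
            inst = generate_lfr(params_fn(mu, seed))
            n_nodes = inst.graph.number_of_nodes()
            res = detect_fn(inst, seed)
            vals.append(nmi(inst.partition, res.partition))
        out[mu] = SweepResult(mu, vals, n_nodes)
    return out


def ddjkm_nmi_sweep(
    mus: Sequence[float],
    replicates: int,
    base_seed: int,
    params_fn=lfr_5000_params,
    h: int = 3,
    max_iter: int = 100,
) -> Dict[float, SweepResult]:
    """Mean DDJKM NMI against the planted partition over a mu sweep."""
    return _sweep(
        mus,
        replicates,
        base_seed,
        params_fn,
        lambda inst, seed: ddjkm_detect(inst.graph, inst.k, h=h, max_iter=max_iter),
    )


def random_init_nmi_sweep(
    mus: Sequence[float],
    replicates: int,
    base_seed: int,
    params_fn=lfr_1000_params,
    max_iter: int = 100,
) -> Dict[float, SweepResult]:
    """Same sweep with the random-initialisation k-means baseline."""
    return _sweep(
        mus,
        replicates,
        base_seed,
        params_fn,
        lambda inst, seed: random_init_kmeans(inst.graph, inst.k, seed, max_iter=max_iter),
    )
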