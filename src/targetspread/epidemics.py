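"""Discrete-time SIR simulation and per-seed spreading-ability measurement.

The model: an infectious node transmits to each currently susceptible
neighbor independently with probability λ per step; recovery probability is
fixed at 1, so every node is infectious for exactly one synchronous step and
is then immune. Spreading ability toward a target set is summarized per seed
by ρ (mean fraction of targets recovered at absorption), the leakage v (mean
fraction of non-targets recovered) and the mean seed→target distance 〈d〉.

Two engines implement the same dynamics: :func:`simulate_sir` is a readable
pure-Python reference returning the full outcome of one realization, and the
numba kernels in :mod:`._kernels` run the Monte-Carlo batches the experiment
harnesses need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .netcore import Network, ParameterError, bfs_distances, hmf_lambda_c
from .targets import TargetSet

__all__ = [
    "SIRParams",
    "SIROutcome",
    "SeedSummary",
    "simulate_sir",
    "seed_summary",
    "mean_target_distance",
    "hmf_critical_lambda",
]


@dataclass(frozen=True)
class SIRParams:
    """λ per-contact infection probability; R Monte-Carlo realizations.

    The recovery probability mu is part of the model definition and fixed at
    1 (one step of infectiousness); it is carried only so configs are
    explicit about it.
    """

    lam: float
    n_realizations: int = 100
    rng_seed: int = 0
    mu: float = 1.0

    def __post_init__(self):
        if not 0 <= self.lam <= 1:
            raise ParameterError(f"lam must be in [0, 1], got {self.lam}")
        if self.mu != 1.0:
            raise ParameterError("only mu = 1 (one-step infectiousness) is supported")
        if self.n_realizations <= 0:
            raise ParameterError("n_realizations must be positive")


@dataclass(frozen=True)
class SIROutcome:
    """Recovered set (internal indices) and step count of one realization."""

    recovered: frozenset
    n_steps: int


@dataclass(frozen=True)
class SeedSummary:
    """Monte-Carlo summary of one candidate seed's spreading toward targets."""

    seed: int
    rho: float
    v: float
    mean_dist: float
    n_unreachable: int
    n_realizations: int


def simulate_sir(
    net: Network, seed: str | int, lam: float, rng: np.random.Generator
) -> SIROutcome:
    """One synchronous SIR realization (pure-Python reference engine).

    Each infectious node draws an independent Bernoulli(λ) contact against
    every neighbor that was susceptible at the start of the step; a node
    infected by any contact becomes infectious next step, and infectors
    recover at the end of their step.
    """
    if not 0 <= lam <= 1:
        raise ParameterError(f"lam must be in [0, 1], got {lam}")
    s = net.index_of(seed)
    status = np.zeros(net.n, dtype=np.int8)  # 0 S, 1 I, 2 R
    status[s] = 1
    infectious = [s]
    n_steps = 0
    while infectious:
        n_steps += 1
        newly: list[int] = []
        for i in infectious:
            for j in net.adj[i]:
                if status[j] == 0 and rng.random() < lam:
                    status[j] = 3  # infected this step; no further draws needed
                    newly.append(int(j))
        for i in infectious:
            status[i] = 2
        for j in newly:
            status[j] = 1
        infectious = newly
    return SIROutcome(frozenset(np.flatnonzero(status == 2).tolist()), n_steps)


def mean_target_distance(
    net: Network, seed: str | int, targets: TargetSet
) -> tuple[float, int]:
    """Mean shortest-path length from the seed to each reachable target.

    Returns ``(mean, n_unreachable)``; unreachable targets are excluded from
    the mean (NaN if none is reachable).
    """
    s = net.index_of(seed)
    dist = bfs_distances(net, [s])
    d = dist[list(targets.members)]
    finite = d[np.isfinite(d)]
    n_unreachable = int(len(d) - len(finite))
    mean = float(finite.mean()) if len(finite) else math.nan
    return mean, n_unreachable


def seed_summary(
    net: Network,
    seed: str | int,
    targets: TargetSet,
    params: SIRParams,
    allow_target_seed: bool = False,
) -> SeedSummary:
    """ρ, v and 〈d〉 for one candidate seed over ``params.n_realizations`` runs."""
    s = net.index_of(seed)
    if s in set(targets.members) and not allow_target_seed:
        raise ParameterError(
            f"seed {net.labels[s]!r} is a target; pass allow_target_seed=True "
            "for the global-target benchmark"
        )
    indptr, indices = net.csr()
    rho, v = _kernels.rho_v_batch(
        indptr,
        indices,
        net.n,
        np.array([s], dtype=np.int64),
        targets.mask(net.n),
        float(params.lam),
        int(params.n_realizations),
        int(params.rng_seed) % (2**31),
    )
    mean_dist, n_unreachable = mean_target_distance(net, s, targets)
    return SeedSummary(
        seed=s,
        rho=float(rho[0]),
        v=float(v[0]),
        mean_dist=mean_dist,
        n_unreachable=n_unreachable,
        n_realizations=params.n_realizations,
    )


def hmf_critical_lambda(net: Network) -> float:
    """Heterogeneous-mean-field SIR threshold 〈k〉/(〈k²〉−〈k〉) from the degree
    moments (inf on degenerate graphs where 〈k²〉 ≤ 〈k〉)."""
    if net.n < 2:
        raise ParameterError("need at least 2 nodes")
    deg = net.degrees.astype(float)
    return hmf_lambda_c(float(deg.mean()), float((deg**2).mean()))
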