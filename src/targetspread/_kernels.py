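"""Numba kernels for the SIR Monte Carlo.

Dynamics (synchronous, recovery probability 1): at each step every
infectious node contacts each currently-susceptible neighbor and transmits
with probability lam; a node contacted successfully by any infector this
step becomes infectious at the next step; every infectious node recovers at
the end of its step. A node already infected earlier in the same step is
skipped for further contact draws — distributionally identical to drawing
for every infector, since infection happens if any contact succeeds.

All kernels use numba's MT19937 stream seeded explicitly, so a fixed seed
gives a bit-reproducible result.

Status codes: 0 susceptible, 1 infectious, 2 recovered, 3 infected this step.
"""

import numpy as np
from numba import njit

__all__ = ["sir_counts_single", "rho_v_batch", "coverage_samples"]


@njit(cache=False)
def _run_sir(indptr, indices, n, seed_node, lam, status, frontier, nxt):
    """One epidemic in-place; returns the number of steps until absorption."""
    for i in range(n):
        status[i] = 0
    status[seed_node] = 1
    frontier[0] = seed_node
    fs = 1
    steps = 0
    while fs > 0:
        steps += 1
        ns = 0
        for fi in range(fs):
            i = frontier[fi]
            for p in range(indptr[i], indptr[i + 1]):
                j = indices[p]
                if status[j] == 0 and np.random.random() < lam:
                    status[j] = 3
                    nxt[ns] = j
                    ns += 1
        for fi in range(fs):
            status[frontier[fi]] = 2
        for q in range(ns):
            status[nxt[q]] = 1
            frontier[q] = nxt[q]
        fs = ns
    return steps


@njit(cache=False)
def sir_counts_single(indptr, indices, n, seed_node, lam, rng_seed):
    """One realization; returns (recovered mask, n_steps)."""
    np.random.seed(rng_seed)
    status = np.empty(n, np.uint8)
    frontier = np.empty(n, np.int64)
    nxt = np.empty(n, np.int64)
    steps = _run_sir(indptr, indices, n, seed_node, lam, status, frontier, nxt)
    return status == 2, steps


@njit(cache=False)
def rho_v_batch(indptr, indices, n, seed_nodes, target_mask, lam, n_reps, rng_seed):
    """Mean target coverage rho and non-target leakage v per candidate seed.

    For each seed node, runs n_reps independent epidemics and averages the
    fraction of targets recovered (rho) and of non-targets recovered (v).
    v is NaN when every node is a target.
    """
    np.random.seed(rng_seed)
    m = 0
    for i in range(n):
        if target_mask[i]:
            m += 1
    n_seeds = seed_nodes.shape[0]
    rho = np.zeros(n_seeds)
    v = np.zeros(n_seeds)
    status = np.empty(n, np.uint8)
    frontier = np.empty(n, np.int64)
    nxt = np.empty(n, np.int64)
    for s in range(n_seeds):
        t_sum = 0.0
        nt_sum = 0.0
        for _ in range(n_reps):
            _run_sir(indptr, indices, n, seed_nodes[s], lam, status, frontier, nxt)
            tc = 0
            nc = 0
            for i in range(n):
                if status[i] == 2:
                    if target_mask[i]:
                        tc += 1
                    else:
                        nc += 1
            t_sum += tc
            nt_sum += nc
        rho[s] = t_sum / (n_reps * m)
        v[s] = nt_sum / (n_reps * (n - m)) if n > m else np.nan
    return rho, v


@njit(cache=False)
def coverage_samples(
    indptr, indices, n, candidates, target_mask, lam, n_samples, rng_seed
):
    """n_samples one-shot epidemics, seed drawn uniformly from candidates each
    time; returns the per-sample fraction of targets recovered."""
    np.random.seed(rng_seed)
    m = 0
    for i in range(n):
        if target_mask[i]:
            m += 1
    out = np.empty(n_samples)
    status = np.empty(n, np.uint8)
    frontier = np.empty(n, np.int64)
    nxt = np.empty(n, np.int64)
    for t in range(n_samples):
        seed_node = candidates[np.random.randint(0, candidates.shape[0])]
        _run_sir(indptr, indices, n, seed_node, lam, status, frontier, nxt)
        tc = 0
        for i in range(n):
            if status[i] == 2 and target_mask[i]:
                tc += 1
        out[t] = tc / m
    return out
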