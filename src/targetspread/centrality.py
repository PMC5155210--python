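"""Baseline node-ranking indices: degree, betweenness, k-shell, local degree.

These are the comparators the target-spreading benchmarks rank RLP against.
Betweenness follows the raw unordered-pair formula b_i = Σ_{a<b, a≠i≠b}
n_ab(i)/n_ab with no normalization; k-shell is the iterative peeling index
(core number). Local degree zeroes the degree of every node farther than a
radius (default 3) from the target set.
"""

from __future__ import annotations

import igraph as ig
import networkx as nx
import numpy as np

from .netcore import Network, ParameterError
from .scores import ScoreVector
from .targets import TargetSet

__all__ = [
    "degree_scores",
    "betweenness_scores",
    "kshell_scores",
    "local_degree_scores",
]


def degree_scores(net: Network) -> ScoreVector:
    """Number of neighbors of each node."""
    return ScoreVector("degree", net.degrees.astype(float))


def betweenness_scores(net: Network) -> ScoreVector:
    """Raw betweenness: per node, the sum over unordered pairs (excluding the
    node) of the fraction of shortest paths passing through it.

    Computed by dependency accumulation (Brandes, via igraph), which equals
    the pair-sum formula exactly for undirected unweighted graphs;
    disconnected pairs contribute 0.
    """
    g = ig.Graph(n=net.n, edges=list(net.edges()))
    return ScoreVector("betweenness", np.asarray(g.betweenness(), dtype=float))


def kshell_scores(net: Network) -> ScoreVector:
    """k-shell (core number) by iterative peeling.

    Stage n repeatedly removes every node of residual degree <= n; nodes
    removed at stage n get ks = n. Nearly constant on WS/BA graphs, which is
    why the evaluation layer lets experiments skip it there.
    """
    ks = nx.core_number(net.to_networkx())
    return ScoreVector("kshell", np.array([ks[i] for i in range(net.n)], dtype=float))


def local_degree_scores(
    net: Network, targets: TargetSet, radius: float = 3
) -> ScoreVector:
    """Degree for nodes within ``radius`` of the target set (Ω), zero outside."""
    if not isinstance(targets, TargetSet) or targets.m == 0:
        raise ParameterError("targets must be a non-empty TargetSet")
    values = net.degrees.astype(float)
    values[targets.distances(net) > radius] = 0.0
    return ScoreVector("local_degree", values, info={"radius": radius})
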