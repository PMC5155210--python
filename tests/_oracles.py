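"""Independent brute-force oracles used only by the tests.

Deliberately naive: explicit enumeration rather than the algorithms the
package uses, so agreement is a real cross-check.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

from targetspread import Network


def floyd_warshall(net: Network) -> np.ndarray:
    n = net.n
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j in net.edges():
        d[i, j] = d[j, i] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d


def all_shortest_paths(net: Network, s: int, t: int) -> list[tuple[int, ...]]:
    """Every shortest s-t path, by BFS layers + DFS enumeration."""
    dist = {s: 0}
    q = deque([s])
    while q:
        i = q.popleft()
        for j in net.adj[i]:
            j = int(j)
            if j not in dist:
                dist[j] = dist[i] + 1
                q.append(j)
    if t not in dist:
        return []
    paths: list[tuple[int, ...]] = []

    def walk(node: int, acc: list[int]):
        if node == s:
            paths.append(tuple(reversed(acc + [s])))
            return
        for j in net.adj[node]:
            j = int(j)
            if dist.get(j, -1) == dist[node] - 1:
                walk(j, acc + [node])

    walk(t, [])
    return paths


def betweenness_by_enumeration(net: Network) -> np.ndarray:
    """b_i = sum over unordered pairs {a,b}, a != i != b, of the fraction of
    all shortest a-b paths whose interior contains i."""
    n = net.n
    b = np.zeros(n)
    for a, c in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(net, a, c)
        if not paths:
            continue
        for i in range(n):
            if i == a or i == c:
                continue
            through = sum(1 for p in paths if i in p[1:-1])
            b[i] += through / len(paths)
    return b


def kendall_by_pairs(x, y, variant: str = "a") -> float:
    """Pairwise-enumeration Kendall tau (tau_a or tie-corrected tau_b)."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n_pairs = n * (n - 1) // 2
    if variant == "a":
        return (conc - disc) / n_pairs
    denom = np.sqrt((n_pairs - tx) * (n_pairs - ty))
    return 0.0 if denom == 0 else (conc - disc) / denom
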