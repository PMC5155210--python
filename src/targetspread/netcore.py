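"""Graph container, edge-list I/O, synthetic generators and shortest-path utilities.

Networks are undirected simple graphs. Node identity is an opaque string label;
all numerics run over dense internal indices ``0..N-1`` assigned in order of
first appearance, and every public score/distance array is indexed that way.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "NetStats",
    "ParameterError",
    "EdgeListFormatError",
    "load_edge_list",
    "load_gml",
    "write_edge_list",
    "generate_ba",
    "generate_ws",
    "generate_gn",
    "bfs_distances",
    "network_stats",
    "hmf_lambda_c",
]


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class EdgeListFormatError(ValueError):
    """A line of an edge-list file could not be parsed."""


def _as_int_seed(rng: np.random.Generator | int | None) -> int:
    """Collapse any accepted random source into a 31-bit integer seed."""
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        return int(rng) % (2**31)
    return int(rng.integers(2**31))


class Network:
    """Undirected simple graph with stable label <-> index mapping.

    Parameters
    ----------
    labels
        Node labels in internal-index order.
    edges
        Iterable of ``(i, j)`` internal-index pairs. Self-loops are dropped and
        duplicates collapsed.
    community
        Optional per-node community assignment (planted-partition metadata).
    """

    __slots__ = ("labels", "_index", "adj", "community", "_csr", "_nx")

    def __init__(
        self,
        labels: Sequence[str],
        edges: Iterable[tuple[int, int]],
        community: np.ndarray | None = None,
    ):
        self.labels: list[str] = [str(x) for x in labels]
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("duplicate node labels")
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        neigh: list[set[int]] = [set() for _ in range(n)]
        for i, j in edges:
            if i == j:
                continue
            neigh[i].add(j)
            neigh[j].add(i)
        self.adj: list[np.ndarray] = [
            np.fromiter(sorted(s), dtype=np.int64, count=len(s)) for s in neigh
        ]
        self.community = community
        self._csr: tuple[np.ndarray, np.ndarray] | None = None
        self._nx: nx.Graph | None = None

    # -- basic protocol ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return self.n

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def index_of(self, node: str | int) -> int:
        """Resolve a label (or pass through an internal index) to an index."""
        if isinstance(node, (int, np.integer)):
            i = int(node)
            if not 0 <= i < self.n:
                raise KeyError(f"node index {i} out of range")
            return i
        try:
            return self._index[str(node)]
        except KeyError:
            raise KeyError(f"unknown node label {node!r}") from None

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self.adj], dtype=np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.degrees.sum()) // 2

    def edges(self) -> Iterable[tuple[int, int]]:
        """Yield each undirected edge once as an (i, j) index pair with i < j."""
        for i, nbrs in enumerate(self.adj):
            for j in nbrs:
                if i < j:
                    yield i, int(j)

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Adjacency in CSR form ``(indptr, indices)`` for the numba kernels."""
        if self._csr is None:
            indptr = np.zeros(self.n + 1, dtype=np.int64)
            indptr[1:] = np.cumsum([len(a) for a in self.adj])
            indices = (
                np.concatenate(self.adj)
                if self.n and indptr[-1] > 0
                else np.empty(0, dtype=np.int64)
            )
            self._csr = (indptr, indices.astype(np.int64))
        return self._csr

    def dense_adjacency(self) -> np.ndarray:
        A = np.zeros((self.n, self.n))
        for i, j in self.edges():
            A[i, j] = A[j, i] = 1.0
        return A

    def to_networkx(self) -> nx.Graph:
        """networkx view on internal indices (cached; treat as read-only)."""
        if self._nx is None:
            g = nx.Graph()
            g.add_nodes_from(range(self.n))
            g.add_edges_from(self.edges())
            self._nx = g
        return self._nx

    @classmethod
    def from_label_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Network":
        """Build from labelled endpoint pairs; first appearance fixes indexing."""
        labels: list[str] = []
        index: dict[str, int] = {}
        idx_pairs: list[tuple[int, int]] = []
        for a, b in pairs:
            for lab in (a, b):
                if lab not in index:
                    index[lab] = len(labels)
                    labels.append(lab)
            idx_pairs.append((index[a], index[b]))
        return cls(labels, idx_pairs)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        labels = [str(v) for v in g.nodes()]
        index = {v: i for i, v in enumerate(g.nodes())}
        return cls(labels, [(index[a], index[b]) for a, b in g.edges()])


@dataclass(frozen=True)
class NetStats:
    """Structural summary: size, degree moments, diameter, epidemic threshold.

    ``lambda_c`` is the heterogeneous-mean-field SIR threshold estimate
    〈k〉/(〈k²〉−〈k〉); it is ``inf`` when the denominator is non-positive
    (e.g. a perfect matching). ``diameter`` is measured within the largest
    connected component.
    """

    n: int
    mean_degree: float
    second_moment: float
    diameter: int
    lambda_c: float


def load_edge_list(path, comment_prefix: str = "#") -> Network:
    """Read a whitespace-delimited edge list.

    Each non-comment, non-blank line contributes one edge; the first two
    tokens are the endpoint labels, any further tokens are ignored.
    Self-loops are dropped and duplicate edges collapsed.
    """
    pairs: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or (comment_prefix and stripped.startswith(comment_prefix)):
                continue
            toks = stripped.split()
            if len(toks) < 2:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected at least two tokens, got {len(toks)}"
                )
            pairs.append((toks[0], toks[1]))
    return Network.from_label_pairs(pairs)


def load_gml(path) -> Network:
    """Read a GML graph (labels only; attributes and weights are ignored)."""
    g = nx.read_gml(path, label="label")
    return Network.from_networkx(g)


def write_edge_list(net: Network, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in net.edges():
            fh.write(f"{net.labels[i]} {net.labels[j]}\n")


def generate_ba(n: int, m_links: int, rng: np.random.Generator | int | None = None) -> Network:
    """Barabási–Albert preferential-attachment graph (connected by construction).

    Each arriving node attaches ``m_links`` edges, so 〈k〉 ≈ 2·m_links
    (e.g. n=500, m_links=2 gives the 〈k〉 = 4 setting used in the synthetic
    benchmarks).
    """
    if m_links < 1 or n <= m_links:
        raise ParameterError(f"require n > m_links >= 1, got n={n}, m_links={m_links}")
    g = nx.barabasi_albert_graph(n, m_links, seed=_as_int_seed(rng))
    return Network.from_networkx(g)


def generate_ws(
    n: int, k_ring: int, p_rewire: float, rng: np.random.Generator | int | None = None
) -> Network:
    """Watts–Strogatz small-world graph; rewiring preserves the edge count n·k/2."""
    if k_ring % 2 != 0:
        raise ParameterError(f"k_ring must be even, got {k_ring}")
    if not 0 <= p_rewire <= 1:
        raise ParameterError(f"p_rewire must be in [0, 1], got {p_rewire}")
    if n <= k_ring:
        raise ParameterError(f"require n > k_ring, got n={n}, k_ring={k_ring}")
    g = nx.watts_strogatz_graph(n, k_ring, p_rewire, seed=_as_int_seed(rng))
    return Network.from_networkx(g)


def generate_gn(
    n_comm: int,
    comm_size: int,
    avg_degree: float,
    frac_in: float,
    rng: np.random.Generator | int | None = None,
) -> Network:
    """Planted-partition (GN-style) community benchmark.

    ``frac_in`` is the expected fraction of a node's links that stay inside
    its community; the expected total degree is ``avg_degree``. The planted
    assignment is kept on ``Network.community``.
    """
    if n_comm < 2 or comm_size < 2:
        raise ParameterError("need n_comm >= 2 and comm_size >= 2")
    if not 0 <= frac_in <= 1:
        raise ParameterError(f"frac_in must be in [0, 1], got {frac_in}")
    p_in = frac_in * avg_degree / (comm_size - 1)
    p_out = (1 - frac_in) * avg_degree / ((n_comm - 1) * comm_size)
    if p_in > 1 or p_out > 1:
        raise ParameterError(
            f"avg_degree={avg_degree} infeasible for community sizes "
            f"(p_in={p_in:.3f}, p_out={p_out:.3f})"
        )
    g = nx.planted_partition_graph(n_comm, comm_size, p_in, p_out, seed=_as_int_seed(rng))
    net = Network.from_networkx(g)
    net.community = np.arange(net.n) // comm_size
    return net


def bfs_distances(net: Network, sources: Iterable[str | int]) -> np.ndarray:
    """Shortest-path distance from each node to the nearest source.

    Returns a float array over internal indices; unreachable nodes get
    ``inf``. Multi-source BFS, so distance is the minimum over sources.
    """
    src = [net.index_of(s) for s in sources]
    if not src:
        raise ParameterError("sources must be non-empty")
    dist = np.full(net.n, np.inf)
    q: deque[int] = deque()
    for s in src:
        if dist[s] > 0:
            dist[s] = 0.0
            q.append(s)
    while q:
        i = q.popleft()
        d1 = dist[i] + 1.0
        for j in net.adj[i]:
            if d1 < dist[j]:
                dist[j] = d1
                q.append(int(j))
    return dist


def hmf_lambda_c(mean_degree: float, second_moment: float) -> float:
    """Heterogeneous-mean-field SIR threshold 〈k〉/(〈k²〉−〈k〉); inf if degenerate."""
    denom = second_moment - mean_degree
    if denom <= 0:
        return math.inf
    return mean_degree / denom


def network_stats(net: Network) -> NetStats:
    """Degree moments, diameter of the largest component, and λc estimate."""
    if net.n < 2:
        raise ParameterError("need at least 2 nodes")
    deg = net.degrees.astype(float)
    mean_k = float(deg.mean())
    k2 = float((deg**2).mean())
    g = net.to_networkx()
    if net.n_edges == 0:
        diameter = 0
    else:
        comp = max(nx.connected_components(g), key=len)
        diameter = int(nx.diameter(g.subgraph(comp)))
    return NetStats(
        n=net.n,
        mean_degree=mean_k,
        second_moment=k2,
        diameter=diameter,
        lambda_c=hmf_lambda_c(mean_k, k2),
    )
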