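"""Target-set construction and the seed-eligibility constraint.

A target set is the group of nodes the spreading is meant to reach. Two
placement schemes are supported: uniformly random members, and localized
members confined to a shortest-path ball of radius ``L`` around a center
node (the center is itself a target). Seeds are by default restricted to
non-target nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .netcore import Network, ParameterError, bfs_distances

__all__ = [
    "TargetSet",
    "InfeasiblePlacementError",
    "place_random",
    "place_localized",
    "candidate_seeds",
]

CENTER_RETRY_BUDGET = 100


class InfeasiblePlacementError(RuntimeError):
    """No feasible center found within the retry budget."""


@dataclass(frozen=True)
class TargetSet:
    """Immutable set of target nodes, as sorted internal indices.

    ``center``/``radius`` record localized-placement metadata and stay
    ``None`` for random placement. ``omega(net)`` gives the radius-3
    neighborhood Ω used by the local-degree index.
    """

    members: tuple[int, ...]
    center: int | None = None
    radius: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(sorted(set(self.members))))
        if not self.members:
            raise ParameterError("target set must be non-empty")
        if self.center is not None and self.center not in set(self.members):
            raise ParameterError("center must be a member of the target set")

    @property
    def m(self) -> int:
        return len(self.members)

    def mask(self, n: int) -> np.ndarray:
        out = np.zeros(n, dtype=bool)
        out[list(self.members)] = True
        return out

    def indicator(self, n: int) -> np.ndarray:
        """The 0/1 row vector f with ones exactly on the targets."""
        return self.mask(n).astype(float)

    def distances(self, net: Network) -> np.ndarray:
        return bfs_distances(net, self.members)

    def omega(self, net: Network, radius: float = 3) -> np.ndarray:
        """Indices of nodes within graph distance ``radius`` of any target."""
        return np.flatnonzero(self.distances(net) <= radius)

    def labels(self, net: Network) -> list[str]:
        return [net.labels[i] for i in self.members]

    @classmethod
    def from_nodes(
        cls,
        net: Network,
        nodes: Iterable[str | int],
        center: str | int | None = None,
        radius: float | None = None,
    ) -> "TargetSet":
        members = tuple(net.index_of(v) for v in nodes)
        c = None if center is None else net.index_of(center)
        return cls(members, center=c, radius=radius)


def place_random(net: Network, m: int, rng: np.random.Generator) -> TargetSet:
    """m distinct targets chosen uniformly at random."""
    if not 1 <= m <= net.n:
        raise ParameterError(f"need 1 <= m <= N, got m={m}, N={net.n}")
    members = rng.choice(net.n, size=m, replace=False)
    return TargetSet(tuple(int(i) for i in members))


def place_localized(
    net: Network,
    m: int,
    L: float,
    rng: np.random.Generator,
    center: str | int | None = None,
) -> TargetSet:
    """Localized placement: the center plus m−1 nodes within distance L of it.

    With ``center=None`` a center is drawn uniformly and re-drawn (up to
    ``CENTER_RETRY_BUDGET`` times) until its radius-L ball holds at least
    m−1 other nodes. ``L = inf`` reduces to random placement on a connected
    graph.
    """
    if m < 1:
        raise ParameterError(f"need m >= 1, got {m}")
    if L < 1:
        raise ParameterError(f"need L >= 1, got {L}")

    def ball(c: int) -> np.ndarray:
        dist = bfs_distances(net, [c])
        hits = np.flatnonzero(dist <= L)
        return hits[hits != c]

    if center is not None:
        c = net.index_of(center)
        candidates = ball(c)
        if len(candidates) < m - 1:
            raise InfeasiblePlacementError(
                f"ball of radius {L} around {net.labels[c]!r} holds "
                f"{len(candidates)} nodes, need {m - 1}"
            )
    else:
        best = -1
        for _ in range(CENTER_RETRY_BUDGET):
            c = int(rng.integers(net.n))
            candidates = ball(c)
            best = max(best, len(candidates))
            if len(candidates) >= m - 1:
                break
        else:
            raise InfeasiblePlacementError(
                f"no center with a radius-{L} ball of >= {m - 1} nodes found in "
                f"{CENTER_RETRY_BUDGET} draws (largest seen: {best})"
            )
    rest = rng.choice(candidates, size=m - 1, replace=False) if m > 1 else []
    members = (c, *(int(i) for i in rest))
    return TargetSet(members, center=c, radius=L)


def candidate_seeds(
    net: Network, targets: TargetSet, allow_target_seeds: bool = False
) -> np.ndarray:
    """Eligible seed nodes in stable index order.

    By default targets cannot be seeds; ``allow_target_seeds=True`` lifts the
    constraint (needed for the global-target benchmark where every node is a
    target).
    """
    if allow_target_seeds:
        return np.arange(net.n, dtype=np.int64)
    mask = ~targets.mask(net.n)
    cands = np.flatnonzero(mask).astype(np.int64)
    if len(cands) == 0:
        raise ParameterError(
            "every node is a target; pass allow_target_seeds=True for the "
            "global-target benchmark"
        )
    return cands
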