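"""Per-node score container shared by all ranking methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netcore import Network

__all__ = ["ScoreVector"]


@dataclass
class ScoreVector:
    """A real-valued score per node, tagged with the method that produced it.

    ``values`` is indexed by internal node index. ``info`` carries method
    diagnostics (e.g. how many nodes the frontier computation touched).
    """

    method: str
    values: np.ndarray
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")
        if np.any(self.values < 0):
            raise ValueError("scores must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i):
        return self.values[i]

    def as_series(self, net: Network) -> pd.Series:
        """Label-indexed view, for CSV output and human inspection."""
        return pd.Series(self.values, index=net.labels, name=self.method)
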