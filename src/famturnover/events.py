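"""Per-branch gain/loss bookkeeping shared by all estimators.

An :class:`EventMap` stores, for every branch ``i`` of a species tree, the
number of gains ``G_i`` and losses ``L_i``, the copy number ``C_i`` at the
branch's ancestral node, and the branch duration ``T_i`` in Myr.  It can
describe a single orthologous group (OG) or the aggregate over many OGs
(fields add across independent OGs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

from .trees import DatedTree

__all__ = ["EventMap"]


@dataclass
class EventMap:
    """Gains, losses, ancestral copy number and duration per branch."""

    branch_ids: List[str]
    G: np.ndarray
    L: np.ndarray
    C: np.ndarray
    T: np.ndarray

    _index: Dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int64)
        self.L = np.asarray(self.L, dtype=np.int64)
        self.C = np.asarray(self.C, dtype=np.int64)
        self.T = np.asarray(self.T, dtype=float)
        k = len(self.branch_ids)
        if not (len(self.G) == len(self.L) == len(self.C) == len(self.T) == k):
            raise ValueError("per-branch arrays must align with branch_ids")
        if np.any(self.T <= 0):
            raise ValueError("all branch durations must be positive")
        if np.any(self.G < 0) or np.any(self.L < 0) or np.any(self.C < 0):
            raise ValueError("gains, losses and copy numbers must be non-negative")
        self._index = {b: i for i, b in enumerate(self.branch_ids)}

    @classmethod
    def zeros(cls, tree: DatedTree) -> "EventMap":
        ids = tree.branch_ids
        T = np.array([tree.branch_duration(b) for b in ids])
        z = np.zeros(len(ids), dtype=np.int64)
        return cls(branch_ids=list(ids), G=z.copy(), L=z.copy(), C=z.copy(), T=T)

    @property
    def n(self) -> int:
        """Number of branches included."""
        return len(self.branch_ids)

    def total_gains(self) -> int:
        return int(self.G.sum())

    def total_losses(self) -> int:
        return int(self.L.sum())

    def gene_time(self) -> float:
        """Total gene-time at risk, ``sum_i C_i * T_i`` (gene x Myr)."""
        return float((self.C * self.T).sum())

    def __add__(self, other: "EventMap") -> "EventMap":
        if self.branch_ids != other.branch_ids:
            raise ValueError("cannot aggregate EventMaps over different branch sets")
        if not np.allclose(self.T, other.T):
            raise ValueError("branch durations differ between EventMaps")
        return EventMap(
            branch_ids=list(self.branch_ids),
            G=self.G + other.G,
            L=self.L + other.L,
            C=self.C + other.C,
            T=self.T.copy(),
        )

    def loc(self, branch_id: str) -> Dict[str, float]:
        i = self._index[branch_id]
        return {"G": int(self.G[i]), "L": int(self.L[i]), "C": int(self.C[i]), "T": float(self.T[i])}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"branch": self.branch_ids, "C": self.C, "G": self.G, "L": self.L, "T": self.T}
        ).set_index("branch")
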