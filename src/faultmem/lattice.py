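"""Torus lattice over memory-probe rake-angle pairs.

The stimulus space is circular on both axes, so the L x L grid of
(memory, probe) angle pairs is a torus: 4-neighbour adjacency with
wrap-around on both axes.  Nodes are indexed (x, y) with x the memory-axis
grid index and y the probe-axis index; the flat ordering is row-major
(``x * L + y``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["TorusLattice", "CountLattice"]


@dataclass(frozen=True)
class TorusLattice:
    """L x L grid of memory-probe angle pairs with toroidal adjacency.

    Parameters
    ----------
    L : int
        Nodes per axis, at least 3 (wrap-around on an L < 3 ring would
        create duplicate edges).  The full-scale stimulus grid has L = 180
        (2-degree steps); tests use coarser grids.
    """

    L: int

    def __post_init__(self):
        if int(self.L) != self.L or self.L < 3:
            raise ValueError(f"L must be an integer >= 3, got {self.L!r}")
        object.__setattr__(self, "L", int(self.L))

    @property
    def step(self) -> float:
        """Grid step in degrees."""
        return 360.0 / self.L

    @property
    def n_nodes(self) -> int:
        return self.L * self.L

    @property
    def angles(self) -> np.ndarray:
        """Grid angles in degrees, shape (L,)."""
        return np.arange(self.L) * self.step

    def angle_to_index(self, angle) -> np.ndarray:
        """Map grid angles (degrees) to axis indices; raises if off-grid."""
        a = np.atleast_1d(np.asarray(angle, dtype=float)) % 360.0
        idx = a / self.step
        rounded = np.rint(idx)
        if not np.allclose(idx, rounded, rtol=0, atol=1e-9):
            bad = np.asarray(angle)[np.abs(idx - rounded) > 1e-9]
            raise ValueError(
                f"angle(s) {bad[:5]} not on the {self.step:g}-degree grid; "
                "refusing to snap"
            )
        return rounded.astype(int) % self.L

    def adjacency(self) -> sp.csr_matrix:
        """Sparse 0/1 adjacency of the torus, shape (L^2, L^2)."""
        eye = sp.identity(self.L, format="csr", dtype=float)
        idx = np.arange(self.L)
        ring = sp.csr_matrix(
            (np.ones(2 * self.L),
             (np.concatenate([idx, idx]),
              np.concatenate([(idx - 1) % self.L, (idx + 1) % self.L]))),
            shape=(self.L, self.L))
        return (sp.kron(ring, eye) + sp.kron(eye, ring)).tocsr()

    def edges(self) -> np.ndarray:
        """Undirected edge list, shape (2*L^2, 2), each edge once (i < j)."""
        coo = sp.triu(self.adjacency(), k=1).tocoo()
        return np.column_stack([coo.row, coo.col])


@dataclass
class CountLattice:
    """Per-node trial counts n and 'change'-response counts k on a lattice."""

    lattice: TorusLattice
    n: np.ndarray = field(default=None)
    k: np.ndarray = field(default=None)

    def __post_init__(self):
        L = self.lattice.L
        if self.n is None:
            self.n = np.zeros((L, L), dtype=np.int64)
        if self.k is None:
            self.k = np.zeros((L, L), dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.k = np.asarray(self.k, dtype=np.int64)
        if self.n.shape != (L, L) or self.k.shape != (L, L):
            raise ValueError(
                f"count arrays must have shape ({L}, {L}); "
                f"got n{self.n.shape}, k{self.k.shape}")
        if (self.n < 0).any() or (self.k < 0).any() or (self.k > self.n).any():
            raise ValueError("counts must satisfy 0 <= k <= n elementwise")

    @property
    def total_trials(self) -> int:
        return int(self.n.sum())
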