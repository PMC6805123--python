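"""Regular areal grids, adjacency structure and spatial summaries.

The landscape is a regular lattice of square cells (500 m side in the
motivating study, i.e. 25 ha each).  Cells are stored flat in row-major
order with row 0 the northernmost row, so cell ``j`` sits at
``(row, col) = divmod(j, n_x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class LandscapeGrid:
    """A regular lattice of ``n_y x n_x`` square cells with covariate layers.

    Parameters
    ----------
    n_x, n_y:
        Grid dimensions in cells (columns, rows).
    cell_size:
        Cell side length in metres.
    covariates:
        Mapping from covariate name to a flat array of length ``n_cells``
        (row-major).
    """

    n_x: int
    n_y: int
    cell_size: float = 500.0
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid dimensions must be positive")
        if self.n_cells < 4:
            raise ValueError("grid must contain at least 4 cells")
        for name, layer in self.covariates.items():
            arr = np.asarray(layer, dtype=float).ravel()
            if arr.size != self.n_cells:
                raise ValueError(
                    f"covariate {name!r} has {arr.size} values, expected {self.n_cells}"
                )
            self.covariates[name] = arr

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the lattice."""
        return (self.n_y, self.n_x)

    def layer_2d(self, name: str) -> np.ndarray:
        return self.covariates[name].reshape(self.shape)

    def covariate_table(self) -> pd.DataFrame:
        """All covariate layers as a cell-indexed DataFrame."""
        return pd.DataFrame(self.covariates)

    def cell_of_rowcol(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        if np.any((row < 0) | (row >= self.n_y) | (col < 0) | (col >= self.n_x)):
            raise ValueError("row/col outside grid")
        return row * self.n_x + col


def build_adjacency(
    grid: LandscapeGrid | tuple[int, int], rule: str = "rook"
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Adjacency matrix A and ICAR precision Q = diag(A 1) - A for a lattice.

    ``rule`` is ``"rook"`` (4 neighbours) or ``"queen"`` (8 neighbours).
    Returns sparse CSR matrices; A is symmetric with zero diagonal and Q has
    zero row sums by construction.
    """
    if isinstance(grid, LandscapeGrid):
        n_y, n_x = grid.shape
    else:
        n_y, n_x = grid
    if n_x * n_y < 2:
        raise ValueError("adjacency undefined for a degenerate 1x1 grid")
    if rule not in ("rook", "queen"):
        raise ValueError(f"unknown adjacency rule {rule!r}")

    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    idx = np.arange(n_x * n_y).reshape(n_y, n_x)
    offsets = [(0, 1), (1, 0)]
    if rule == "queen":
        offsets += [(1, 1), (1, -1)]
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), n_y - max(0, dr))
        c0 = slice(max(0, -dc), n_x - max(0, dc))
        r1 = slice(max(0, dr), n_y - max(0, -dr))
        c1 = slice(max(0, dc), n_x - max(0, -dc))
        rows_i.append(idx[r0, c0].ravel())
        rows_j.append(idx[r1, c1].ravel())
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    data = np.ones(i.size)
    n = n_x * n_y
    a = sp.coo_matrix((data, (i, j)), shape=(n, n))
    a = (a + a.T).tocsr()
    degree = np.asarray(a.sum(axis=1)).ravel()
    q = sp.diags(degree) - a
    return a, q.tocsr()


def morans_i(values: np.ndarray, adjacency: sp.spmatrix) -> float:
    """Moran's I spatial autocorrelation of a flat layer under binary weights.

    I = (n / W0) * (z' A z) / (z' z) with z the centred values and
    W0 the sum of all weights.
    """
    z = np.asarray(values, dtype=float).ravel()
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I undefined for a constant layer")
    w0 = adjacency.sum()
    return float(z.size / w0 * (z @ (adjacency @ z)) / denom)


def is_connected(adjacency: sp.spmatrix) -> bool:
    n_comp, _ = sp.csgraph.connected_components(adjacency, directed=False)
    return n_comp == 1
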