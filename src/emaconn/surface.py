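"""Surface geometry: a lattice stand-in for a cortical surface mesh.

The mapping algorithms only need three things from a surface: a vertex count,
a symmetric adjacency relation (for contiguity / connected components), and a
per-vertex area in mm^2 (for the small-patch removal rule).  A 2-D lattice
with 4-neighborhood adjacency provides all three at desk scale while keeping
the same semantics as a triangulated cortical mesh; any mesh can be supplied
through the same container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


@dataclass(frozen=True)
class SurfaceModel:
    """A vertex set with symmetric adjacency and per-vertex area.

    Parameters
    ----------
    n_vertices : int
        Number of vertices.
    adjacency : scipy.sparse.csr_matrix
        Symmetric, irreflexive boolean vertex-adjacency matrix.
    vertex_area : float
        Area represented by each vertex, in mm^2.
    shape : tuple of int, optional
        (rows, cols) when the surface is a lattice; purely informational.
    """

    n_vertices: int
    adjacency: sparse.csr_matrix
    vertex_area: float
    shape: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_vertices <= 0:
            raise ValueError("n_vertices must be positive")
        if self.vertex_area <= 0:
            raise ValueError("vertex_area must be positive")
        adj = self.adjacency
        if adj.shape != (self.n_vertices, self.n_vertices):
            raise ValueError("adjacency shape does not match n_vertices")
        if adj.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        if (adj != adj.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")

    def neighbors(self, v: int) -> np.ndarray:
        """Indices of vertices adjacent to vertex ``v``."""
        return self.adjacency.indices[
            self.adjacency.indptr[v] : self.adjacency.indptr[v + 1]
        ]

    @property
    def n_edges(self) -> int:
        """Number of undirected adjacency pairs."""
        return self.adjacency.nnz // 2


def make_surface(rows: int, cols: int, vertex_area: float = 1.0) -> SurfaceModel:
    """Build a rows x cols lattice surface with 4-neighborhood adjacency.

    Vertices are numbered row-major.  Requires ``rows >= 3`` and
    ``cols >= 3`` so that every vertex has at least two neighbors.
    """
    if rows < 3 or cols < 3:
        raise ValueError(f"lattice must be at least 3x3, got {rows}x{cols}")
    n = rows * cols
    idx = np.arange(n).reshape(rows, cols)
    pairs = []
    # horizontal and vertical lattice edges
    pairs.append(np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1))
    pairs.append(np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1))
    edges = np.concatenate(pairs, axis=0)
    row_ind = np.concatenate([edges[:, 0], edges[:, 1]])
    col_ind = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sparse.csr_matrix(
        (np.ones(row_ind.size, dtype=bool), (row_ind, col_ind)), shape=(n, n)
    )
    return SurfaceModel(
        n_vertices=n, adjacency=adj, vertex_area=float(vertex_area), shape=(rows, cols)
    )
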