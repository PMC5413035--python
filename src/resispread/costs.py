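"""Least-cost-path cost distances over a resistance surface.

The raster is turned into an undirected movement graph: nodes are cells,
edges connect 4- or 8-neighbours, and each edge weight is the mean of the two
cells' resistance values times the distance between cell centres (cell_size,
or cell_size * sqrt(2) for diagonals).  Pairwise cost distances are shortest
paths on this graph (Dijkstra, via scipy's sparse-graph routines).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist, squareform

from .core import BoundsError, ConfigurationError, PairwiseMatrix, RasterGrid
from .resistance import ResistanceSurface

__all__ = ["build_movement_graph", "least_cost_distance", "euclidean_distance"]

_OFFSETS_4 = ((0, 1), (1, 0))
_OFFSETS_DIAG = ((1, 1), (1, -1))


def build_movement_graph(
    surface: ResistanceSurface,
    connectivity: int = 8,
    averaging: str = "arithmetic",
) -> sparse.csr_matrix:
    """Sparse symmetric weighted adjacency matrix over raster cells.

    Cell (r, c) maps to node index ``r * n_cols + c``.  ``averaging`` selects
    how the two cell resistances combine: ``"arithmetic"`` (default) or
    ``"harmonic"`` (conductance-style averaging, for sensitivity checks).
    """
    if connectivity not in (4, 8):
        raise ConfigurationError(f"connectivity must be 4 or 8, got {connectivity}")
    if averaging not in ("arithmetic", "harmonic"):
        raise ConfigurationError(f"unknown averaging {averaging!r}")
    res = surface.raster.values
    if np.any(res <= 0):
        raise ConfigurationError("resistance surface must be strictly positive")
    n_rows, n_cols = res.shape
    cs = surface.raster.cell_size

    offsets = list(_OFFSETS_4)
    if connectivity == 8:
        offsets += list(_OFFSETS_DIAG)

    rows_i, rows_j, weights = [], [], []
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), n_rows - max(0, dr))
        r1 = slice(max(0, dr), n_rows - max(0, -dr))
        c0 = slice(max(0, -dc), n_cols - max(0, dc))
        c1 = slice(max(0, dc), n_cols - max(0, -dc))
        a = res[r0, c0]
        b = res[r1, c1]
        if averaging == "arithmetic":
            mean = 0.5 * (a + b)
        else:
            mean = 2.0 / (1.0 / a + 1.0 / b)
        dist = cs * (np.sqrt(2.0) if (dr and dc) else 1.0)
        rows_i.append(idx[r0, c0].ravel())
        rows_j.append(idx[r1, c1].ravel())
        weights.append((mean * dist).ravel())

    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    w = np.concatenate(weights)
    n = n_rows * n_cols
    graph = sparse.coo_matrix((np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))), shape=(n, n))
    return graph.tocsr()


def _snap_points(grid: RasterGrid, points: np.ndarray) -> np.ndarray:
    nodes = np.empty(len(points), dtype=np.int64)
    for k, (x, y) in enumerate(points):
        r, c = grid.point_to_cell(x, y)
        nodes[k] = r * grid.n_cols + c
    return nodes


def least_cost_distance(
    surface: ResistanceSurface,
    points,
    connectivity: int = 8,
    averaging: str = "arithmetic",
    ids: list | None = None,
) -> PairwiseMatrix:
    """Pairwise accumulated-cost distances between point locations.

    Points are snapped to the centre of their containing cell; duplicate
    coordinates share a Dijkstra source.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ConfigurationError("points must be an (n, 2) array")
    graph = build_movement_graph(surface, connectivity=connectivity, averaging=averaging)
    nodes = _snap_points(surface.raster, points)
    unique_nodes, inverse = np.unique(nodes, return_inverse=True)
    dist_from_sources = dijkstra(graph, directed=False, indices=unique_nodes)
    full = dist_from_sources[:, unique_nodes]
    values = full[np.ix_(inverse, inverse)].copy()
    # enforce exact symmetry and zero diagonal (Dijkstra is symmetric up to fp order)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    if ids is None:
        ids = list(range(len(points)))
    return PairwiseMatrix(ids=ids, values=values, metric_kind="cost")


def euclidean_distance(points, ids: list | None = None) -> PairwiseMatrix:
    """Straight-line pairwise distances between planar points."""
    points = np.asarray(points, dtype=float)
    values = squareform(pdist(points)) if len(points) > 1 else np.zeros((len(points), len(points)))
    if ids is None:
        ids = list(range(len(points)))
    return PairwiseMatrix(ids=ids, values=values, metric_kind="euclidean")
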