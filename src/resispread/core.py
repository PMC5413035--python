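"""Core containers shared across the pipeline.

Conventions
-----------
* Planar coordinates in metres, origin at the lower-left corner of the grid.
* Raster ``values`` arrays store row 0 as the *top* (northernmost) row, the
  standard on-disk grid convention; coordinate <-> cell conversion happens only
  through :meth:`RasterGrid.point_to_cell` / :meth:`RasterGrid.cell_center` so
  the y-flip lives in exactly one place.
* Genotypes are diploid: each locus holds two integer allele states, with
  ``MISSING`` (-1) marking an untyped allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "RasterGrid",
    "PairwiseMatrix",
    "GenotypeTable",
    "ConfigurationError",
    "AlignmentError",
    "BoundsError",
    "CapacityError",
    "MissingDataError",
    "DegenerateFitError",
    "ExtinctionSignal",
]


class ConfigurationError(ValueError):
    """Invalid parameter or option value."""


class AlignmentError(ValueError):
    """Rasters or matrices do not share a common template."""


class BoundsError(ValueError):
    """A coordinate or index falls outside the grid extent."""


class CapacityError(ValueError):
    """More individuals requested than the habitat can hold."""


class MissingDataError(ValueError):
    """No jointly typed loci for a pair of individuals."""


class DegenerateFitError(ValueError):
    """Regression predictor has zero variance (or too few points)."""


class ExtinctionSignal(RuntimeError):
    """Simulated population went extinct; replicate cannot continue."""


@dataclass
class RasterGrid:
    """A single-band raster on a regular square grid.

    Parameters
    ----------
    values
        2-D float array, row 0 = top row.
    cell_size
        Cell edge length in metres (> 0).
    origin
        (x, y) of the lower-left corner of the grid.
    nodata
        Sentinel for missing cells.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ConfigurationError(f"cell_size must be > 0, got {self.cell_size}")
        mask = self.values != self.nodata
        if not np.all(np.isfinite(self.values[mask])):
            raise ConfigurationError("raster contains non-finite values outside nodata")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_template(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_template(self, other: "RasterGrid") -> None:
        if not self.same_template(other):
            raise AlignmentError(
                "raster templates differ: "
                f"shape {self.shape} vs {other.shape}, "
                f"cell_size {self.cell_size} vs {other.cell_size}, "
                f"origin {self.origin} vs {other.origin}"
            )

    # --- coordinate conversion (the only y-flip in the package) -----------

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing planar point (x, y).

        Cells are half-open intervals; points on the top/right outer edge
        belong to the last cell.
        """
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row_from_bottom = int(np.floor((y - self.origin[1]) / self.cell_size))
        # points exactly on the outer boundary snap inward
        if col == self.n_cols and np.isclose(x, self.origin[0] + self.n_cols * self.cell_size):
            col -= 1
        if row_from_bottom == self.n_rows and np.isclose(
            y, self.origin[1] + self.n_rows * self.cell_size
        ):
            row_from_bottom -= 1
        if not (0 <= col < self.n_cols and 0 <= row_from_bottom < self.n_rows):
            raise BoundsError(f"point ({x}, {y}) outside raster extent")
        return self.n_rows - 1 - row_from_bottom, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (self.n_rows - 1 - row + 0.5) * self.cell_size
        return x, y

    def cell_centers(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`cell_center`; returns an (n, 2) array."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = self.origin[0] + (cols + 0.5) * self.cell_size
        y = self.origin[1] + (self.n_rows - 1 - rows + 0.5) * self.cell_size
        return np.column_stack([x, y])

    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2


@dataclass
class PairwiseMatrix:
    """Symmetric matrix of pairwise distances between named individuals."""

    ids: list
    values: np.ndarray
    metric_kind: str  # genetic | cost | euclidean

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ConfigurationError("matrix shape does not match number of ids")
        if self.metric_kind not in ("genetic", "cost", "euclidean"):
            raise ConfigurationError(f"unknown metric_kind {self.metric_kind!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def require_ids(self, other: "PairwiseMatrix") -> None:
        if list(self.ids) != list(other.ids):
            raise AlignmentError("pairwise matrices do not share ids")

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) entries as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes with sampling coordinates.

    ``genotypes`` has shape (N, L, 2) with integer allele states and
    ``MISSING`` for untyped alleles.
    """

    ids: list
    coordinates: np.ndarray  # (N, 2)
    genotypes: np.ndarray  # (N, L, 2) int
    locus_names: list = field(default_factory=list)
    sex: np.ndarray | None = None  # optional, 0 = male, 1 = female

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ConfigurationError("duplicate individual ids")
        if self.coordinates.shape != (n, 2):
            raise ConfigurationError("coordinates must have shape (N, 2)")
        if self.genotypes.ndim != 3 or self.genotypes.shape[0] != n or self.genotypes.shape[2] != 2:
            raise ConfigurationError("genotypes must have shape (N, L, 2)")
        if not self.locus_names:
            self.locus_names = [f"L{k + 1}" for k in range(self.n_loci)]
        if len(self.locus_names) != self.n_loci:
            raise ConfigurationError("locus_names length does not match genotypes")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]
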