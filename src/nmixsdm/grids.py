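"""Planar raster containers: environmental stacks, occurrences, binary range maps.

Grid convention: row-major arrays with row 0 at the top (north); the origin
(x0, y0) is the lower-left corner of the grid. Points are assigned to cells
by half-open intervals [edge, edge + cell_size). Coordinates are planar
meters; no CRS handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    n_rows: int
    n_cols: int
    cell_size: float  # meters
    x0: float = 0.0   # lower-left corner
    y0: float = 0.0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1 or self.cell_size <= 0:
            raise ValueError("grid dimensions and cell size must be positive")

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of each point; indices may fall outside the grid."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = self.n_rows - 1 - np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        return row, col

    def inside(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_centers(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y0 + (self.n_rows - np.asarray(row) - 0.5) * self.cell_size
        return x, y


@dataclass
class EnvStack:
    """Named, geometry-aligned environmental layers with a shared validity mask."""

    geometry: GridGeometry
    layers: dict[str, np.ndarray]
    mask: np.ndarray | None = None  # True where the cell is valid (land)

    def __post_init__(self):
        shape = (self.geometry.n_rows, self.geometry.n_cols)
        for name, arr in self.layers.items():
            if np.shape(arr) != shape:
                raise ValueError(f"layer {name!r} has shape {np.shape(arr)}, expected {shape}")
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        elif np.shape(self.mask) != shape:
            raise ValueError("mask does not match grid shape")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def values_at(self, x: np.ndarray, y: np.ndarray,
                  names: list[str] | None = None) -> np.ndarray:
        """Feature matrix (n_points x n_layers) of layer values at point locations."""
        names = names if names is not None else self.layer_names
        row, col = self.geometry.cell_of(x, y)
        if not np.all(self.geometry.inside(row, col)):
            raise ValueError("some points fall outside the grid")
        return np.column_stack([self.layers[n][row, col] for n in names])

    def valid_cell_features(self, names: list[str] | None = None
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rows, cols, feature matrix) over valid cells in row-major order."""
        names = names if names is not None else self.layer_names
        rows, cols = np.nonzero(self.mask)
        X = np.column_stack([self.layers[n][rows, cols] for n in names])
        return rows, cols, X


@dataclass
class OccurrenceSet:
    """Presence points for one species. points is an (n, 2) array of (x, y)."""

    species: str
    points: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not self.provenance:
            self.provenance = ["unspecified"] * len(self.points)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BinaryRangeMap:
    """Thresholded presence/absence grid; presence defined on valid cells only."""

    geometry: GridGeometry
    presence: np.ndarray          # bool grid
    mask: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self):
        shape = (self.geometry.n_rows, self.geometry.n_cols)
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != shape:
            raise ValueError("presence grid does not match geometry")
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        self.presence = self.presence & self.mask

    @property
    def n_presence_cells(self) -> int:
        return int(self.presence.sum())


def check_same_geometry(*items) -> GridGeometry:
    geom = items[0].geometry
    for it in items[1:]:
        if it.geometry != geom:
            raise ValueError("grid geometries do not match")
    return geom
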