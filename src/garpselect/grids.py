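"""Planar raster grid geometry and named covariate stacks.

Conventions used throughout the package (asserted in the test suite):
arrays are 0-based row-major with row 0 at the *north* edge; coordinates
are cell centroids, x increasing east and y increasing north; the grid is
planar (degree units, no great-circle correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular planar grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions (>= 1).
    resolution : float
        Cell size in map units (degrees), > 0. Cells are square.
    origin_x, origin_y : float
        Coordinates of the lower-left (south-west) corner of the grid.
        The centroid of the cell in column ``j`` is
        ``origin_x + (j + 0.5) * resolution``; the centroid of the cell in
        row ``i`` (row 0 at the north edge) is
        ``origin_y + (n_rows - i - 0.5) * resolution``.
    """

    n_rows: int
    n_cols: int
    resolution: float
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer grid edges."""
        return (
            self.origin_x,
            self.origin_x + self.n_cols * self.resolution,
            self.origin_y,
            self.origin_y + self.n_rows * self.resolution,
        )

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.resolution

    def y_centers(self) -> np.ndarray:
        """Centroid y per row, row 0 first (north to south)."""
        rows = np.arange(self.n_rows)
        return self.origin_y + (self.n_rows - rows - 0.5) * self.resolution

    def centroid(self, row: np.ndarray | int, col: np.ndarray | int):
        """Centroid coordinates (x, y) of cell(s) at (row, col)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.resolution
        y = self.origin_y + (self.n_rows - np.asarray(row) - 0.5) * self.resolution
        return x, y

    def cell_of(self, x: np.ndarray | float, y: np.ndarray | float):
        """(row, col) of the cell containing point(s) (x, y).

        Raises ValueError if any point falls outside the grid extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.resolution).astype(np.int64)
        row_s = np.floor((y - self.origin_y) / self.resolution).astype(np.int64)
        # points exactly on the east/north outer edge belong to the last cell
        col = np.where((col == self.n_cols) & np.isclose(x, self.extent[1]), col - 1, col)
        row_s = np.where(
            (row_s == self.n_rows) & np.isclose(y, self.extent[3]), row_s - 1, row_s
        )
        row = self.n_rows - 1 - row_s
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"point ({x.flat[i]}, {y.flat[i]}) lies outside the grid extent "
                f"{self.extent}"
            )
        return row, col

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "resolution": self.resolution,
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


class Landscape:
    """Ordered stack of co-registered covariate rasters on a common grid.

    Parameters
    ----------
    grid : GridSpec
    covariates : dict of name -> 2-D array
        Insertion order is the covariate order. All arrays must match the
        grid shape and names must be unique (guaranteed by the dict).
    """

    def __init__(self, grid: GridSpec, covariates: dict[str, np.ndarray]):
        if not covariates:
            raise ValueError("a Landscape needs at least one covariate")
        self.grid = grid
        self.covariates: dict[str, np.ndarray] = {}
        for name, arr in covariates.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != grid.shape:
                raise ValueError(
                    f"covariate {name!r} has shape {arr.shape}, "
                    f"expected grid shape {grid.shape}"
                )
            self.covariates[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.covariates)

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.covariates[name]

    def __contains__(self, name: str) -> bool:
        return name in self.covariates

    def feature_matrix(self) -> np.ndarray:
        """All cells as a (n_cells, n_covariates) matrix, row-major cell order."""
        return np.column_stack([a.ravel() for a in self.covariates.values()])

    def values_at(self, xy: np.ndarray) -> np.ndarray:
        """Covariate values at point locations; xy is (n, 2) of (x, y)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        row, col = self.grid.cell_of(xy[:, 0], xy[:, 1])
        return np.column_stack([a[row, col] for a in self.covariates.values()])

    def value_range(self, name: str) -> tuple[float, float]:
        a = self.covariates[name]
        return float(np.nanmin(a)), float(np.nanmax(a))

    def subset(self, names: list[str]) -> "Landscape":
        missing = [n for n in names if n not in self.covariates]
        if missing:
            raise KeyError(f"covariates not in landscape: {missing}")
        return Landscape(self.grid, {n: self.covariates[n] for n in names})
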