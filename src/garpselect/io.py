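"""Raster and point I/O, occurrence handling, and experiment configuration.

Rasters are read and written as ESRI ASCII grids (.asc) — a plain-text
format carrying the grid geometry in its header; no-data cells round-trip
as NaN. Landscapes are stored one file per covariate plus a JSON sidecar
with the grid spec, variogram specs and seeds. Occurrences are CSV with
x,y (and optional species_id) columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSpec, Landscape

NODATA_DEFAULT = -9999.0


# ---------------------------------------------------------------- ascii grids
def write_raster(path: str | Path, grid: GridSpec, array: np.ndarray,
                 nodata: float = NODATA_DEFAULT) -> None:
    """Write a 2-D array (row 0 = north) as an ESRI ASCII grid."""
    array = np.asarray(array, dtype=float)
    if array.shape != grid.shape:
        raise ValueError(f"array shape {array.shape} does not match grid {grid.shape}")
    out = np.where(np.isnan(array), nodata, array)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y!r}\n"
        f"cellsize {grid.resolution!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.17g")


def read_raster(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; no-data cells become NaN.

    Supports both xllcorner/yllcorner and xllcenter/yllcenter headers.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = 0
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    res = float(header["cellsize"])
    if "xllcorner" in header:
        ox, oy = header["xllcorner"], header["yllcorner"]
    else:
        ox, oy = header["xllcenter"] - res / 2, header["yllcenter"] - res / 2
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {data.shape} != header ({n_rows}, {n_cols})")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return GridSpec(n_rows=n_rows, n_cols=n_cols, resolution=res, origin_x=ox, origin_y=oy), data


def write_landscape(directory: str | Path, landscape: Landscape, meta: dict | None = None) -> None:
    """Write one .asc per covariate plus a landscape.json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in landscape.covariates.items():
        write_raster(directory / f"{name}.asc", landscape.grid, arr)
    sidecar = {"grid": landscape.grid.to_dict(), "covariates": landscape.names,
               **(meta or {})}
    (directory / "landscape.json").write_text(json.dumps(sidecar, indent=1))


def read_landscape(directory: str | Path) -> Landscape:
    """Read a landscape directory written by :func:`write_landscape`.

    Without a sidecar, all .asc files in the directory are stacked in
    name order. Rasters with mismatched grids raise an error naming the
    offending file.
    """
    directory = Path(directory)
    sidecar = directory / "landscape.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        names = meta["covariates"]
        paths = [directory / f"{n}.asc" for n in names]
    else:
        paths = sorted(directory.glob("*.asc"))
        names = [p.stem for p in paths]
    if not paths:
        raise FileNotFoundError(f"no .asc rasters in {directory}")
    grid = None
    covs: dict[str, np.ndarray] = {}
    for name, p in zip(names, paths):
        g, arr = read_raster(p)
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError(f"raster {p.name} has grid {g}, expected {grid}")
        covs[name] = arr
    return Landscape(grid, covs)


# -------------------------------------------------------------------- points
def read_points(path: str | Path) -> np.ndarray:
    """Read occurrence points from CSV with x,y (or longitude,latitude) columns."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for xc, yc in (("x", "y"), ("longitude", "latitude"), ("lon", "lat")):
        if xc in cols and yc in cols:
            pts = df[[cols[xc], cols[yc]]].to_numpy(dtype=float)
            if not np.all(np.isfinite(pts)):
                raise ValueError(f"{path}: non-finite coordinates")
            return pts
    raise ValueError(f"{path}: no x/y or longitude/latitude columns found")


def write_points(path: str | Path, points: np.ndarray, species_id: str | None = None) -> None:
    df = pd.DataFrame(np.asarray(points), columns=["x", "y"])
    if species_id is not None:
        df.insert(0, "species_id", species_id)
    df.to_csv(path, index=False)


def spatially_unique(points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Reduce points to one per occupied grid cell, at the cell centroid.

    Order-stable: cells appear in the order their first point appears.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    row, col = grid.cell_of(points[:, 0], points[:, 1])
    keys = row * grid.n_cols + col
    _, first = np.unique(keys, return_index=True)
    first.sort()
    x, y = grid.centroid(row[first], col[first])
    return np.column_stack([x, y])


def external_split(
    points: np.ndarray,
    fraction: float = 0.75,
    seed: int | np.random.SeedSequence | None = 0,
    rounding: str = "half_up",
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random train/test partition of occurrence points.

    Same contract as :func:`garpselect.garp.internal_split`; kept separate
    because it is applied once, before modelling, to reserve an external
    evaluation set.
    """
    from .garp import internal_split

    return internal_split(points, fraction, seed, rounding)


# -------------------------------------------------------------------- config
@dataclasses.dataclass
class ExperimentConfig:
    """All tunables of an experiment, with the study's default values."""

    # landscape
    desk_scale: bool = True
    n_exponential: int = 5
    n_spherical: int = 5
    # species
    scenario: str = "strong"
    n_true_vars: int = 3
    n_presence_points: int = 50
    # GA engine
    n_models: int = 200
    n_rules: int = 50
    max_iter: int = 1000
    tol: float = 0.01
    resample_size: int = 1250
    background_pool: int = 5000
    train_fraction: float = 0.75
    rounding: str = "half_up"
    # best subset
    omission_threshold: float = 10.0
    n_low_omission: int = 20
    commission_window: float = 0.5
    # UI
    ui_threshold: float = 0.5
    coverage_target: float = 0.90
    # seeds
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_json(Path(path).read_text())
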