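"""Raster lattice, plain-text raster I/O and latitude-correct cell areas.

All rasters in the package live on a shared geographic lattice (`Grid`):
north-up row-major arrays on a regular longitude/latitude grid. Files are
exchanged in the ESRI ASCII grid format, which keeps every artifact
human-readable and diff-able.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError, ShapeError

#: mean Earth radius in metres (IUGG)
EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class Grid:
    """A north-up regular lon/lat lattice.

    ``lat_origin``/``lon_origin`` are the coordinates of the *south-west*
    corner of the raster (the ESRI ``xllcorner``/``yllcorner`` convention);
    row 0 of every array is the northernmost row.
    """

    rows: int
    cols: int
    cell_size: float  # degrees
    lat_origin: float  # degrees, south edge
    lon_origin: float = 100.0  # degrees, west edge

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise DataError(f"grid must be at least 2x2, got {self.rows}x{self.cols}")
        if self.cell_size <= 0:
            raise DataError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row center, row 0 northernmost."""
        top = self.lat_origin + self.rows * self.cell_size
        return top - (np.arange(self.rows) + 0.5) * self.cell_size

    def lon_centers(self) -> np.ndarray:
        return self.lon_origin + (np.arange(self.cols) + 0.5) * self.cell_size

    def check(self, array: np.ndarray, name: str = "raster") -> np.ndarray:
        arr = np.asarray(array)
        if arr.shape != self.shape:
            raise ShapeError(f"{name} has shape {arr.shape}, expected {self.shape}")
        return arr


def cell_area_ha(grid: Grid) -> np.ndarray:
    """Spherical area of every cell in hectares, as a (rows, cols) array.

    area = R^2 * dlon * (sin(lat_top) - sin(lat_bottom)); constant along a row.
    """
    dlam = math.radians(grid.cell_size)
    top = grid.lat_origin + grid.rows * grid.cell_size
    lat_top = np.radians(top - np.arange(grid.rows) * grid.cell_size)
    lat_bot = lat_top - math.radians(grid.cell_size)
    row_m2 = EARTH_RADIUS_M**2 * dlam * (np.sin(lat_top) - np.sin(lat_bot))
    return np.broadcast_to((row_m2 / 1e4)[:, None], grid.shape).copy()


def total_area_mha(mask: np.ndarray, grid: Grid) -> float:
    """Total area (Mha) of the True cells of a boolean mask."""
    areas = cell_area_ha(grid)
    return float(areas[np.asarray(mask, bool)].sum() / 1e6)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii(path: str | Path, array: np.ndarray, grid: Grid,
                nodata: float = -9999) -> None:
    arr = grid.check(np.asarray(array, dtype=float), str(path))
    out = np.where(np.isnan(arr), nodata, arr)
    header = (
        f"ncols {grid.cols}\n"
        f"nrows {grid.rows}\n"
        f"xllcorner {grid.lon_origin:.6f}\n"
        f"yllcorner {grid.lat_origin:.6f}\n"
        f"cellsize {grid.cell_size:.8f}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii(path: str | Path) -> tuple[np.ndarray, Grid, float]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    grid = Grid(rows=int(meta["nrows"]), cols=int(meta["ncols"]),
                cell_size=meta["cellsize"], lat_origin=meta["yllcorner"],
                lon_origin=meta["xllcorner"])
    data = data.reshape(grid.shape)
    nodata = meta.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    return data, grid, nodata


def regrid_nearest(array: np.ndarray, src: Grid, dst: Grid) -> np.ndarray:
    """Nearest-neighbour resampling between overlapping lattices.

    Category-preserving; convenience only — the fusion operations require
    their inputs on a common grid.
    """
    src.check(array, "source raster")
    dlat = dst.lat_centers()
    dlon = dst.lon_centers()
    src_top = src.lat_origin + src.rows * src.cell_size
    r = np.clip(((src_top - dlat) / src.cell_size).astype(int), 0, src.rows - 1)
    c = np.clip(((dlon - src.lon_origin) / src.cell_size).astype(int), 0, src.cols - 1)
    return np.asarray(array)[np.ix_(r, c)]
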