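"""Planar gridded fields and text raster I/O.

All spatial data in this package live on regular square-cell grids in a
planar metric coordinate system (x, y in metres).  Grids are stored
raster-style: ``values[0, 0]`` is the north-west (top-left) cell and row
index increases southward.  Cell membership is half-open:
``x in [x0 + col*dx, x0 + (col+1)*dx)`` and likewise for y, so a point
exactly on a shared edge belongs to the cell on its east/north side.

Grids are serialized as ESRI ASCII grids (``.asc``), a plain-text raster
format with a six-line header, which keeps fixtures and outputs
human-readable and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class Grid:
    """A single-band raster on a planar metric grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; ``np.nan`` marks no-data cells.
    cell_size : float
        Cell edge length in metres.
    origin : tuple of float
        ``(x0, y0)`` coordinates of the lower-left corner of the
        lower-left cell, in metres.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid footprint."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        return (x0, x0 + ncols * self.cell_size, y0, y0 + nrows * self.cell_size)

    def contains(self, x, y) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing (x, y), half-open convention."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nrows = self.values.shape[0]
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        row = nrows - 1 - row_from_bottom
        return row, col

    def lookup(self, x, y):
        """Nearest-cell value at planar coordinates; scalar in, scalar out."""
        scalar = np.isscalar(x) and np.isscalar(y)
        inside = self.contains(x, y)
        if not np.all(inside):
            bad = np.argwhere(~np.atleast_1d(inside)).ravel()
            raise ValueError(
                f"{bad.size} point(s) outside grid extent {self.extent}; "
                f"first offending index {bad[0]}"
            )
        row, col = self.index_of(x, y)
        out = self.values[row, col]
        return float(out) if scalar else out

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-center coordinates, same shape as values."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (nrows - 1 - np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def copy_with(self, values: np.ndarray) -> "Grid":
        return Grid(np.asarray(values, dtype=float), self.cell_size, self.origin)


def write_ascii_grid(grid: Grid, path) -> None:
    """Write a grid as an ESRI ASCII raster (plain text)."""
    nrows, ncols = grid.values.shape
    vals = np.where(np.isnan(grid.values), NODATA, grid.values)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {NODATA}\n"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"shape mismatch reading {path}")
    return Grid(
        values,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )


@dataclass
class Isoscape:
    """Paired mean/SD grids of bioavailable 87Sr/86Sr with metadata.

    The mean grid is the predicted ratio surface; the SD grid is the
    per-cell 1-sigma spatial uncertainty.  Both share georeferencing.
    """

    mean: Grid
    sd: Grid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd grids must share a shape")
        if self.mean.cell_size != self.sd.cell_size or self.mean.origin != self.sd.origin:
            raise ValueError("mean and sd grids must share georeferencing")
        sd_vals = self.sd.values[~np.isnan(self.sd.values)]
        if sd_vals.size and not np.all(sd_vals > 0):
            raise ValueError("sd grid must be strictly positive")

    @property
    def mean_grid(self) -> np.ndarray:
        return self.mean.values

    @property
    def sd_grid(self) -> np.ndarray:
        return self.sd.values

    @property
    def cell_size(self) -> float:
        return self.mean.cell_size

    @property
    def origin(self) -> tuple[float, float]:
        return self.mean.origin

    def write(self, mean_path, sd_path) -> None:
        write_ascii_grid(self.mean, mean_path)
        write_ascii_grid(self.sd, sd_path)

    @classmethod
    def read(cls, mean_path, sd_path, metadata: dict | None = None) -> "Isoscape":
        return cls(read_ascii_grid(mean_path), read_ascii_grid(sd_path), metadata or {})
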