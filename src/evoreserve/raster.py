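"""Gridded-raster infrastructure: grids, layer stacks, ESRI ASCII I/O.

All rasters in the package share a :class:`Grid`: row 0 is the top of the
map, coordinates are in abstract map units and cell centres are used as
point locations.  Rasters are stored as plain ``numpy`` arrays; persistent
form is the ESRI ASCII grid (a text format every GIS reads).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Geometry of a raster: dimensions, cell size and top-left origin."""

    nrows: int
    ncols: int
    cellsize: float = 1.0
    x0: float = 0.0
    y0: float = None  # y of the top-left corner; default nrows*cellsize

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError(f"grid dimensions must be positive, got {self.nrows}x{self.ncols}")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if self.y0 is None:  # lower-left corner at the map origin
            object.__setattr__(self, "y0", self.nrows * self.cellsize)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of the centre of cell (row, col)."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.cellsize
        y = self.y0 - (np.asarray(row) + 0.5) * self.cellsize
        return x, y

    def cell_of(self, x: np.ndarray | float, y: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing map point (x, y)."""
        col = np.floor((np.asarray(x) - self.x0) / self.cellsize).astype(int)
        row = np.floor((self.y0 - np.asarray(y)) / self.cellsize).astype(int)
        return row, col

    def coord_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (nrows, ncols) arrays of cell-centre x (lon) and y (lat)."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        return self.cell_center(rows, cols)


@dataclass
class LandscapeStack:
    """A set of aligned real-valued raster layers with a shared validity mask."""

    grid: Grid
    layers: dict[str, np.ndarray]
    mask: np.ndarray = field(default=None)  # True where valid

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not self.mask.any():
            raise ValueError("stack must contain at least one valid cell")
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")

    @property
    def var_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_vars(self) -> int:
        return len(self.layers)

    def values_at(self, rows: np.ndarray, cols: np.ndarray, names: Iterable[str] | None = None) -> np.ndarray:
        """(n_points, n_vars) matrix of layer values at the given cells."""
        names = list(names) if names is not None else self.var_names
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def valid_matrix(self, names: Iterable[str] | None = None) -> np.ndarray:
        """(n_valid_cells, n_vars) matrix of layer values over the mask."""
        names = list(names) if names is not None else self.var_names
        return np.column_stack([self.layers[n][self.mask] for n in names])

    def subset(self, names: Iterable[str]) -> "LandscapeStack":
        names = list(names)
        return LandscapeStack(self.grid, {n: self.layers[n] for n in names}, self.mask)


def write_ascii_grid(path, array: np.ndarray, grid: Grid, mask: np.ndarray | None = None) -> None:
    """Write an array as an ESRI ASCII grid; masked cells become NODATA."""
    arr = np.array(array, dtype=float)
    if mask is not None:
        arr = np.where(mask, arr, NODATA)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x0}\n"
        f"yllcorner {grid.y0 - grid.nrows * grid.cellsize}\n"
        f"cellsize {grid.cellsize}\n"
        f"NODATA_value {NODATA}\n"
    )
    buf = io.StringIO()
    np.savetxt(buf, arr, fmt="%.10g")
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(buf.getvalue())


def read_ascii_grid(path) -> tuple[np.ndarray, Grid, np.ndarray]:
    """Read an ESRI ASCII grid; returns (array, grid, mask) with NaN at NODATA."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    arr = np.loadtxt(io.StringIO("".join(lines[i:])))
    arr = np.atleast_2d(arr)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if arr.shape != (nrows, ncols):
        raise ValueError(f"data shape {arr.shape} does not match header {nrows}x{ncols}")
    cellsize = header.get("cellsize", 1.0)
    grid = Grid(
        nrows=nrows,
        ncols=ncols,
        cellsize=cellsize,
        x0=header.get("xllcorner", 0.0),
        y0=header.get("yllcorner", 0.0) + nrows * cellsize,
    )
    nodata = header.get("nodata_value", NODATA)
    mask = arr != nodata
    out = arr.astype(float)
    out[~mask] = np.nan
    return out, grid, mask
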