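"""Regular-grid rasters in a projected metric CRS.

A :class:`GridRaster` is a row-major array with cell-centre registration:
row 0 is the *northern* edge, and the centre of cell ``(row, col)`` sits at
``(origin_x + (col + 0.5) * cell_size, origin_y + (n_rows - row - 0.5) * cell_size)``.
Point-in-cell lookups use half-open intervals ``[edge, edge + cell_size)`` so
that every point inside the extent maps to exactly one cell.

Rasters round-trip through the ESRI ASCII grid format, which keeps every
artefact plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class RasterError(ValueError):
    """Invalid raster geometry or content."""


@dataclass
class GridRaster:
    """A single-band raster on a regular metric grid.

    Parameters
    ----------
    origin_x, origin_y : float
        Coordinates (m) of the lower-left corner of the grid.
    cell_size : float
        Cell edge length in metres; cells are square.
    values : ndarray of shape (n_rows, n_cols)
        Cell values, row 0 at the top (north).
    nodata : float
        Sentinel for missing cells.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise RasterError("values must be a 2-D array")
        if self.cell_size <= 0:
            raise RasterError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise RasterError("raster must have at least one cell")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.width,
            self.origin_y + self.height,
        )

    def like(self, values: np.ndarray, nodata: float | None = None) -> "GridRaster":
        """New raster sharing this grid's geometry."""
        return GridRaster(
            self.origin_x,
            self.origin_y,
            self.cell_size,
            np.asarray(values),
            self.nodata if nodata is None else nodata,
        )

    def same_grid(self, other: "GridRaster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
        )

    # -- coordinate transforms ------------------------------------------------

    def cell_of(self, x, y):
        """Map point coordinates to (row, col) indices (half-open cells)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = self.n_rows - 1 - np.floor((y - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y):
        """True where the point falls inside the grid extent (half-open)."""
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def value_at(self, x, y):
        """Cell value at point coordinates; caller must ensure containment."""
        row, col = self.cell_of(x, y)
        return self.values[row, col]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, shaped like values."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)


def distance_transform(source: GridRaster) -> GridRaster:
    """Euclidean distance (m) from each cell centre to the nearest source cell.

    ``source.values`` is interpreted as a boolean mask (nonzero = source).
    Source cells get distance 0.  Exact Euclidean distances between cell
    centres, computed with the exact EDT of ``scipy.ndimage``.

    Raises
    ------
    RasterError
        If no source cell exists (distances would be undefined everywhere).
    """
    mask = np.asarray(source.values) != 0
    if not mask.any():
        raise RasterError("distance transform undefined: no source cells")
    dist = ndimage.distance_transform_edt(~mask, sampling=source.cell_size)
    return source.like(dist.astype(float))


# -- ESRI ASCII grid I/O ------------------------------------------------------

def write_ascii_grid(raster: GridRaster, path) -> None:
    """Write a raster as an ESRI ASCII grid (plain text)."""
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.origin_x!r}\n"
        f"yllcorner {raster.origin_y!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.10g")


def read_ascii_grid(path) -> GridRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise RasterError("ASCII grid body does not match its header")
    return GridRaster(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        values=values,
        nodata=header["nodata_value"],
    )
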