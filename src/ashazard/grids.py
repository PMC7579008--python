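"""Lightweight georeferenced raster grids.

All rasters in the package share one convention: a regular geographic
(longitude/latitude) grid defined by its lower-left corner, a square cell
size in degrees, and a shape.  Arrays are stored with row 0 at the *southern*
edge so that ``row = floor((lat - lat0) / cell_size)`` — the ESRI ASCII grid
on disk is north-up and is flipped on read/write.  Nodata is ``NaN`` in
memory and an explicit sentinel on disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "RasterGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    Parameters
    ----------
    lon0, lat0:
        Coordinates of the lower-left (south-west) corner of the grid, in
        degrees.
    cell_size:
        Edge length of a (square) cell in degrees.  The default used
        throughout the package is 1/120 degree, i.e. 30 arc-seconds
        (about 1 km at the equator).
    nrows, ncols:
        Grid shape.
    """

    lon0: float
    lat0: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError(f"grid shape must be positive, got {self.nrows}x{self.ncols}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def lon_max(self) -> float:
        return self.lon0 + self.ncols * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat0 + self.nrows * self.cell_size

    def cell_of(self, lon, lat):
        """Map coordinates to (row, col) using half-open cell intervals.

        A cell owns ``[edge, edge + cell_size)``; points lying exactly on the
        outer max boundary are assigned to the last row/column so the full
        closed extent is covered.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon0) / self.cell_size).astype(np.int64)
        row = np.floor((lat - self.lat0) / self.cell_size).astype(np.int64)
        col = np.where((lon == self.lon_max), self.ncols - 1, col)
        row = np.where((lat == self.lat_max), self.nrows - 1, row)
        return row, col

    def contains(self, lon, lat):
        """Boolean mask: inside the closed grid extent."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon0)
            & (lon <= self.lon_max)
            & (lat >= self.lat0)
            & (lat <= self.lat_max)
        )

    def center_of(self, row, col):
        """Coordinates of cell centers for (row, col) indices."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.lon0 + (col + 0.5) * self.cell_size
        lat = self.lat0 + (row + 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self):
        """(lon, lat) arrays of shape (nrows, ncols) with every cell center."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        return self.center_of(rows, cols)


@dataclass
class RasterGrid:
    """A single-band raster: a float array on a :class:`GridSpec`.

    Nodata cells hold ``NaN``.  Categorical rasters store integer category
    codes as floats; their identity as categorical is tracked by the caller
    (e.g. :class:`ashazard.synthetic.Landscape`).
    """

    spec: GridSpec
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.spec.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.spec.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.data)

    def values_at(self, lon, lat):
        """Sample the raster at point coordinates (NaN outside the extent)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        inside = self.spec.contains(lon, lat)
        row, col = self.spec.cell_of(lon, lat)
        out = np.full(np.shape(lon), np.nan, dtype=float)
        r = row[inside]
        c = col[inside]
        out[inside] = self.data[r, c]
        return out

    def copy_with(self, data: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.spec, np.asarray(data, dtype=float))


def same_grid(*rasters: RasterGrid) -> bool:
    first = rasters[0].spec
    return all(r.spec == first for r in rasters[1:])


def require_coregistered(**rasters: RasterGrid) -> None:
    """Raise with the offending names if rasters are not on one grid."""
    items = list(rasters.items())
    ref_name, ref = items[0]
    for name, r in items[1:]:
        if r.spec != ref.spec:
            raise ValueError(
                f"rasters not co-registered: '{name}' grid {r.spec} differs from "
                f"'{ref_name}' grid {ref.spec}"
            )


def write_ascii_grid(raster: RasterGrid, path: str | Path, nodata_value: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (north-up on disk)."""
    spec = raster.spec
    data = np.flipud(raster.data)  # row 0 south in memory -> north-up file
    data = np.where(np.isnan(data), nodata_value, data)
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcorner {spec.lon0!r}\n"
        f"yllcorner {spec.lat0!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {nodata_value!r}\n"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:  # NODATA_value is optional in the format
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    spec = GridSpec(
        lon0=header["xllcorner"],
        lat0=header["yllcorner"],
        cell_size=header["cellsize"],
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
    )
    return RasterGrid(spec, np.flipud(data))
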