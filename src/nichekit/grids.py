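"""Gridded climate data containers and plain-text raster I/O.

Rasters live on a regular geographic (lon/lat, WGS84) grid described by the
lower-left corner and a square cell size in decimal degrees, following the
ESRI ASCII grid convention (row 0 is the northernmost row). All layers of a
:class:`ClimateStack` share one grid and one nodata mask; nodata is carried
as NaN in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridGeometry", "ClimateStack", "read_ascii_grid", "write_ascii_grid"]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridGeometry:
    """Regular lon/lat grid: ``nrows x ncols`` square cells of ``cellsize`` degrees.

    ``xll``/``yll`` are the corner coordinates of the lower-left cell
    (ESRI ASCII ``xllcorner``/``yllcorner``).
    """

    nrows: int
    ncols: int
    xll: float
    yll: float
    cellsize: float

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def lon_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes from north (row 0) to south (last row)."""
        return self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point; -1 where off-grid.

        A point exactly on an interior cell edge belongs to the cell with the
        larger coordinate (floor rule), so a point epsilon inside an edge is
        assigned to its containing cell, never the neighbour.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xll) / self.cellsize).astype(int)
        row_from_bottom = np.floor((lat - self.yll) / self.cellsize).astype(int)
        row = self.nrows - 1 - row_from_bottom
        ok = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return np.where(ok, row, -1), np.where(ok, col, -1)

    def cell_centers(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.lon_centers[np.asarray(cols)], self.lat_centers[np.asarray(rows)]

    def cell_areas_km2(self) -> np.ndarray:
        """Spherical surface area of each row's cells (km^2), one value per row.

        Area of a lon/lat cell on a sphere of radius R:
        ``R^2 * dlam * (sin(phi_top) - sin(phi_bottom))`` with angles in radians.
        """
        lat_top = np.deg2rad(self.lat_centers + self.cellsize / 2.0)
        lat_bot = np.deg2rad(self.lat_centers - self.cellsize / 2.0)
        dlam = np.deg2rad(self.cellsize)
        return EARTH_RADIUS_KM**2 * dlam * (np.sin(lat_top) - np.sin(lat_bot))


@dataclass
class ClimateStack:
    """Co-registered predictor layers on one grid with a shared nodata mask."""

    geometry: GridGeometry
    names: list[str]
    values: np.ndarray  # (n_layers, nrows, ncols), NaN = nodata
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a (n_layers, nrows, ncols) array")
        L, nr, nc = self.values.shape
        if L != len(self.names):
            raise ValueError("number of layers does not match names")
        if (nr, nc) != (self.geometry.nrows, self.geometry.ncols):
            raise ValueError("layer shape does not match grid geometry")
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells where every layer has data."""
        return np.all(np.isfinite(self.values), axis=0)

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.names.index(name)]

    def subset(self, names: list[str]) -> "ClimateStack":
        idx = [self.names.index(n) for n in names]
        return ClimateStack(self.geometry, list(names), self.values[idx].copy(), dict(self.meta))

    def values_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) matrix of layer values at the given cells."""
        return self.values[:, rows, cols].T

    def write_dir(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, layer in zip(self.names, self.values):
            p = directory / f"{name}.asc"
            write_ascii_grid(p, layer, self.geometry)
            paths.append(p)
        return paths

    @classmethod
    def read_dir(cls, directory: str | Path) -> "ClimateStack":
        directory = Path(directory)
        paths = sorted(directory.glob("*.asc"))
        if not paths:
            raise FileNotFoundError(f"no .asc layers under {directory}")
        layers, names, geom = [], [], None
        for p in paths:
            arr, g = read_ascii_grid(p)
            if geom is None:
                geom = g
            elif g != geom:
                raise ValueError(f"layer {p.name} is not co-registered with the others")
            layers.append(arr)
            names.append(p.stem)
        return cls(geom, names, np.stack(layers))


def write_ascii_grid(path: str | Path, array: np.ndarray, geometry: GridGeometry,
                     nodata: float = -9999.0) -> None:
    """Write one layer as an ESRI ASCII grid (.asc)."""
    array = np.asarray(array, dtype=float)
    if array.shape != (geometry.nrows, geometry.ncols):
        raise ValueError("array shape does not match geometry")
    out = np.where(np.isfinite(array), array, nodata)
    header = (
        f"ncols {geometry.ncols}\n"
        f"nrows {geometry.nrows}\n"
        f"xllcorner {geometry.xll!r}\n"
        f"yllcorner {geometry.yll!r}\n"
        f"cellsize {geometry.cellsize!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value", "xllcenter", "yllcenter",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    cellsize = header["cellsize"]
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cellsize / 2.0)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cellsize / 2.0)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, GridGeometry(nrows, ncols, xll, yll, cellsize)
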