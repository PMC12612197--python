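"""Regular geographic grids, spherical cell areas, and plain-text raster I/O.

Grids are regular latitude/longitude lattices in WGS84 degrees, stored
north-up: row 0 is the northernmost row and column 0 the westernmost.
Cells are half-open — a point lying exactly on a shared edge belongs to
the cell to the south/east. Missing data are encoded as NaN.

Rasters are serialised as ESRI ASCII grids (``.asc``), a plain-text format
readable by GDAL/QGIS; the DX/DY header extension is used when cells are
not square in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Mean Earth radius in kilometres (IUGG mean radius R1).
EARTH_RADIUS_KM = 6371.0088

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lat/lon grid.

    Parameters
    ----------
    n_rows, n_cols
        Number of cells along latitude / longitude. Both must be >= 2.
    lat_min, lat_max, lon_min, lon_max
        Outer extent in decimal degrees (WGS84).
    """

    n_rows: int
    n_cols: int
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must have at least 2 rows and 2 columns")
        if not (self.lat_max > self.lat_min):
            raise ValueError("lat_max must exceed lat_min")
        if not (self.lon_max > self.lon_min):
            raise ValueError("lon_max must exceed lon_min")
        if not all(
            math.isfinite(v)
            for v in (self.lat_min, self.lat_max, self.lon_min, self.lon_max)
        ):
            raise ValueError("grid extent must be finite")

    @property
    def dlat(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_rows

    @property
    def dlon(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-centre latitudes, north to south (one per row)."""
        i = np.arange(self.n_rows)
        return self.lat_max - (i + 0.5) * self.dlat

    @property
    def lon_centers(self) -> np.ndarray:
        """Cell-centre longitudes, west to east (one per column)."""
        j = np.arange(self.n_cols)
        return self.lon_min + (j + 0.5) * self.dlon

    def rowcol(self, lats, lons) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) indices.

        Returns ``(rows, cols, inside)``; indices are -1 where ``inside``
        is False. Edge points belong to the cell to the south/east, so a
        point exactly on the southern or eastern extent boundary is
        outside the grid.
        """
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        with np.errstate(invalid="ignore"):
            rows = np.floor((self.lat_max - lats) / self.dlat)
            cols = np.floor((lons - self.lon_min) / self.dlon)
        finite = np.isfinite(lats) & np.isfinite(lons)
        inside = (
            finite
            & (rows >= 0)
            & (rows < self.n_rows)
            & (cols >= 0)
            & (cols < self.n_cols)
        )
        rows = np.where(inside, rows, -1).astype(int)
        cols = np.where(inside, cols, -1).astype(int)
        return rows, cols, inside

    def cell_center(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        return (
            self.lat_max - (rows + 0.5) * self.dlat,
            self.lon_min + (cols + 0.5) * self.dlon,
        )


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Spherical area of each grid row in km², one value per row.

    For a cell spanning latitudes [phi_bottom, phi_top] and a longitude
    width of dlon radians, the area on a sphere of radius R is
    ``R^2 * dlon * (sin(phi_top) - sin(phi_bottom))``; it is constant
    along a row.
    """
    i = np.arange(grid.n_rows)
    top = np.radians(grid.lat_max - i * grid.dlat)
    bottom = np.radians(grid.lat_max - (i + 1) * grid.dlat)
    dlon_rad = math.radians(grid.dlon)
    return EARTH_RADIUS_KM**2 * dlon_rad * (np.sin(top) - np.sin(bottom))


@dataclass
class RasterGrid:
    """A single-band raster: a :class:`GridSpec` plus a value matrix.

    ``values`` has shape ``(n_rows, n_cols)``; NaN marks missing cells.
    """

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix, True where the cell holds a valid value."""
        return np.isfinite(self.values)

    def aligned_with(self, other: "RasterGrid") -> bool:
        return self.grid == other.grid

    def sample(self, lats, lons) -> tuple[np.ndarray, np.ndarray]:
        """Value of the cell containing each point (nearest-cell lookup).

        Returns ``(values, inside)``; values are NaN for points outside
        the extent. No interpolation is performed.
        """
        rows, cols, inside = self.grid.rowcol(lats, lons)
        out = np.full(rows.shape, np.nan)
        out[inside] = self.values[rows[inside], cols[inside]]
        return out, inside

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.grid, np.array(values, dtype=float))

    # ------------------------------------------------------------------
    # ESRI ASCII grid serialisation
    # ------------------------------------------------------------------
    def write_ascii(self, path: str | Path) -> None:
        g = self.grid
        lines = [f"ncols {g.n_cols}", f"nrows {g.n_rows}",
                 f"xllcorner {g.lon_min:.10g}", f"yllcorner {g.lat_min:.10g}"]
        if abs(g.dlon - g.dlat) < 1e-12:
            lines.append(f"cellsize {g.dlon:.12g}")
        else:
            lines.append(f"dx {g.dlon:.12g}")
            lines.append(f"dy {g.dlat:.12g}")
        lines.append(f"NODATA_value {NODATA:.10g}")
        vals = np.where(self.mask, self.values, NODATA)
        body = "\n".join(
            " ".join(f"{v:.10g}" for v in row) for row in vals
        )
        Path(path).write_text("\n".join(lines) + "\n" + body + "\n")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        text = Path(path).read_text().splitlines()
        header: dict[str, float] = {}
        idx = 0
        for idx, line in enumerate(text):
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "dx", "dy", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                break
        n_cols = int(header["ncols"])
        n_rows = int(header["nrows"])
        dx = header.get("dx", header.get("cellsize"))
        dy = header.get("dy", header.get("cellsize"))
        if dx is None or dy is None:
            raise ValueError(f"{path}: missing cellsize/dx/dy header")
        nodata = header.get("nodata_value", NODATA)
        values = np.loadtxt(text[idx:], dtype=float).reshape(n_rows, n_cols)
        values = np.where(values == nodata, np.nan, values)
        grid = GridSpec(
            n_rows=n_rows,
            n_cols=n_cols,
            lat_min=header["yllcorner"],
            lat_max=header["yllcorner"] + n_rows * dy,
            lon_min=header["xllcorner"],
            lon_max=header["xllcorner"] + n_cols * dx,
        )
        return cls(grid, values)


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle (haversine) distance in km on the mean-radius sphere."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
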