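"""Geographic grids and raster containers.

All rasters in this package live on a regular latitude/longitude grid
(EPSG:4326-style, degrees). Row 0 is the northernmost row and pixel
coordinates refer to pixel centers. Rasters are serialized as ESRI ASCII
grids (plain text), a format readable by every GIS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid: bounds in degrees, square pixels.

    ``lon_min``/``lat_min`` are the outer (edge) coordinates of the
    south-west corner, ``resolution`` the pixel size in degrees. Pixel
    counts come from floor division so that a grid written to disk and
    read back has identical shape.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("grid bounds must satisfy min < max")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows == 0 or self.n_cols == 0:
            raise ValueError("grid has zero pixels; enlarge bounds or shrink resolution")

    @property
    def n_cols(self) -> int:
        return int(math.floor((self.lon_max - self.lon_min) / self.resolution + 1e-9))

    @property
    def n_rows(self) -> int:
        return int(math.floor((self.lat_max - self.lat_min) / self.resolution + 1e-9))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, row 0 = northernmost."""
        top = self.lat_min + self.n_rows * self.resolution
        return top - (np.arange(self.n_rows) + 0.5) * self.resolution

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) arrays of shape ``self.shape`` giving pixel centers."""
        lon = self.lon_centers()
        lat = self.lat_centers()
        return np.broadcast_to(lat[:, None], self.shape).copy(), np.broadcast_to(
            lon[None, :], self.shape
        ).copy()

    def contains(self, lat: float, lon: float) -> bool:
        top = self.lat_min + self.n_rows * self.resolution
        right = self.lon_min + self.n_cols * self.resolution
        return self.lat_min <= lat <= top and self.lon_min <= lon <= right

    def index_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/column of the pixel containing (lat, lon)."""
        if not self.contains(lat, lon):
            raise ValueError(f"point ({lat}, {lon}) outside grid")
        top = self.lat_min + self.n_rows * self.resolution
        i = min(int((top - lat) / self.resolution), self.n_rows - 1)
        j = min(int((lon - self.lon_min) / self.resolution), self.n_cols - 1)
        return i, j

    def pixel_areas_km2(self) -> np.ndarray:
        """Spherical-rectangle area of every pixel, km², shape ``self.shape``.

        area = R² · Δλ · Δφ · cos(φ_center) with angles in radians.
        """
        dlam = math.radians(self.resolution)
        dphi = math.radians(self.resolution)
        phi = np.radians(self.lat_centers())
        row_area = EARTH_RADIUS_KM**2 * dlam * dphi * np.cos(phi)
        return np.broadcast_to(row_area[:, None], self.shape).copy()


@dataclass
class Raster:
    """A single-band raster on a :class:`GridSpec` with an optional validity mask."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape mismatch")

    def masked(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out


NODATA = -9999.0


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.17g") -> None:
    """Write a raster as an ESRI ASCII grid (text)."""
    g = raster.grid
    vals = raster.values.copy()
    vals[~raster.mask] = NODATA
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.lon_min!r}\n"
        f"yllcorner {g.lat_min!r}\n"
        f"cellsize {g.resolution!r}\n"
        f"nodata_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` or a GIS."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                meta[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        vals = np.loadtxt(fh, ndmin=2)
    ncols = int(meta["ncols"])
    nrows = int(meta["nrows"])
    res = meta["cellsize"]
    grid = GridSpec(
        lon_min=meta["xllcorner"],
        lon_max=meta["xllcorner"] + ncols * res,
        lat_min=meta["yllcorner"],
        lat_max=meta["yllcorner"] + nrows * res,
        resolution=res,
    )
    nodata = meta.get("nodata_value", NODATA)
    mask = vals != nodata
    return Raster(grid=grid, values=vals, mask=mask)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
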