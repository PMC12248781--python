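"""Land-surface-temperature rasters and the canopy cooling simulation.

An :class:`LSTGrid` is a north-up single-band °C raster in WGS84 with an
origin/pixel-size geotransform; no-data is carried as NaN in memory. The
cooling simulation subtracts, under every tree's canopy buffer, that tree's
species cooling index from the pixels whose centers the buffer covers;
where buffers overlap the *maximum* cooling index applies (not the sum), so
the per-pixel reduction stays within the physically plausible 2–8 °C range
of the species index itself.

File formats: GeoTIFF (read/written with tifffile, carrying the
ModelPixelScale/ModelTiepoint/GeoKey/GDAL_NODATA tags) and the plain-text
ESRI ASCII grid (``.asc``) for text fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import RasterError
from .placement import EARTH_RADIUS_M, GeoPoint, PlantedTree, PlantingLayout, haversine

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey directory declaring geographic WGS84 (EPSG 4326), degree units
_WGS84_GEOKEYS = (1, 1, 0, 4, 1024, 0, 1, 2, 1025, 0, 1, 2, 2048, 0, 1, 4326, 2054, 0, 1, 9102)


@dataclass
class LSTGrid:
    """Single-band °C raster, north-up, WGS84; NaN marks no-data."""

    values: np.ndarray  # 2-D float array, NaN = no-data
    lon_origin: float  # west edge of pixel (0, 0), degrees
    lat_origin: float  # north edge of pixel (0, 0), degrees
    pixel_size: float  # degrees, square pixels
    crs: str = "EPSG:4326"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise RasterError("LSTGrid values must be a 2-D array")
        if not self.pixel_size > 0:
            raise RasterError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_center(self, row: int, col: int) -> GeoPoint:
        return GeoPoint(
            latitude=self.lat_origin - (row + 0.5) * self.pixel_size,
            longitude=self.lon_origin + (col + 0.5) * self.pixel_size,
        )

    def index_of(self, p: GeoPoint) -> tuple[int, int]:
        """Row/col of the pixel containing a point (may be out of bounds)."""
        row = int(math.floor((self.lat_origin - p.latitude) / self.pixel_size))
        col = int(math.floor((p.longitude - self.lon_origin) / self.pixel_size))
        return row, col

    def contains(self, p: GeoPoint) -> bool:
        r, c = self.index_of(p)
        nr, nc = self.shape
        return 0 <= r < nr and 0 <= c < nc

    def value_at(self, p: GeoPoint) -> float:
        if not self.contains(p):
            return float("nan")
        r, c = self.index_of(p)
        return float(self.values[r, c])

    def copy(self) -> "LSTGrid":
        return LSTGrid(
            self.values.copy(), self.lon_origin, self.lat_origin, self.pixel_size, self.crs
        )


def write_lst(grid: LSTGrid, path: str | Path) -> None:
    """Write a grid as GeoTIFF (default) or ESRI ASCII grid for ``.asc`` paths."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        _write_asc(grid, path)
        return
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0), False),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.lon_origin, grid.lat_origin, 0.0), False),
        (_TAG_GEO_KEYS, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS, False),
        (_TAG_GDAL_NODATA, "s", 0, "nan", False),
    ]
    tifffile.imwrite(path, grid.values.astype(np.float32), extratags=extratags)


def read_lst(path: str | Path) -> LSTGrid:
    """Read a single-band georeferenced GeoTIFF or ``.asc`` grid.

    Raises :class:`RasterError` for multi-band rasters or files without a
    geotransform/CRS (those need reprojection to WGS84 first).
    """
    path = Path(path)
    if path.suffix.lower() == ".asc":
        return _read_asc(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        if arr.ndim == 3:
            raise RasterError(f"{path}: multi-band raster; a single LST band is required")
        scale = page.tags.get(_TAG_PIXEL_SCALE)
        tie = page.tags.get(_TAG_TIEPOINT)
        keys = page.tags.get(_TAG_GEO_KEYS)
        if scale is None or tie is None or keys is None:
            raise RasterError(
                f"{path}: missing georeferencing tags; reproject/export as WGS84 GeoTIFF"
            )
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        px, py = scale.value[0], scale.value[1]
        lon0, lat0 = tie.value[3], tie.value[4]
        nodata_val = None if nodata_tag is None else str(nodata_tag.value)
    if not math.isclose(px, py, rel_tol=1e-9):
        raise RasterError(f"{path}: non-square pixels ({px} x {py}) unsupported")
    arr = np.asarray(arr, dtype=np.float32)
    if nodata_val is not None:
        nd = nodata_val.strip()
        if nd.lower() != "nan":
            arr = np.where(arr == float(nd), np.nan, arr)
    return LSTGrid(arr, lon_origin=lon0, lat_origin=lat0, pixel_size=px)


_ASC_NODATA = -9999.0


def _write_asc(grid: LSTGrid, path: Path) -> None:
    nr, nc = grid.shape
    vals = np.where(np.isnan(grid.values), _ASC_NODATA, grid.values)
    header = (
        f"ncols {nc}\nnrows {nr}\n"
        f"xllcorner {grid.lon_origin!r}\n"
        f"yllcorner {grid.lat_origin - nr * grid.pixel_size!r}\n"
        f"cellsize {grid.pixel_size!r}\nNODATA_value {_ASC_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.9g")


def _read_asc(path: Path) -> LSTGrid:
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        meta[key.lower()] = float(val)
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= meta.keys():
        raise RasterError(f"{path}: incomplete ESRI ASCII header")
    arr = np.loadtxt(lines[6:], dtype=np.float32)
    arr = np.atleast_2d(arr)
    nodata = meta.get("nodata_value", _ASC_NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    return LSTGrid(
        arr,
        lon_origin=meta["xllcorner"],
        lat_origin=meta["yllcorner"] + meta["nrows"] * meta["cellsize"],
        pixel_size=meta["cellsize"],
    )


def pixels_under_buffer(grid: LSTGrid, tree: PlantedTree) -> set[tuple[int, int]]:
    """Pixels whose centers lie within the tree's canopy buffer.

    Membership is center-in-circle with geodesic (haversine) distance at
    most diameter/2. A tree outside the raster extent covers no pixels.
    """
    radius = tree.diameter / 2.0
    loc = tree.location
    # search window: buffer bbox in degrees, padded by one pixel
    dlat = math.degrees(radius / EARTH_RADIUS_M)
    coslat = max(1e-9, math.cos(math.radians(loc.latitude)))
    dlon = math.degrees(radius / (EARTH_RADIUS_M * coslat))
    nr, nc = grid.shape
    r0, c0 = grid.index_of(
        GeoPoint(min(90.0, loc.latitude + dlat), max(-180.0, loc.longitude - dlon))
    )
    r1, c1 = grid.index_of(
        GeoPoint(max(-90.0, loc.latitude - dlat), min(180.0, loc.longitude + dlon))
    )
    out = set()
    for r in range(max(0, r0 - 1), min(nr, r1 + 2)):
        for c in range(max(0, c0 - 1), min(nc, c1 + 2)):
            if haversine(grid.pixel_center(r, c), loc) <= radius:
                out.add((r, c))
    return out


@dataclass
class CoolingResult:
    modified: LSTGrid
    delta: LSTGrid  # per-pixel reduction, ≥ 0, 0 off-buffer
    covered_pixels: int


def apply_cooling(grid: LSTGrid, layout: PlantingLayout) -> CoolingResult:
    """Simulate localized LST reduction under the layout's canopy buffers.

    Per pixel the reduction is the maximum cooling index over all trees
    whose buffer covers it; ``modified = original − delta``. No-data pixels
    are left untouched and report a zero delta.
    """
    delta = np.zeros(grid.shape, dtype=np.float32)
    covered: set[tuple[int, int]] = set()
    for tree in layout:
        pix = pixels_under_buffer(grid, tree)
        covered |= pix
        for r, c in pix:
            if tree.cooling_index > delta[r, c]:
                delta[r, c] = tree.cooling_index
    nodata = np.isnan(grid.values)
    delta[nodata] = 0.0
    covered = {rc for rc in covered if not nodata[rc]}
    modified = grid.copy()
    modified.values = grid.values - delta
    delta_grid = LSTGrid(delta, grid.lon_origin, grid.lat_origin, grid.pixel_size, grid.crs)
    return CoolingResult(modified=modified, delta=delta_grid, covered_pixels=len(covered))
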