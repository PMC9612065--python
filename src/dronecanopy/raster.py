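"""Georeferenced raster data model and GeoTIFF I/O.

A :class:`Grid` is the raster currency used throughout the package: a 2-D
array of values, an affine pixel->map transform, a CRS tag and a nodata
sentinel.  The coordinate convention is the dominant geospatial one: pixel
(row 0, col 0) is the top-left cell, the map coordinate of a pixel is its
*centre*, and y decreases with increasing row (pixel height is negative).

GeoTIFFs are read and written with :mod:`tifffile`, carrying the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory,
GDAL_NODATA) so the files interoperate with GDAL-based GIS software.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

DEFAULT_NODATA = -9999.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

_GEOKEY_MODEL_TYPE = 1024
_GEOKEY_RASTER_TYPE = 1025
_GEOKEY_PROJECTED_CRS = 3072
_GEOKEY_GEOGRAPHIC_CRS = 2048


class RasterAlignmentError(ValueError):
    """Raised when rasters that must share one grid do not."""


@dataclass(frozen=True)
class GridTransform:
    """Affine mapping from pixel (row, col) to map (x, y).

    ``x_origin, y_origin`` is the map coordinate of the *outer corner* of
    the top-left pixel.  ``pixel_width`` is positive; ``pixel_height`` is
    signed and conventionally negative (y decreases downwards).
    """

    x_origin: float
    y_origin: float
    pixel_width: float
    pixel_height: float

    def __post_init__(self) -> None:
        if not self.pixel_width > 0:
            raise ValueError(f"pixel_width must be > 0, got {self.pixel_width}")
        if self.pixel_height == 0:
            raise ValueError("pixel_height must be nonzero")

    def pixel_to_map(self, row, col):
        """Map coordinate of the centre of pixel (row, col)."""
        x = self.x_origin + (np.asarray(col) + 0.5) * self.pixel_width
        y = self.y_origin + (np.asarray(row) + 0.5) * self.pixel_height
        return x, y

    def map_to_pixel(self, x, y):
        """(row, col) of the cell containing map point (x, y)."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.pixel_width).astype(int)
        row = np.floor((np.asarray(y) - self.y_origin) / self.pixel_height).astype(int)
        return row, col


@dataclass
class Grid:
    """2-D georeferenced raster of real values.

    Parameters
    ----------
    values
        2-D float array.  Non-finite entries are rejected; missing data is
        encoded by the ``nodata`` sentinel instead.
    transform
        Pixel->map affine transform (top-left origin, centre convention).
    crs
        CRS identifier, e.g. ``"EPSG:32756"``; must refer to a projected,
        metre-unit CRS for the analysis to be dimensionally meaningful.
        ``None`` flags unit ambiguity.
    nodata
        Sentinel value marking missing pixels, or ``None``.
    """

    values: np.ndarray
    transform: GridTransform
    crs: str | None = None
    nodata: float | None = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError(f"values must be 2-D with >=1 rows and cols, got shape {self.values.shape}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite (use the nodata sentinel for missing pixels)")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def gsd(self) -> float:
        """Ground sampling distance (pixel width) in map units."""
        return self.transform.pixel_width

    @property
    def pixel_area(self) -> float:
        return self.transform.pixel_width * abs(self.transform.pixel_height)

    def pixel_to_map(self, row, col):
        r, c = np.asarray(row), np.asarray(col)
        nrows, ncols = self.shape
        if np.any(r < 0) or np.any(r >= nrows) or np.any(c < 0) or np.any(c >= ncols):
            raise IndexError(f"pixel index out of range for shape {self.shape}")
        return self.transform.pixel_to_map(row, col)

    def map_to_pixel(self, x, y):
        return self.transform.map_to_pixel(x, y)

    def pixel_centres(self):
        """(X, Y) arrays of every pixel-centre map coordinate."""
        rows = np.arange(self.shape[0])
        cols = np.arange(self.shape[1])
        x, _ = self.transform.pixel_to_map(np.zeros_like(cols), cols)
        _, y = self.transform.pixel_to_map(rows, np.zeros_like(rows))
        return np.meshgrid(x, y)

    # -- values ------------------------------------------------------------
    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of pixels that are not nodata."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        return self.values != self.nodata

    def masked_values(self) -> np.ndarray:
        """Values as float with nodata replaced by NaN."""
        out = self.values.astype(float, copy=True)
        if self.nodata is not None:
            out[~self.valid] = np.nan
        return out

    def with_values(self, values: np.ndarray, nodata: float | None = DEFAULT_NODATA) -> "Grid":
        """New grid on the same geometry with different values."""
        if values.shape != self.shape:
            raise RasterAlignmentError(f"shape {values.shape} != template {self.shape}")
        return Grid(values=values, transform=self.transform, crs=self.crs, nodata=nodata)

    def aligned_with(self, other: "Grid") -> bool:
        return self.shape == other.shape and self.transform == other.transform and self.crs == other.crs


def grid_from_nan(values: np.ndarray, template: Grid, nodata: float = DEFAULT_NODATA) -> Grid:
    """Build a grid from a float array that uses NaN for missing pixels."""
    out = np.asarray(values, dtype=np.float64).copy()
    out[~np.isfinite(out)] = nodata
    return template.with_values(out, nodata=nodata)


def require_aligned(*grids: Grid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.aligned_with(g):
            raise RasterAlignmentError(
                "rasters must share one grid (shape, transform, crs); "
                f"got {first.shape}/{first.transform} vs {g.shape}/{g.transform}"
            )


@dataclass
class RGBOrthomosaic:
    """Three aligned red/green/blue band grids (symbols R, G, B)."""

    red: Grid
    green: Grid
    blue: Grid

    def __post_init__(self) -> None:
        require_aligned(self.red, self.green, self.blue)
        for name, band in (("red", self.red), ("green", self.green), ("blue", self.blue)):
            vals = band.values[band.valid]
            if vals.size and vals.min() < 0:
                raise ValueError(f"{name} band has negative values")

    @property
    def bands(self) -> tuple[Grid, Grid, Grid]:
        return (self.red, self.green, self.blue)

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def transform(self) -> GridTransform:
        return self.red.transform

    @property
    def crs(self) -> str | None:
        return self.red.crs


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _geotags(transform: GridTransform, crs: str | None, nodata: float | None):
    """tifffile extratags carrying GeoTIFF georeferencing."""
    tags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3,
         (transform.pixel_width, abs(transform.pixel_height), 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, transform.x_origin, transform.y_origin, 0.0), True),
    ]
    if crs is not None:
        code = _epsg_code(crs)
        if code is not None:
            keydir = (1, 1, 0, 3,
                      _GEOKEY_MODEL_TYPE, 0, 1, 1,       # projected model
                      _GEOKEY_RASTER_TYPE, 0, 1, 1,      # pixel-is-area
                      _GEOKEY_PROJECTED_CRS, 0, 1, code)
            tags.append((_TAG_GEO_KEY_DIRECTORY, "H", len(keydir), keydir, True))
    if nodata is not None:
        s = repr(float(nodata))
        tags.append((_TAG_GDAL_NODATA, "s", len(s) + 1, s, True))
    return tags


def _epsg_code(crs: str) -> int | None:
    crs = crs.strip().upper()
    if crs.startswith("EPSG:"):
        try:
            return int(crs.split(":", 1)[1])
        except ValueError:
            return None
    return None


def write_raster(obj: Grid | RGBOrthomosaic, path, dtype=None) -> str:
    """Write a Grid (single band) or RGBOrthomosaic (3 bands) as GeoTIFF.

    Float payloads are written as float32; pass ``dtype`` to force e.g.
    uint8 for RGB.  Round-trips value-exactly for float32 and integer data.
    """
    if isinstance(obj, RGBOrthomosaic):
        data = np.stack([b.values for b in obj.bands], axis=-1)
        transform, crs, nodata = obj.transform, obj.crs, obj.red.nodata
        photometric = "rgb"
    elif isinstance(obj, Grid):
        data = obj.values
        transform, crs, nodata = obj.transform, obj.crs, obj.nodata
        photometric = "minisblack"
    else:
        raise TypeError(f"expected Grid or RGBOrthomosaic, got {type(obj).__name__}")

    if dtype is None:
        dtype = np.float32 if np.issubdtype(data.dtype, np.floating) else data.dtype
    data = np.ascontiguousarray(data.astype(dtype))
    tifffile.imwrite(
        str(path), data, photometric=photometric,
        extratags=_geotags(transform, crs, nodata),
    )
    return str(path)


def _read_geotags(page) -> tuple[GridTransform, str | None, float | None]:
    tags = page.tags
    scale = tags.valueof(_TAG_MODEL_PIXEL_SCALE)
    tiepoint = tags.valueof(_TAG_MODEL_TIEPOINT)
    if scale is None or tiepoint is None:
        warnings.warn("GeoTIFF lacks georeferencing tags; assuming unit pixels at origin "
                      "(map units ambiguous)", stacklevel=3)
        transform = GridTransform(0.0, 0.0, 1.0, -1.0)
    else:
        px, py = float(scale[0]), float(scale[1])
        # tiepoint maps raster (col=i, row=j) to map (x, y): adjust to outer corner
        i, j, _, x, y, _ = (float(v) for v in tiepoint[:6])
        transform = GridTransform(x - i * px, y + j * py, px, -py)

    crs: str | None = None
    keydir = tags.valueof(_TAG_GEO_KEY_DIRECTORY)
    if keydir is not None:
        keys = {int(keydir[4 + 4 * k]): int(keydir[4 + 4 * k + 3])
                for k in range(int(keydir[3]))}
        if _GEOKEY_PROJECTED_CRS in keys:
            crs = f"EPSG:{keys[_GEOKEY_PROJECTED_CRS]}"
        elif _GEOKEY_GEOGRAPHIC_CRS in keys:
            warnings.warn("GeoTIFF has a geographic (degree-unit) CRS; distances and areas "
                          "in metres will be wrong", stacklevel=3)
            crs = f"EPSG:{keys[_GEOKEY_GEOGRAPHIC_CRS]}"
    if crs is None:
        warnings.warn("GeoTIFF has no CRS; proceeding with unit ambiguity", stacklevel=3)

    nodata = None
    nd = tags.valueof(_TAG_GDAL_NODATA)
    if nd is not None:
        try:
            nodata = float(str(nd).strip("\x00 "))
        except ValueError:
            nodata = None
    return transform, crs, nodata


def read_raster(path, band_indices: list[int] | None = None) -> Grid | RGBOrthomosaic:
    """Read a GeoTIFF as a Grid (one band) or RGBOrthomosaic (three bands).

    ``band_indices`` are 1-based.  A single requested band returns a Grid;
    exactly three return an RGBOrthomosaic in the requested order.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        transform, crs, nodata = _read_geotags(page)

    if data.ndim == 2:
        data = data[:, :, None]
    n_bands = data.shape[2]
    if band_indices is None:
        band_indices = list(range(1, n_bands + 1))
    for b in band_indices:
        if not 1 <= b <= n_bands:
            raise IndexError(f"band {b} out of range for {n_bands}-band file")

    grids = [Grid(values=data[:, :, b - 1], transform=transform, crs=crs, nodata=nodata)
             for b in band_indices]
    if len(grids) == 1:
        return grids[0]
    if len(grids) == 3:
        return RGBOrthomosaic(red=grids[0], green=grids[1], blue=grids[2])
    raise ValueError(f"band_indices must select 1 or 3 bands, got {len(band_indices)}")
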