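"""Vegetation masking and tree-crown polygon extraction.

An index raster (NGBDI by default downstream) is reclassified into a
binary vegetation/ground mask, cleaned morphologically, and each
8-connected vegetated component is traced into an identified crown
polygon.  Per-crown mean index values then split the crowns into k
classes by equal-count quantile breaks — a reproducible stand-in for a
visual three-class reclassification, with ties going to the lower class.

Touching crowns are deliberately not split: each connected vegetated
region is one unit (no watershed segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing as _closing, disk

from .indices import IndexRaster
from .raster import Grid

MASK_NODATA = -9999.0


@dataclass
class VegetationMask:
    """Binary vegetation raster: 1 = vegetation, 0 = ground."""

    mask: Grid
    source_index: str
    threshold: float

    def __post_init__(self) -> None:
        vals = self.mask.values[self.mask.valid]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("mask values must be 0, 1 or nodata")

    @property
    def vegetation(self) -> np.ndarray:
        """Boolean array of vegetated pixels."""
        return self.mask.valid & (self.mask.values == 1.0)

    @property
    def ground(self) -> np.ndarray:
        return self.mask.valid & (self.mask.values == 0.0)


@dataclass
class CrownPolygon:
    """One identified tree-crown region."""

    id: int
    polygon: Polygon
    area_m2: float
    class_label: int | None = None
    mean_index: float | None = None

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValueError("crown ids start at 1")
        if self.area_m2 <= 0:
            raise ValueError("crown area must be > 0")


def reclassify_index(index: IndexRaster, threshold: float | str = "auto") -> VegetationMask:
    """Threshold an index raster into a vegetation mask (1 where index > t).

    ``threshold="auto"`` picks t by Otsu's method on the valid-pixel
    histogram (256 bins over the observed range) and records it.
    """
    grid = index.grid
    valid = grid.valid
    vals = grid.values[valid]
    if threshold == "auto":
        if vals.size == 0 or np.unique(vals).size < 2:
            raise ValueError("auto threshold needs >= 2 distinct valid values")
        threshold = float(threshold_otsu(vals, nbins=256))
    t = float(threshold)
    out = np.where(valid, (grid.values > t).astype(np.float64), MASK_NODATA)
    mask_grid = grid.with_values(out, nodata=MASK_NODATA)
    return VegetationMask(mask=mask_grid, source_index=index.name, threshold=t)


def clean_mask(mask: VegetationMask, min_patch_area_m2: float = 1.0,
               closing_radius_px: int = 1) -> VegetationMask:
    """Morphological closing then small-patch removal (8-connectivity).

    Patches whose area is strictly below ``min_patch_area_m2`` are
    removed.  Parameters (0, 0) are the identity.
    """
    if min_patch_area_m2 < 0 or closing_radius_px < 0:
        raise ValueError("cleaning parameters must be >= 0")
    veg = mask.vegetation
    if closing_radius_px > 0:
        veg = _closing(veg, footprint=disk(closing_radius_px)).astype(bool)
    if min_patch_area_m2 > 0:
        labels = cc_label(veg, connectivity=2)
        pixel_area = mask.mask.pixel_area
        counts = np.bincount(labels.ravel())
        small = np.nonzero(counts * pixel_area < min_patch_area_m2)[0]
        small = small[small != 0]
        if small.size:
            veg = veg & ~np.isin(labels, small)
    out = np.where(mask.mask.valid, veg.astype(np.float64), MASK_NODATA)
    return VegetationMask(mask=mask.mask.with_values(out, nodata=MASK_NODATA),
                          source_index=mask.source_index, threshold=mask.threshold)


def _component_polygon(rows: np.ndarray, cols: np.ndarray, grid: Grid) -> Polygon:
    """Exact pixel-boundary polygon of one component via row-run union."""
    t = grid.transform
    boxes = []
    for r in np.unique(rows):
        cs = np.sort(cols[rows == r])
        # split into consecutive runs
        breaks = np.nonzero(np.diff(cs) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [cs.size - 1]))
        y_top = t.y_origin + r * t.pixel_height
        y_bot = t.y_origin + (r + 1) * t.pixel_height
        for s, e in zip(starts, ends):
            x0 = t.x_origin + cs[s] * t.pixel_width
            x1 = t.x_origin + (cs[e] + 1) * t.pixel_width
            boxes.append(box(x0, min(y_top, y_bot), x1, max(y_top, y_bot)))
    return unary_union(boxes)


def extract_crown_polygons(mask: VegetationMask, simplify_tol_m: float | None = None) -> list[CrownPolygon]:
    """Trace each 8-connected vegetated component into a crown polygon.

    Vertices lie on pixel boundaries and are then Douglas-Peucker
    simplified (topology preserved) with tolerance ``simplify_tol_m``
    (default 2 x gsd).  Ids are sequential in top-most, then left-most
    component-pixel order.  An empty mask yields an empty list.
    """
    if simplify_tol_m is None:
        simplify_tol_m = 2.0 * mask.mask.gsd
    veg = mask.vegetation
    labels = cc_label(veg, connectivity=2)
    n = labels.max()
    if n == 0:
        return []
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.nonzero(flat)[0]
    # first row-major occurrence per label -> top-most, then left-most
    np.minimum.at(first, flat[nz], nz)
    order = np.argsort(first[1:], kind="stable")

    crowns: list[CrownPolygon] = []
    for new_id, lab_idx in enumerate(order, start=1):
        lab = lab_idx + 1
        rows, cols = np.nonzero(labels == lab)
        poly = _component_polygon(rows, cols, mask.mask)
        if simplify_tol_m > 0:
            poly = poly.simplify(simplify_tol_m, preserve_topology=True)
        if poly.is_empty or poly.area <= 0:
            continue
        crowns.append(CrownPolygon(id=new_id, polygon=poly, area_m2=float(poly.area)))
    return crowns


def classify_crowns(index: IndexRaster, crowns: list[CrownPolygon], k: int = 3) -> list[CrownPolygon]:
    """Label crowns 1..k by equal-count quantile breaks of mean index.

    The per-crown mean is taken over interior pixels (pixel centres inside
    the polygon).  A crown's label is 1 + (number of quantile breaks its
    mean strictly exceeds); ties at a break go to the lower class.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(crowns) < k:
        raise ValueError(f"need >= {k} crowns to form {k} classes, got {len(crowns)}")
    means = np.array([_polygon_mean(index.grid, c.polygon) for c in crowns])
    breaks = np.quantile(means, [i / k for i in range(1, k)]) if k > 1 else np.array([])
    out = []
    for crown, m in zip(crowns, means):
        label = int(1 + np.sum(m > breaks))
        out.append(CrownPolygon(id=crown.id, polygon=crown.polygon, area_m2=crown.area_m2,
                                class_label=label, mean_index=float(m)))
    return out


def _polygon_mean(grid: Grid, poly: Polygon) -> float:
    rows, cols = _member_pixels(grid, poly)
    if rows.size == 0:
        return np.nan
    vals = grid.values[rows, cols]
    ok = vals != grid.nodata if grid.nodata is not None else np.ones(vals.shape, bool)
    return float(vals[ok].mean()) if ok.any() else np.nan


def _member_pixels(grid: Grid, poly) -> tuple[np.ndarray, np.ndarray]:
    """Pixels whose centres fall inside the polygon (the zonal convention)."""
    t = grid.transform
    nrows, ncols = grid.shape
    xmin, ymin, xmax, ymax = poly.bounds
    c0 = max(0, int(np.floor((xmin - t.x_origin) / t.pixel_width - 0.5)))
    c1 = min(ncols - 1, int(np.ceil((xmax - t.x_origin) / t.pixel_width - 0.5)))
    r0 = max(0, int(np.floor((ymax - t.y_origin) / t.pixel_height - 0.5)))
    r1 = min(nrows - 1, int(np.ceil((ymin - t.y_origin) / t.pixel_height - 0.5)))
    if c0 > c1 or r0 > r1:
        return np.array([], int), np.array([], int)
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    xc = t.x_origin + (cols + 0.5) * t.pixel_width
    yc = t.y_origin + (rows + 0.5) * t.pixel_height
    X, Y = np.meshgrid(xc, yc)
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    rr, cc = np.nonzero(inside)
    return rows[rr], cols[cc]
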