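"""Ground-point sampling, DEM interpolation and the canopy height model.

The bare-earth DEM is reconstructed photogrammetry-style: random locations
are drawn on the ground class of the vegetation mask, their elevations are
read from the DSM, and a surface is interpolated through them (piecewise
linear on the Delaunay triangulation, nearest-point fill outside the
convex hull).  The canopy height model is then

    CHM = DSM - DEM

per pixel, clamped at zero by default because heights are physical; the
number of clamped pixels is reported for diagnosability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

from .mask import VegetationMask
from .raster import DEFAULT_NODATA, Grid, require_aligned

#: Default ground-point density: one point per 25 m^2.
DEFAULT_POINT_DENSITY = 1.0 / 25.0


@dataclass
class GroundPointSet:
    """Random ground locations with DSM-read elevations."""

    points: np.ndarray  # (n, 3): x, y, elevation
    seed: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of x, y, z")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class SurfaceSet:
    """Aligned DSM / DEM / CHM triplet."""

    dsm: Grid
    dem: Grid
    chm: Grid

    def __post_init__(self) -> None:
        require_aligned(self.dsm, self.dem, self.chm)


class ChmResult(NamedTuple):
    grid: Grid
    n_clamped: int


def sample_ground_points(mask: VegetationMask, dsm: Grid, n_points: int, seed: int = 0) -> GroundPointSet:
    """Sample ``n_points`` distinct ground pixels uniformly without replacement.

    Point coordinates are pixel centres; elevations are the DSM values
    there.  Pixels that are nodata in the DSM are never candidates.
    """
    require_aligned(mask.mask, dsm)
    candidates = mask.ground & dsm.valid
    rows, cols = np.nonzero(candidates)
    if rows.size < n_points:
        raise ValueError(f"only {rows.size} valid ground pixels; cannot sample {n_points}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n_points, replace=False)
    r, c = rows[pick], cols[pick]
    x, y = dsm.transform.pixel_to_map(r, c)
    z = dsm.values[r, c]
    return GroundPointSet(points=np.column_stack([x, y, z]), seed=seed)


def interpolate_dem(points: GroundPointSet, template: Grid) -> Grid:
    """Interpolate a DEM through ground points onto the template grid.

    Piecewise-linear on the Delaunay triangulation inside the convex hull
    (exact on planar point sets), nearest-point value outside it.
    """
    if points.n < 3:
        raise ValueError("need >= 3 ground points to interpolate")
    xy = points.points[:, :2]
    z = points.points[:, 2]
    try:
        linear = LinearNDInterpolator(xy, z)
    except QhullError as err:
        raise ValueError(f"degenerate (collinear?) ground points: {err}") from None
    X, Y = template.pixel_centres()
    dem = linear(X, Y)
    hole = ~np.isfinite(dem)
    if hole.any():
        nearest = NearestNDInterpolator(xy, z)
        dem[hole] = nearest(X[hole], Y[hole])
    return template.with_values(dem, nodata=None)


def compute_chm(dsm: Grid, dem: Grid, clamp_negative: bool = True) -> ChmResult:
    """CHM = DSM - DEM per pixel; nodata propagates.

    With ``clamp_negative`` (default), values below zero are set to zero
    and the count of clamped pixels is returned alongside the grid.
    """
    require_aligned(dsm, dem)
    valid = dsm.valid & dem.valid
    chm = np.where(valid, dsm.values - dem.values, np.nan)
    n_clamped = 0
    if clamp_negative:
        neg = valid & (chm < 0)
        n_clamped = int(neg.sum())
        chm[neg] = 0.0
    chm = np.where(valid, chm, DEFAULT_NODATA)
    return ChmResult(grid=dsm.with_values(chm, nodata=DEFAULT_NODATA), n_clamped=n_clamped)
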