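"""Synthetic forest-scene generator.

Emulates the data products of a drone photogrammetry survey over a
subtropical eucalypt stand — terrain, a digital surface model, an RGB
orthomosaic — together with a simulated ground crew measuring tree height
and DBH at GNSS-located stems.  Everything is a pure function of its
configuration plus a seed.

Model choices:

* terrain is Gaussian-smoothed white noise rescaled to a requested relief
  amplitude (smoothing length = correlation length);
* each tree crown is a paraboloid of revolution whose apex equals the tree
  height exactly, so height recovery has a clean target;
* the DSM is the pixelwise maximum of the terrain and all crown surfaces;
* crown pixels are coloured by the tree's class colour, ground by a soil /
  dry-grass mosaic, and a fraction of each crown's southern border pixels
  is recoloured to a dark shadow tone to emulate cast shadow eating into
  the crown outline;
* field positions get isotropic Gaussian GNSS error and field heights get
  Gaussian measurement error; only trees with DBH >= 10 cm are eligible,
  matching the survey inclusion rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .raster import Grid, GridTransform, RGBOrthomosaic, require_aligned

DEFAULT_CRS = "EPSG:32756"  # UTM 56S, southeast Queensland

#: Default scene: desk-scale (~10^6 px) stand matching the study character.
DEFAULT_EXTENT = (0.0, 0.0, 100.0, 100.0)
DEFAULT_GSD = 0.10
DEFAULT_N_TREES = 120
DEFAULT_HEIGHT_RANGE = (10.0, 30.0)
DEFAULT_CROWN_RATIO = 0.15
DEFAULT_MIN_SPACING = 5.0
DEFAULT_RELIEF_AMPLITUDE = 3.0
DEFAULT_CORRELATION_LENGTH = 30.0
DEFAULT_BASE_ELEVATION = 100.0


@dataclass(frozen=True)
class Tree:
    id: int
    x: float
    y: float
    height_m: float
    crown_radius_m: float
    dbh_cm: float
    class_label: int


@dataclass
class SceneTruth:
    """Ground-truth stand description underlying a synthetic scene."""

    trees: list[Tree]
    extent: tuple[float, float, float, float]
    seed: int
    relief_amplitude: float = DEFAULT_RELIEF_AMPLITUDE
    correlation_length: float = DEFAULT_CORRELATION_LENGTH

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        for t in self.trees:
            if t.height_m <= 0 or t.crown_radius_m <= 0 or t.dbh_cm <= 0:
                raise ValueError(f"tree {t.id}: height, crown radius and DBH must be > 0")
            if not (xmin <= t.x <= xmax and ymin <= t.y <= ymax):
                raise ValueError(f"tree {t.id}: stem outside extent")

    def to_records(self) -> list[dict]:
        return [vars(t) | {} for t in self.trees]


@dataclass(frozen=True)
class FieldPoint:
    """One field-survey record: GNSS-located stem with measured height/DBH."""

    id: int
    x: float
    y: float
    height_m: float
    dbh_cm: float

    def __post_init__(self) -> None:
        if self.dbh_cm < 10:
            raise ValueError("survey inclusion rule: DBH >= 10 cm")
        if self.height_m <= 0:
            raise ValueError("height must be > 0")


@dataclass
class ColourParams:
    """Mean (R, G, B) digital numbers per scene class, 0-255 scale.

    Crown colours must be green-dominant (g fraction > b fraction) and
    ground/grass/shadow colours must not be (g <= b), so that the
    green-blue index NGBDI can separate crowns from everything else — a
    scene violating this is unlabellable and rejected.
    """

    ground: tuple[float, float, float] = (110.0, 100.0, 105.0)
    grass: tuple[float, float, float] = (150.0, 140.0, 145.0)
    crown_classes: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: {1: (60.0, 120.0, 50.0),
                                 2: (70.0, 140.0, 60.0),
                                 3: (50.0, 100.0, 45.0)})
    shadow: tuple[float, float, float] = (30.0, 28.0, 35.0)

    def validate(self) -> None:
        def frac(c):
            tot = sum(c)
            return c[1] / tot, c[2] / tot

        for label, colour in self.crown_classes.items():
            gf, bf = frac(colour)
            if not gf > bf:
                raise ValueError(f"crown class {label} colour must have g fraction > b fraction")
        for name, colour in (("ground", self.ground), ("grass", self.grass), ("shadow", self.shadow)):
            gf, bf = frac(colour)
            if gf > bf:
                raise ValueError(f"{name} colour must have g fraction <= b fraction")


def _scene_transform(extent, pixel_size) -> tuple[GridTransform, int, int]:
    xmin, ymin, xmax, ymax = extent
    ncols = int(round((xmax - xmin) / pixel_size))
    nrows = int(round((ymax - ymin) / pixel_size))
    if ncols < 1 or nrows < 1:
        raise ValueError("extent too small for pixel size")
    return GridTransform(xmin, ymax, pixel_size, -pixel_size), nrows, ncols


def generate_terrain(extent=DEFAULT_EXTENT, pixel_size=DEFAULT_GSD,
                     relief_amplitude=DEFAULT_RELIEF_AMPLITUDE,
                     correlation_length=DEFAULT_CORRELATION_LENGTH,
                     base_elevation=DEFAULT_BASE_ELEVATION, seed=0) -> Grid:
    """Smooth random ground-elevation surface.

    The elevation range is exactly 2 x relief_amplitude (min-max rescaled),
    centred on ``base_elevation``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if relief_amplitude < 0:
        raise ValueError("relief_amplitude must be >= 0")
    transform, nrows, ncols = _scene_transform(extent, pixel_size)
    if relief_amplitude == 0:
        z = np.full((nrows, ncols), base_elevation, dtype=np.float64)
    else:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((nrows, ncols))
        smooth = gaussian_filter(noise, sigma=correlation_length / pixel_size, mode="reflect")
        lo, hi = smooth.min(), smooth.max()
        if hi - lo < 1e-15:
            z = np.full((nrows, ncols), base_elevation, dtype=np.float64)
        else:
            z = base_elevation + relief_amplitude * (2 * (smooth - lo) / (hi - lo) - 1)
    return Grid(values=z, transform=transform, crs=DEFAULT_CRS, nodata=None)


def place_trees(extent=DEFAULT_EXTENT, n_trees=DEFAULT_N_TREES,
                height_range=DEFAULT_HEIGHT_RANGE, crown_ratio=DEFAULT_CROWN_RATIO,
                min_spacing=DEFAULT_MIN_SPACING, seed=0, allom_a=2.0,
                max_attempts_per_tree=2000) -> SceneTruth:
    """Place tree stems by dart-throwing with a minimum spacing.

    Heights are uniform in ``height_range``; crown radius = crown_ratio x
    height; DBH follows the linear allometry DBH_cm = allom_a x height_m
    (DBH only matters for the >=10 cm survey inclusion filter); class
    labels cycle 1, 2, 3.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = extent
    xs: list[float] = []
    ys: list[float] = []
    attempts = 0
    budget = max_attempts_per_tree * n_trees
    while len(xs) < n_trees:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n_trees} trees at min_spacing={min_spacing} m "
                f"within {budget} attempts (infeasible packing?)")
        attempts += 1
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if xs:
            d2 = (np.array(xs) - x) ** 2 + (np.array(ys) - y) ** 2
            if d2.min() < min_spacing ** 2:
                continue
        xs.append(x)
        ys.append(y)

    heights = rng.uniform(height_range[0], height_range[1], size=n_trees)
    trees = [
        Tree(id=i + 1, x=xs[i], y=ys[i], height_m=float(heights[i]),
             crown_radius_m=float(crown_ratio * heights[i]),
             dbh_cm=float(allom_a * heights[i]), class_label=(i % 3) + 1)
        for i in range(n_trees)
    ]
    return SceneTruth(trees=trees, extent=extent, seed=seed)


def _crown_window(grid: Grid, tree: Tree):
    """Rows/cols bounding the crown footprint, plus d^2 to the stem."""
    t = grid.transform
    nrows, ncols = grid.shape
    rc = tree.crown_radius_m
    c0 = max(0, int(math.floor((tree.x - rc - t.x_origin) / t.pixel_width)))
    c1 = min(ncols, int(math.ceil((tree.x + rc - t.x_origin) / t.pixel_width)) + 1)
    r0 = max(0, int(math.floor((tree.y + rc - t.y_origin) / t.pixel_height)))
    r1 = min(nrows, int(math.ceil((tree.y - rc - t.y_origin) / t.pixel_height)) + 1)
    if c0 >= c1 or r0 >= r1:
        return None
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    xc = t.x_origin + (cols + 0.5) * t.pixel_width
    yc = t.y_origin + (rows + 0.5) * t.pixel_height
    X, Y = np.meshgrid(xc, yc)
    d2 = (X - tree.x) ** 2 + (Y - tree.y) ** 2
    return (slice(r0, r1), slice(c0, c1)), d2


def crown_surface(tree: Tree, ground_at_stem: float, d2: np.ndarray) -> np.ndarray:
    """Paraboloid crown surface z(d) = ground + h (1 - (d/rc)^2) for d <= rc."""
    rc2 = tree.crown_radius_m ** 2
    z = ground_at_stem + tree.height_m * (1.0 - d2 / rc2)
    z[d2 > rc2] = -np.inf
    return z


def _ground_at_stem(terrain: Grid, tree: Tree) -> float:
    row, col = terrain.map_to_pixel(tree.x, tree.y)
    row = min(max(int(row), 0), terrain.shape[0] - 1)
    col = min(max(int(col), 0), terrain.shape[1] - 1)
    return float(terrain.values[row, col])


def render_dsm(terrain: Grid, truth: SceneTruth) -> Grid:
    """DSM = pixelwise max of terrain and every crown surface."""
    dsm = terrain.values.astype(np.float64).copy()
    for tree in truth.trees:
        win = _crown_window(terrain, tree)
        if win is None:
            continue
        sl, d2 = win
        z = crown_surface(tree, _ground_at_stem(terrain, tree), d2)
        np.maximum(dsm[sl], z, out=dsm[sl])
    return terrain.with_values(dsm, nodata=None)


def _crown_assignment(terrain: Grid, truth: SceneTruth):
    """Per-pixel winning tree index (-1 = no crown), by highest crown surface."""
    best_z = np.full(terrain.shape, -np.inf)
    owner = np.full(terrain.shape, -1, dtype=np.int32)
    for i, tree in enumerate(truth.trees):
        win = _crown_window(terrain, tree)
        if win is None:
            continue
        sl, d2 = win
        z = crown_surface(tree, _ground_at_stem(terrain, tree), d2)
        better = z > best_z[sl]
        best_z[sl][better] = z[better]
        ow = owner[sl]
        ow[better] = i
        owner[sl] = ow
    return owner


def render_orthomosaic(terrain: Grid, truth: SceneTruth,
                       colour_params: ColourParams | None = None,
                       shadow_fraction: float = 0.3, noise_sd: float = 8.0,
                       grass_fraction: float = 0.3, seed: int = 0) -> RGBOrthomosaic:
    """Render the RGB orthomosaic of a scene.

    Crown pixels take their tree's class colour; ground is a soil matrix
    with smooth dry-grass patches covering ``grass_fraction`` of it; a
    ``shadow_fraction`` of each crown's southern border pixels is set to
    the shadow colour; finally Gaussian noise of sd ``noise_sd`` DN is
    added per channel and clipped at 0.
    """
    cp = colour_params or ColourParams()
    cp.validate()
    if not 0 <= shadow_fraction <= 1:
        raise ValueError("shadow_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nrows, ncols = terrain.shape

    owner = _crown_assignment(terrain, truth)
    img = np.empty((nrows, ncols, 3), dtype=np.float64)
    img[:] = cp.ground

    if grass_fraction > 0:
        blob = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=max(2.0, 5.0 / terrain.gsd * 0.2))
        grass = blob > np.quantile(blob, 1 - grass_fraction)
        img[grass & (owner < 0)] = cp.grass

    for i, tree in enumerate(truth.trees):
        img[owner == i] = cp.crown_classes[tree.class_label]

    if shadow_fraction > 0:
        crown_mask = owner >= 0
        interior = binary_erosion(crown_mask, structure=np.ones((3, 3)))
        border = crown_mask & ~interior
        for i, tree in enumerate(truth.trees):
            stem_row, _ = terrain.map_to_pixel(tree.x, tree.y)
            rows_b, cols_b = np.nonzero(border & (owner == i))
            south = rows_b > stem_row  # larger row = smaller y = south
            rows_b, cols_b = rows_b[south], cols_b[south]
            n_shadow = int(round(shadow_fraction * rows_b.size))
            if n_shadow:
                pick = rng.choice(rows_b.size, size=n_shadow, replace=False)
                img[rows_b[pick], cols_b[pick]] = cp.shadow

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    bands = [terrain.with_values(img[:, :, k], nodata=None) for k in range(3)]
    return RGBOrthomosaic(red=bands[0], green=bands[1], blue=bands[2])


def simulate_field_survey(truth: SceneTruth, gnss_sd: float = 0.10,
                          height_error_sd: float = 0.5, n_points: int = 116,
                          seed: int = 0) -> list[FieldPoint]:
    """Simulate a ground crew measuring ``n_points`` trees.

    Trees are sampled without replacement from those meeting the DBH >= 10
    cm inclusion rule; recorded positions get per-axis Gaussian GNSS error
    and recorded heights get Gaussian measurement error.
    """
    eligible = [t for t in truth.trees if t.dbh_cm >= 10.0]
    if n_points > len(eligible):
        raise ValueError(f"only {len(eligible)} trees meet the DBH >= 10 cm rule; "
                         f"cannot survey {n_points}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_points, replace=False)
    points = []
    for idx in chosen:
        t = eligible[idx]
        points.append(FieldPoint(
            id=t.id,
            x=t.x + rng.normal(0.0, gnss_sd) if gnss_sd > 0 else t.x,
            y=t.y + rng.normal(0.0, gnss_sd) if gnss_sd > 0 else t.y,
            height_m=t.height_m + (rng.normal(0.0, height_error_sd) if height_error_sd > 0 else 0.0),
            dbh_cm=t.dbh_cm,
        ))
    return points
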