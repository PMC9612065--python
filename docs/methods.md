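# Methods

This note documents the models, conventions, parameter choices and
limitations behind `dronecanopy`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Raster model and conventions

All stages share one raster currency (`Grid`): a 2-D array, an affine
pixel→map transform, a CRS tag and a nodata sentinel (−9999.0 for produced
float rasters). Pixel (0, 0) is the top-left cell, the map coordinate of a
pixel is its **centre**, and y decreases with increasing row — the dominant
geospatial convention. Rasters with differing transforms are rejected rather
than silently resampled: the analysis assumes one common photogrammetric
product grid, and resampling would hide registration errors. A projected,
metre-unit CRS is required for areas and buffer distances to be meaningful;
files without one are read with a warning and a `crs=None` ambiguity flag.
GeoTIFF I/O is implemented on `tifffile` with the standard georeferencing
tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA), so
files interoperate with GDAL-based GIS software; round-trips are value-exact
for float32 and integer payloads.

## Spectral indices

Digital numbers are normalised per pixel to fractions r, g, b that sum to
one; all twelve colour indices are evaluated **on the normalised bands**,
even where an index's original publication used raw digital numbers, because
the workflow this package implements computes them that way. Consequences
used as test invariants: every index is invariant to uniform brightness
scaling; ExGR = ExG − ExR; GLA = ExG/(1 + g) (since 2g + r + b = 1 + g); and
MGRVI = 2·NGRDI/(1 + NGRDI²). Pixels where a formula's denominator falls
below 1e−12 in magnitude (VARI at g + r − b = 0; WI at r = g) become nodata
rather than ±inf so that downstream thresholding never sees infinities.

On the naming of NGBDI: the green–blue formula (g − b)/(g + b) circulates
under inconsistent names and abbreviations in the applied literature
(sometimes labelled as a green–red index, sometimes NGBVI). This package
uses the formula as written and the abbreviation NGBDI throughout.

## Vegetation mask and crowns

The default masking index is NGBDI because green-dominant crowns (g > b)
score positive while soil, dry grass and shadow (g ≤ b) score non-positive.
The threshold is Otsu's method on the valid-pixel histogram (256 bins over
the observed range) by default — a reproducible stand-in for a threshold
chosen by visual inspection — with an explicit override available. Cleaning
is a morphological closing (disc radius 1 px by default) followed by removal
of 8-connected patches smaller than 1 m². Each remaining component becomes
one crown polygon: exact pixel-boundary geometry (union of per-row pixel
runs) simplified by Douglas–Peucker with tolerance 2 × GSD, topology
preserved, so the unsimplified polygon area equals pixel count × pixel area
exactly and the simplified area differs by at most perimeter × tolerance.
Ids are sequential in top-most-then-left-most order. Touching crowns are
deliberately **not** split — each connected vegetated region is one unit;
watershed-style separation of merged canopies is out of scope.

Crown classification into k = 3 classes uses equal-count quantile breaks of
the per-crown mean index, ties going to the lower class. This is a declared
stand-in for whatever visual reclassification produced three classes in
comparable workflows; it is deterministic and order-forced, which makes it
testable, but it imposes equal class counts where colours are not well
separated.

## Ground points, DEM, CHM

Ground elevations are read from the DSM at randomly sampled mask-0 pixels
(uniform, without replacement, pixel-centre coordinates) — there is no
separate ground survey in this workflow. The default density is one point
per 25 m² (~400 points on the default scene), enough for a stable
triangulation at desk scale. The DEM is piecewise-linear interpolation on
the Delaunay triangulation of those points, with nearest-point fill outside
the convex hull: parameter-free and exact on planes, which the tests exploit
as an oracle. CHM = DSM − DEM per pixel; negative values (DEM interpolation
error over ground) are clamped to zero by default because heights are
physical, and the clamped-pixel count is returned so the clamping is never
silent.

Error structure worth knowing: the crown apex lies up to half a pixel
diagonal from the nearest pixel centre, so the rendered DSM maximum
underestimates a tree's height by at most ε_apex = h·(gsd/(√2·r_c))² (≈ 7 mm
for a 30 m tree with a 4.5 m crown at 0.10 m GSD); the DEM error is the
dominant term and is measured, not assumed, wherever the tests bound height
recovery.

## Zonal statistics and validation

A pixel belongs to a crown iff its centre is inside the polygon; the same
centre-distance convention defines the 1 m validation buffer. Both
operations are checked exactly against brute-force all-pixel scans. The 95th
percentile interpolates linearly between order statistics; the sd is the
population sd (a single-pixel crown reports sd = 0). The inventory table
aggregates the per-crown CHM maximum as the tree-height estimate.

Validation pairs each field point with the buffer-maximum CHM height — no
tree-identity matching, since the 1 m buffer absorbs GNSS error up to
0.10 m. The Pearson r, the t-transform t = r√((n−2)/(1−r²)) and the OLS fit
of field height on CHM height are computed in closed form by this package;
only the Student-t CDF evaluation is delegated to scipy, and the whole test
is cross-checked against an independent reference implementation in the
suite. The reported RMSE is the residual RMSE of the OLS fit; bias is
mean(chm − field). The p-value is two-sided.

## Synthetic scenes: what they emulate, and what they do not

The generator reproduces the statistical structure the analysis relies on,
with defaults frozen as the study conditions:

| parameter | default | why |
|---|---|---|
| extent / GSD | 100 × 100 m at 0.10 m | desk-scale (10⁶ px) stand, drone-typical GSD |
| trees | 120, heights uniform 10–30 m | eucalypt-range heights; > 116 so a 116-point survey is samplable |
| crown radius | 0.15 × height | realistic crown:height ratio; crowns 1.5–4.5 m |
| stem spacing | ≥ 5 m | open managed stand; some crowns still touch and merge |
| terrain | amplitude 3 m, correlation 30 m, base 100 m | gentle relief: Gaussian-smoothed white noise rescaled to the amplitude |
| colours | crown classes green-dominant; soil/grass/shadow g ≤ b | guarantees NGBDI separability, checked as a precondition |
| noise / shadow | sd 8 DN; 30% of each crown's southern border | sensor noise; directional cast shadow as a nuisance |
| survey | n = 116, GNSS sd 0.10 m, height error sd 0.5 m | survey design with differential-GNSS accuracy and hypsometer-scale height error |
| DBH | 2 × height (cm), inclusion rule ≥ 10 cm | DBH matters only for the inclusion filter |

Crowns are paraboloids of revolution so the apex equals the true height
exactly — a clean recovery target. Shadows are rendered by recolouring
border pixels to a dark tone with g ≤ b rather than by dimming: a pure
brightness change would be invisible to ratio indices, whereas a colour
shift pushes those pixels over the threshold to the ground class, which is
the actual failure mode shadow causes in this analysis (eroded crown
outlines, occasional contaminated ground points under the canopy edge).

What the generator does **not** emulate: radiometric realism or BRDF
effects, within-crown texture, photogrammetric reconstruction artefacts
(doming, smearing between close crowns, holes under dense canopy),
off-terrain objects, understorey vegetation with crown-like colour, or
stems leaning away from crown centres. Passing tests therefore show that
the analysis chain is internally correct and recovers heights under the
stated noise model; they do not show that a particular real forest will
validate equally well.

## Numerical and design choices

- One global seed fans out to per-stage sub-seeds by fixed offsets
  (terrain +0, trees +1, orthomosaic +2, survey +3, ground points +4), so a
  whole run is reproducible from one integer and any stage can be re-run in
  isolation. CSV/JSON outputs of identical runs are byte-identical.
- Tree placement is dart-throwing with a bounded attempt budget; an
  infeasible packing raises rather than silently degrading density.
- Where crowns overlap, the pixel's colour follows the highest crown
  surface, consistent with the DSM maximum.
- Quantile-break ties in crown classification go to the lower class; crown
  component ids are ordered top-most then left-most — both pinned so tests
  are exact.
- Problem sizes in the test suite: most tests run on scenes from 20 × 20 m
  (5 trees) to 50 × 50 m; the end-to-end recovery checks run the full
  default 100 × 100 m stand twice (clean and noisy), a few seconds each.

## Known limitations

- Merged crowns are reported as one unit; per-stem inventory in closed
  canopy requires a segmentation step this package intentionally omits.
- Otsu assumes a bimodal index histogram; scenes dominated by vegetation or
  by ground can push the threshold into one mode (the explicit-threshold
  override exists for that case).
- The DEM is only as good as the visible-ground sampling: under fully
  closed canopy the nearest ground pixels can be tens of metres away and
  heights will be biased by the interpolated surface.
- The buffer-max validation rule is biased toward the tallest nearby tree;
  with dense mixed-height stands and larger GNSS error it can pair a stem
  with a taller neighbour's crown.
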