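import numpy as np
import pytest

from dronecanopy import (GroundPointSet, compute_chm, generate_terrain,
                         interpolate_dem, sample_ground_points)
from dronecanopy.mask import VegetationMask
from dronecanopy.raster import RasterAlignmentError

from conftest import make_grid


def as_mask(binary, gsd=1.0):
    g = make_grid(np.asarray(binary, dtype=np.float64), gsd=gsd)
    return VegetationMask(mask=g, source_index="NGBDI", threshold=0.0)


class TestSampleGroundPoints:
    def test_all_ground_sample_everything(self):
        dsm = make_grid(np.arange(36, dtype=float).reshape(6, 6), nodata=None)
        mask = as_mask(np.zeros((6, 6)))
        gp = sample_ground_points(mask, dsm, 36, seed=0)
        assert gp.n == 36
        assert len({tuple(p) for p in gp.points[:, :2]}) == 36

    def test_points_only_on_ground_pixels(self):
        rng = np.random.default_rng(1)
        binary = rng.integers(0, 2, (20, 20))
        dsm = make_grid(rng.normal(100, 2, (20, 20)), nodata=None)
        mask = as_mask(binary)
        gp = sample_ground_points(mask, dsm, 50, seed=2)
        for x, y, z in gp.points:
            r, c = dsm.map_to_pixel(x, y)
            assert binary[r, c] == 0
            assert z == dsm.values[r, c]

    def test_determinism(self):
        dsm = make_grid(np.zeros((10, 10)), nodata=None)
        mask = as_mask(np.zeros((10, 10)))
        a = sample_ground_points(mask, dsm, 20, seed=7)
        b = sample_ground_points(mask, dsm, 20, seed=7)
        np.testing.assert_array_equal(a.points, b.points)

    def test_too_few_ground_pixels(self):
        dsm = make_grid(np.zeros((3, 3)), nodata=None)
        mask = as_mask(np.ones((3, 3)))
        with pytest.raises(ValueError):
            sample_ground_points(mask, dsm, 1, seed=0)

    def test_dsm_nodata_pixels_never_sampled(self):
        vals = np.zeros((5, 5))
        vals[2, 2] = -9999.0
        dsm = make_grid(vals)
        mask = as_mask(np.zeros((5, 5)))
        gp = sample_ground_points(mask, dsm, 24, seed=3)
        assert all((x, y) != dsm.pixel_to_map(2, 2) for x, y, _ in gp.points)


class TestInterpolateDem:
    def test_plane_reproduced_exactly_inside_hull(self):
        rng = np.random.default_rng(4)
        template = make_grid(np.zeros((40, 40)), gsd=0.5)  # map y in (-20, 0)
        x = rng.uniform(0, 20, 60)
        y = -rng.uniform(0, 20, 60)
        z = 2.0 * x + 3.0 * y + 10.0
        gp = GroundPointSet(points=np.column_stack([x, y, z]), seed=0)
        dem = interpolate_dem(gp, template)
        X, Y = template.pixel_centres()
        from scipy.spatial import Delaunay

        inside = Delaunay(gp.points[:, :2]).find_simplex(
            np.column_stack([X.ravel(), Y.ravel()])) >= 0
        expected = (2.0 * X + 3.0 * Y + 10.0).ravel()[inside]
        np.testing.assert_allclose(dem.values.ravel()[inside], expected, atol=1e-9)

    def test_constant_points_give_constant_dem(self):
        rng = np.random.default_rng(5)
        template = make_grid(np.zeros((20, 20)), gsd=1.0)
        xy = np.column_stack([rng.uniform(0, 20, 30), -rng.uniform(0, 20, 30)])
        gp = GroundPointSet(points=np.column_stack([xy, np.full(30, 77.0)]), seed=0)
        dem = interpolate_dem(gp, template)
        np.testing.assert_allclose(dem.values, 77.0, atol=1e-9)

    def test_collinear_points_rejected(self):
        template = make_grid(np.zeros((5, 5)))
        pts = np.array([[0.0, 0.0, 1.0], [1.0, -1.0, 2.0], [2.0, -2.0, 3.0]])
        with pytest.raises(ValueError):
            interpolate_dem(GroundPointSet(points=pts, seed=0), template)

    def test_against_barycentric_oracle_on_smooth_terrain(self):
        """Independent per-pixel barycentric evaluation at 50 random pixels."""
        from scipy.spatial import Delaunay

        terrain = generate_terrain((0, 0, 50, 50), 0.1, 3.0, 30.0, 100.0, seed=6)
        rng = np.random.default_rng(7)
        rows = rng.integers(0, terrain.shape[0], 200)
        cols = rng.integers(0, terrain.shape[1], 200)
        x, y = terrain.transform.pixel_to_map(rows, cols)
        z = terrain.values[rows, cols]
        gp = GroundPointSet(points=np.column_stack([x, y, z]), seed=0)
        dem = interpolate_dem(gp, terrain)

        tri = Delaunay(gp.points[:, :2])
        check_r = rng.integers(0, terrain.shape[0], 50)
        check_c = rng.integers(0, terrain.shape[1], 50)
        qx, qy = terrain.transform.pixel_to_map(check_r, check_c)
        simplex = tri.find_simplex(np.column_stack([qx, qy]))
        for r, c, px, py, s in zip(check_r, check_c, qx, qy, simplex):
            if s < 0:
                continue  # outside hull: nearest fill, not covered by this oracle
            verts = tri.simplices[s]
            T = tri.transform[s]
            bary = T[:2] @ (np.array([px, py]) - T[2])
            lam = np.array([bary[0], bary[1], 1 - bary.sum()])
            expected = float(lam @ gp.points[verts, 2])
            assert dem.values[r, c] == pytest.approx(expected, abs=1e-8)


class TestComputeChm:
    def test_equal_surfaces_give_zero(self):
        g = make_grid(np.full((5, 5), 321.0), nodata=None)
        chm, n = compute_chm(g, g)
        assert n == 0
        np.testing.assert_array_equal(chm.values, 0.0)

    def test_subtraction(self):
        dsm = make_grid([[512.3]], nodata=None)
        dem = make_grid([[500.0]], nodata=None)
        chm, _ = compute_chm(dsm, dem)
        assert chm.values[0, 0] == pytest.approx(12.3)

    def test_clamping_and_count(self):
        dsm = make_grid([[499.5, 505.0]], nodata=None)
        dem = make_grid([[500.0, 500.0]], nodata=None)
        clamped, n = compute_chm(dsm, dem, clamp_negative=True)
        assert n == 1 and clamped.values[0, 0] == 0.0
        raw, n0 = compute_chm(dsm, dem, clamp_negative=False)
        assert n0 == 0 and raw.values[0, 0] == pytest.approx(-0.5)

    def test_nodata_propagates(self):
        dsm = make_grid([[-9999.0, 505.0]])
        dem = make_grid([[500.0, 500.0]], nodata=None)
        chm, _ = compute_chm(dsm, dem)
        assert not chm.valid[0, 0] and chm.values[0, 1] == pytest.approx(5.0)

    def test_misaligned_rejected(self):
        dsm = make_grid(np.zeros((4, 4)), nodata=None)
        dem = make_grid(np.zeros((4, 4)), gsd=2.0, nodata=None)
        with pytest.raises(RasterAlignmentError):
            compute_chm(dsm, dem)

    def test_chm_near_zero_outside_crowns_on_scene(self, tiny_scene):
        """Noise-free scene: |CHM| off-crown is bounded by the DEM error."""
        from conftest import truth_footprint
        from dronecanopy import (clean_mask, compute_index, normalize_bands,
                                 reclassify_index)

        nb = normalize_bands(tiny_scene["ortho"])
        mask = clean_mask(reclassify_index(compute_index(nb, "NGBDI"), 0.2), 0.5, 0)
        dsm = tiny_scene["dsm"]
        gp = sample_ground_points(mask, dsm, 120, seed=8)
        dem = interpolate_dem(gp, dsm)
        chm, _ = compute_chm(dsm, dem, clamp_negative=False)
        eps_dem = np.abs(dem.values - tiny_scene["terrain"].values).max()
        outside = ~truth_footprint(tiny_scene["terrain"], tiny_scene["truth"])
        assert np.abs(chm.values[outside]).max() <= eps_dem + 1e-9

    def test_dem_accuracy_not_degraded_by_more_points(self):
        """Median |DEM - truth| does not increase with ground-point count."""
        terrain = generate_terrain((0, 0, 30, 30), 0.2, 3.0, 30.0, 100.0, seed=9)
        mask = VegetationMask(mask=terrain.with_values(np.zeros(terrain.shape)),
                              source_index="NGBDI", threshold=0.0)
        medians = []
        for n in (30, 120, 480):
            errs = []
            for seed in range(5):
                gp = sample_ground_points(mask, terrain, n, seed=seed)
                dem = interpolate_dem(gp, terrain)
                errs.append(np.median(np.abs(dem.values - terrain.values)))
            medians.append(np.median(errs))
        assert medians[2] <= medians[0] + 1e-6
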