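import numpy as np
import pytest

from dronecanopy import (IndexRaster, classify_crowns, clean_mask, compute_index,
                         extract_crown_polygons, normalize_bands, reclassify_index)
from dronecanopy.mask import VegetationMask

from conftest import make_grid, truth_footprint


def index_raster(values, gsd=1.0, nodata=-9999.0):
    return IndexRaster(name="NGBDI", grid=make_grid(values, gsd=gsd, nodata=nodata))


def as_mask(binary, gsd=1.0):
    g = make_grid(np.asarray(binary, dtype=np.float64), gsd=gsd)
    return VegetationMask(mask=g, source_index="NGBDI", threshold=0.0)


class TestReclassify:
    def test_fixed_threshold_recovers_crown_footprints(self, tiny_scene):
        """Noise-free scene: pixels above 0.2 are exactly the crown-coloured ones."""
        nb = normalize_bands(tiny_scene["ortho"])
        ngbdi = compute_index(nb, "NGBDI")
        mask = reclassify_index(ngbdi, threshold=0.2)
        fp = truth_footprint(tiny_scene["terrain"], tiny_scene["truth"])
        np.testing.assert_array_equal(mask.vegetation, fp)

    def test_auto_threshold_separates_bimodal(self):
        vals = np.concatenate([np.full(500, 0.0), np.full(500, 0.43)])
        rng = np.random.default_rng(0)
        vals += rng.normal(0, 0.01, vals.size)
        mask = reclassify_index(index_raster(vals.reshape(20, 50)), "auto")
        # threshold must fall in the gap between the two modes
        assert vals[:500].max() <= mask.threshold < vals[500:].min()
        assert mask.vegetation.sum() == 500

    def test_threshold_above_max_gives_empty_mask(self):
        mask = reclassify_index(index_raster([[0.1, 0.4], [0.2, 0.3]]), threshold=0.5)
        assert mask.vegetation.sum() == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        idx = index_raster(rng.uniform(-1, 1, (30, 30)))
        lo = reclassify_index(idx, threshold=0.1).vegetation
        hi = reclassify_index(idx, threshold=0.5).vegetation
        assert not (hi & ~lo).any()  # hi subset of lo

    def test_auto_on_constant_raster_raises(self):
        with pytest.raises(ValueError):
            reclassify_index(index_raster(np.full((5, 5), 0.3)), "auto")

    def test_nodata_propagates(self):
        mask = reclassify_index(index_raster([[0.4, -9999.0]]), threshold=0.2)
        assert mask.vegetation[0, 0] and not mask.mask.valid[0, 1]


class TestCleanMask:
    def test_identity_parameters(self):
        rng = np.random.default_rng(4)
        m = as_mask(rng.integers(0, 2, (20, 20)))
        out = clean_mask(m, 0.0, 0)
        np.testing.assert_array_equal(out.vegetation, m.vegetation)

    def test_small_patch_removed_by_area(self):
        # 5 pixels at gsd 0.1 m -> 0.05 m^2 < 0.1 m^2 minimum
        binary = np.zeros((20, 20))
        binary[10, 5:10] = 1
        out = clean_mask(as_mask(binary, gsd=0.1), min_patch_area_m2=0.1, closing_radius_px=0)
        assert out.vegetation.sum() == 0

    def test_patch_at_exact_minimum_kept(self):
        binary = np.zeros((20, 20))
        binary[10, 5:15] = 1  # 10 px x 0.01 m^2 = 0.1 m^2, not smaller
        out = clean_mask(as_mask(binary, gsd=0.1), min_patch_area_m2=0.1, closing_radius_px=0)
        assert out.vegetation.sum() == 10

    def test_min_area_larger_than_everything_empties(self):
        rng = np.random.default_rng(5)
        m = as_mask(rng.integers(0, 2, (15, 15)), gsd=0.1)
        out = clean_mask(m, min_patch_area_m2=1e6, closing_radius_px=0)
        assert out.vegetation.sum() == 0

    def test_closing_bridges_small_gap(self):
        binary = np.zeros((9, 9))
        binary[3:6, 2:4] = 1
        binary[3:6, 5:7] = 1   # one-pixel slit at column 4
        out = clean_mask(as_mask(binary), min_patch_area_m2=0.0, closing_radius_px=1)
        assert out.vegetation[4, 4]

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            clean_mask(as_mask(np.zeros((3, 3))), -1.0, 0)


class TestExtractCrowns:
    def test_square_patch_exact_area(self):
        binary = np.zeros((20, 20))
        binary[5:15, 5:15] = 1  # 10x10 px at gsd 0.1 -> 1 m^2
        crowns = extract_crown_polygons(as_mask(binary, gsd=0.1), simplify_tol_m=0.0)
        assert len(crowns) == 1
        assert crowns[0].area_m2 == pytest.approx(1.0, abs=1e-9)

    def test_two_separated_patches(self):
        binary = np.zeros((10, 10))
        binary[1:3, 1:3] = 1
        binary[6:8, 6:9] = 1
        crowns = extract_crown_polygons(as_mask(binary), simplify_tol_m=0.0)
        assert len(crowns) == 2
        # id 1 is the top-most patch
        assert crowns[0].polygon.bounds[3] > crowns[1].polygon.bounds[3]

    def test_diagonal_pixels_are_one_component(self):
        binary = np.zeros((5, 5))
        binary[1, 1] = binary[2, 2] = 1  # touching only at a corner: 8-connected
        crowns = extract_crown_polygons(as_mask(binary), simplify_tol_m=0.0)
        assert len(crowns) == 1
        assert crowns[0].area_m2 == pytest.approx(2.0, abs=1e-9)

    def test_empty_mask_gives_empty_list(self):
        assert extract_crown_polygons(as_mask(np.zeros((5, 5)))) == []

    def test_polygon_count_matches_touching_analysis(self, tiny_scene):
        """Noise-free scene: one polygon per group of touching crowns."""
        from skimage.measure import label as cc_label

        nb = normalize_bands(tiny_scene["ortho"])
        mask = reclassify_index(compute_index(nb, "NGBDI"), threshold=0.2)
        crowns = extract_crown_polygons(mask, simplify_tol_m=0.0)
        fp = truth_footprint(tiny_scene["terrain"], tiny_scene["truth"])
        expected = cc_label(fp, connectivity=2).max()
        assert len(crowns) == expected

    def test_area_sum_matches_pixel_count_within_tolerance(self, tiny_scene):
        nb = normalize_bands(tiny_scene["ortho"])
        mask = reclassify_index(compute_index(nb, "NGBDI"), threshold=0.2)
        tol = 2 * mask.mask.gsd
        crowns = extract_crown_polygons(mask, simplify_tol_m=tol)
        pixel_area_total = mask.vegetation.sum() * mask.mask.pixel_area
        bound = sum(c.polygon.length * tol for c in crowns)
        assert abs(sum(c.area_m2 for c in crowns) - pixel_area_total) <= bound

    def test_every_stem_in_exactly_one_polygon(self, tiny_scene):
        import shapely

        nb = normalize_bands(tiny_scene["ortho"])
        mask = reclassify_index(compute_index(nb, "NGBDI"), threshold=0.2)
        crowns = extract_crown_polygons(mask)
        for t in tiny_scene["truth"].trees:
            hits = [c.id for c in crowns if shapely.contains_xy(c.polygon, t.x, t.y)]
            assert len(hits) == 1


class TestClassifyCrowns:
    def _crowns_with_means(self, means):
        """One 3x3-pixel crown per requested mean, spaced apart."""
        n = len(means)
        vals = np.full((5, 5 * n), -9999.0)
        binary = np.zeros((5, 5 * n))
        for i, m in enumerate(means):
            vals[1:4, 5 * i + 1:5 * i + 4] = m
            binary[1:4, 5 * i + 1:5 * i + 4] = 1
        idx = index_raster(vals)
        crowns = extract_crown_polygons(as_mask(binary), simplify_tol_m=0.0)
        return idx, crowns

    def test_three_distinct_means_order_forced(self):
        idx, crowns = self._crowns_with_means([0.2, 0.5, 0.8])
        labelled = classify_crowns(idx, crowns, k=3)
        assert [c.class_label for c in labelled] == [1, 2, 3]

    def test_identical_means_all_lowest_class(self):
        idx, crowns = self._crowns_with_means([0.4, 0.4, 0.4, 0.4])
        labelled = classify_crowns(idx, crowns, k=3)
        assert all(c.class_label == 1 for c in labelled)

    def test_fewer_crowns_than_k_raises(self):
        idx, crowns = self._crowns_with_means([0.2, 0.5])
        with pytest.raises(ValueError):
            classify_crowns(idx, crowns, k=3)

    def test_scene_class_recovery_up_to_permutation(self):
        """Three distinct crown colours, two trees each: the NGBDI tercile
        partition must reproduce the truth classes up to label permutation."""
        import shapely

        from dronecanopy import generate_terrain, render_orthomosaic
        from dronecanopy.scene import SceneTruth, Tree

        extent = (0.0, 0.0, 21.0, 14.0)
        positions = [(3.5, 3.5), (10.5, 3.5), (17.5, 3.5),
                     (3.5, 10.5), (10.5, 10.5), (17.5, 10.5)]
        trees = [Tree(id=i + 1, x=x, y=y, height_m=12.0, crown_radius_m=1.8,
                      dbh_cm=24.0, class_label=(i % 3) + 1)
                 for i, (x, y) in enumerate(positions)]
        truth = SceneTruth(trees=trees, extent=extent, seed=0)
        terrain = generate_terrain(extent, 0.2, 0.0, 8.0, 100.0, seed=0)
        ortho = render_orthomosaic(terrain, truth, noise_sd=0.0, shadow_fraction=0.0, seed=0)
        ngbdi = compute_index(normalize_bands(ortho), "NGBDI")
        crowns = extract_crown_polygons(reclassify_index(ngbdi, threshold=0.2))
        assert len(crowns) == 6
        labelled = classify_crowns(ngbdi, crowns, k=3)
        mapping: dict[int, set[int]] = {}
        for c in labelled:
            stem = next(t for t in trees if shapely.contains_xy(c.polygon, t.x, t.y))
            mapping.setdefault(c.class_label, set()).add(stem.class_label)
        assert sorted(mapping) == [1, 2, 3]
        assert all(len(v) == 1 for v in mapping.values())
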