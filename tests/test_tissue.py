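"""Tissue morphology metrics: perimeter, fractal dimension, lacunarity,
and the scope-aggregated feature families."""

import numpy as np
import pytest

from hifquant.contours import mask_perimeter_px
from hifquant.slides import connected_components, region_mask
from hifquant.tissue import (
    SlideRegions,
    architecture_features,
    area_multiplicity_features,
    component_boundary_pixels,
    fractal_dimension,
    lacunarity,
    morphology_features,
    perimeter,
)

from conftest import make_slide


def disk_mask(r, pad=50):
    n = 2 * (r + pad)
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - n / 2.0) ** 2 + (yy - n / 2.0) ** 2 <= r * r


class TestPerimeter:
    def test_square_shape_roughness_is_sixteen(self):
        mask = np.zeros((220, 220), bool)
        mask[10:210, 10:210] = True
        p = mask_perimeter_px(mask)
        assert p == pytest.approx(4 * 200, abs=1e-9)
        assert p ** 2 / mask.sum() == pytest.approx(16.0, abs=1e-9)

    def test_disk_shape_roughness_near_four_pi(self):
        mask = disk_mask(500)
        p = mask_perimeter_px(mask)
        assert p ** 2 / mask.sum() == pytest.approx(4 * np.pi, rel=0.02)

    def test_rectangle_closed_form(self):
        mask = np.zeros((100, 150), bool)
        mask[10:90, 10:130] = True
        assert perimeter(mask, mpp=4.0) == pytest.approx(2 * (80 + 120) * 4.0)

    def test_single_pixel_is_pixel_square(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        assert perimeter(mask, mpp=4.0) == pytest.approx(16.0)

    def test_annulus_includes_hole_boundary(self):
        yy, xx = np.mgrid[0:200, 0:200]
        d2 = (xx - 100.0) ** 2 + (yy - 100.0) ** 2
        mask = (d2 <= 80 ** 2) & (d2 >= 40 ** 2)
        p = mask_perimeter_px(mask)
        assert p == pytest.approx(2 * np.pi * (80 + 40), rel=0.02)

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            perimeter(np.zeros((4, 4), bool), mpp=4.0)


class TestFractalDimension:
    def test_straight_interface_dimension_one(self):
        # the pixels on both sides of a straight horizontal interface
        # across a 1024-wide raster
        pts = np.array([(r, c) for r in (511, 512) for c in range(1024)])
        assert fractal_dimension(pts) == pytest.approx(1.0, abs=0.05)

    def test_filled_square_boundary_dimension_one(self):
        mask = np.zeros((600, 600), bool)
        mask[50:550, 50:550] = True
        boundary = component_boundary_pixels(mask)
        assert fractal_dimension(boundary) == pytest.approx(1.0, abs=0.1)

    def test_full_plane_dimension_two_with_exact_counts(self):
        w = 256
        pts = np.argwhere(np.ones((w, w), bool))
        # oracle: N(eps) = ceil(w/eps)^2 for the filled square
        for eps in (2, 4, 8, 16):
            boxes = np.unique(pts // eps, axis=0)
            assert len(boxes) == int(np.ceil(w / eps)) ** 2
        assert fractal_dimension(pts) == pytest.approx(2.0, abs=0.05)

    def test_degenerate_single_pixel_is_nan(self):
        assert np.isnan(fractal_dimension(np.array([[3, 3]])))


class TestLacunarity:
    def test_filled_mask_is_one(self):
        assert lacunarity(np.ones((64, 64), bool), 16) == pytest.approx(1.0)

    def test_bernoulli_mask_matches_moment_formula(self):
        p, r = 0.3, 8
        rng = np.random.default_rng(0)
        mask = rng.random((512, 512)) < p
        expect = 1 + (1 - p) / (p * r * r)
        assert lacunarity(mask, r) == pytest.approx(expect, rel=0.02)

    def test_checkerboard_decreases_with_window(self):
        tile = 8
        n = 128
        yy, xx = np.mgrid[0:n, 0:n]
        board = ((yy // tile + xx // tile) % 2).astype(bool)
        assert lacunarity(board, tile) > lacunarity(board, 2 * tile)

    def test_matches_exhaustive_window_enumeration(self, rng):
        mask = rng.random((20, 20)) < 0.4
        r = 5
        masses = [mask[i:i + r, j:j + r].sum()
                  for i in range(20 - r + 1) for j in range(20 - r + 1)]
        masses = np.array(masses, float)
        expect = (masses ** 2).mean() / masses.mean() ** 2
        assert lacunarity(mask, r) == pytest.approx(expect)

    def test_box_larger_than_raster_rejected(self):
        with pytest.raises(ValueError):
            lacunarity(np.ones((8, 8), bool), 9)


class TestMorphologyFeatures:
    def test_single_rectangle_sd_zero_and_solidity_one(self):
        raster = np.zeros((64, 64), np.uint8)
        raster[10:40, 10:50] = 1
        slide = make_slide(raster)
        morph = morphology_features(slide)
        arch = architecture_features(slide)
        for k, v in morph.items():
            if k.endswith(".sig_sd") and ".CT." in k:
                assert v == 0.0, k
        assert arch["arch.CT.solidity.largest"] == pytest.approx(1.0)
        assert morph["morph.CT.extent_bbox.largest"] == pytest.approx(1.0)

    def test_eccentricity_disk_low_thin_rectangle_high(self):
        raster = np.zeros((240, 240), np.uint8)
        yy, xx = np.mgrid[0:240, 0:240]
        raster[(xx - 120.0) ** 2 + (yy - 120.0) ** 2 <= 80 ** 2] = 1
        slide = make_slide(raster)
        assert (morphology_features(slide)["morph.CT.eccentricity.largest"]
                == pytest.approx(0.0, abs=0.02))
        raster = np.zeros((60, 420), np.uint8)
        raster[20:40, 10:410] = 1  # 400 × 20 px bar
        slide = make_slide(raster)
        assert morphology_features(slide)["morph.CT.eccentricity.largest"] >= 0.99

    def test_euler_numbers_annulus_and_disjoint_disks(self):
        yy, xx = np.mgrid[0:120, 0:120]
        d2 = (xx - 60.0) ** 2 + (yy - 60.0) ** 2
        raster = ((d2 <= 40 ** 2) & (d2 >= 15 ** 2)).astype(np.uint8)
        slide = make_slide(raster)
        assert morphology_features(slide)["morph.CT.euler_number.largest"] == 0.0
        raster = np.zeros((60, 120), np.uint8)
        raster[(xx[:60] - 30) ** 2 + (yy[:60] - 30) ** 2 <= 12 ** 2] = 1
        raster[(xx[:60] - 90) ** 2 + (yy[:60] - 30) ** 2 <= 12 ** 2] = 1
        slide = make_slide(raster)
        comps = connected_components(region_mask(slide, "CT"))
        assert len(comps) == 2
        m = morphology_features(slide)
        # each solid disk has Euler number 1; the mask total is 2
        assert m["morph.CT.euler_number.sig_mean"] == pytest.approx(1.0)

    def test_empty_region_gives_nan(self):
        slide = make_slide(np.zeros((32, 32), np.uint8))
        m = morphology_features(slide)
        assert all(np.isnan(v) for v in m.values())

    def test_scale_invariance_of_dimensionless_metrics(self):
        # a genuine 2× rescaling (bilinear, so the boundary stays smooth at
        # the finer grid; nearest-neighbor blocks would legitimately add
        # corner structure and change roughness)
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter, zoom
        field = gaussian_filter(rng.normal(size=(80, 80)), 6)
        blob = field > 0.02
        up = zoom(field, 2.0, order=1) > 0.02
        s1 = make_slide(blob.astype(np.uint8))
        s2 = make_slide(up.astype(np.uint8))
        m1, m2 = morphology_features(s1), morphology_features(s2)
        a1, a2 = architecture_features(s1), architecture_features(s2)
        for key in ("morph.CT.shape_roughness.largest",
                    "morph.CT.eccentricity.largest",
                    "morph.CT.extent_bbox.largest"):
            assert m2[key] == pytest.approx(m1[key], rel=0.015), key
        assert a2["arch.CT.solidity.largest"] == pytest.approx(
            a1["arch.CT.solidity.largest"], rel=0.015)


class TestArchitectureFeatures:
    def test_plus_sign_solidity_matches_hull_oracle(self):
        raster = np.zeros((64, 64), np.uint8)
        raster[24:40, 8:56] = 1   # horizontal bar
        raster[8:56, 24:40] = 1   # vertical bar
        slide = make_slide(raster)
        sol = architecture_features(slide)["arch.CT.solidity.largest"]
        # hull of the plus sign: the bounding square minus 4 corner
        # triangles; computed from the exact corner geometry
        area = float((raster == 1).sum())
        w, length = 16.0, 48.0
        hull_area = length * length - 4 * 0.5 * ((length - w) / 2) ** 2
        assert sol == pytest.approx(area / hull_area, rel=0.05)

    def test_smooth_interface_fractal_dimension_near_one(self):
        raster = np.full((256, 256), 1, np.uint8)
        raster[:, 128:] = 2
        slide = make_slide(raster)
        fd = architecture_features(slide)["arch.CSI.fractal_dimension.interface"]
        assert fd == pytest.approx(1.0, abs=0.05)

    def test_isoperimetric_bound_on_random_blobs(self):
        from scipy.ndimage import binary_fill_holes, gaussian_filter
        for seed in range(5):
            rng = np.random.default_rng(seed)
            blob = gaussian_filter(rng.normal(size=(128, 128)), 7) > 0.0
            slide = make_slide(binary_fill_holes(blob).astype(np.uint8))
            m = morphology_features(slide)
            assert m["morph.CT.shape_roughness.largest"] >= 4 * np.pi * 0.95


class TestAreaFeatures:
    def test_area_unit_conversion(self):
        raster = np.zeros((40, 40), np.uint8)
        raster[:25, :40] = 1  # 1000 CT pixels at 4 μm/px
        slide = make_slide(raster)
        f = area_multiplicity_features(slide)
        assert f["area.CT.mm2"] == pytest.approx(1000 * 16 / 1e6)

    def test_all_normal_slide(self):
        f = area_multiplicity_features(make_slide(np.zeros((16, 16), np.uint8)))
        for k, v in f.items():
            if k.startswith("area.") or k.startswith("multiplicity."):
                assert v == 0.0
            else:
                assert np.isnan(v)

    def test_disjoint_blobs_no_interface(self):
        raster = np.zeros((40, 40), np.uint8)
        raster[5:15, 5:15] = 1
        raster[25:35, 25:35] = 2
        f = area_multiplicity_features(make_slide(raster))
        assert f["area.CSI.mm2"] == 0.0
        assert f["relarea.CAS_over_CT+CAS"] == pytest.approx(100 / 200)

    def test_component_region_caching_consistent(self, small_scene):
        ctx = SlideRegions(small_scene)
        f1 = area_multiplicity_features(small_scene, ctx)
        f2 = area_multiplicity_features(small_scene)
        assert f1 == f2
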