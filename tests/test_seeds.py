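import numpy as np
import pytest

from nucseg.config import SeedParams
from nucseg.image_io import GrayImage
from nucseg.seeds import (
    DegenerateImageError,
    DistanceMap,
    build_seeds,
    distance_transform,
    fill_holes,
    morph_close,
    morph_open,
    normalize_distance,
    otsu_threshold,
    refine_mask,
    regional_maxima,
    remove_small_objects,
    seeds_from_maxima,
)
from nucseg._chamfer import CHAMFER_ERROR_BOUND

import oracles


class TestOtsu:
    def test_bimodal_split(self):
        arr = np.full((10, 10), 10.0)
        arr.ravel()[:10] = 200.0
        mask = otsu_threshold(GrayImage(arr, bit_depth=8))
        np.testing.assert_array_equal(mask.pixels, arr == 200.0)

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(GrayImage(np.full((5, 5), 3.0), bit_depth=8))

    def test_two_value_image_any_arrangement(self, rng):
        arr = np.where(rng.random((9, 9)) < 0.4, 255.0, 0.0)
        if arr.max() == arr.min():
            arr[0, 0] = 255.0
        mask = otsu_threshold(GrayImage(arr, bit_depth=8))
        np.testing.assert_array_equal(mask.pixels, arr == 255.0)

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(30):
            arr = rng.integers(0, 200, (12, 12)).astype(float)
            t_ref = oracles.otsu_brute(arr)
            got = otsu_threshold(GrayImage(arr, bit_depth=8)).pixels
            np.testing.assert_array_equal(got, arr > t_ref)


class TestMaskRefinement:
    def test_ring_fills_to_disk(self):
        ring = np.zeros((9, 9), bool)
        ring[2, 2:7] = ring[6, 2:7] = ring[2:7, 2] = ring[2:7, 6] = True
        filled = fill_holes(ring).pixels
        assert filled[4, 4]
        assert filled[2:7, 2:7].all()

    def test_c_shape_unchanged(self):
        c = np.zeros((9, 9), bool)
        c[2:7, 2] = c[2, 2:7] = c[6, 2:7] = True  # open toward the right
        np.testing.assert_array_equal(fill_holes(c).pixels,
                                      oracles.fill_holes_brute(c))
        np.testing.assert_array_equal(fill_holes(c).pixels, c)

    def test_open_removes_isolated_pixel_and_severs_bridge(self):
        from scipy import ndimage
        m = np.zeros((9, 18), bool)
        m[4, 1] = True  # isolated pixel
        m[2:7, 4:9] = True
        m[4, 9:13] = True  # 1-px bridge, 4 px long
        m[2:7, 13:16] = True
        opened = morph_open(m, 1).pixels
        assert not opened[4, 1]
        assert not opened[4, 10] and not opened[4, 11]  # mid-bridge severed
        assert ndimage.label(opened)[1] == 2
        np.testing.assert_array_equal(opened, oracles.binary_open_brute(m, 1))

    def test_close_merges_nearby_blobs(self):
        m = np.zeros((9, 13), bool)
        m[3:6, 2:5] = True
        m[3:6, 7:10] = True  # 2 px gap
        closed = morph_close(m, 2).pixels
        assert closed[4, 5] and closed[4, 6]
        np.testing.assert_array_equal(closed, oracles.binary_close_brute(m, 2))

    @pytest.mark.parametrize("area,survives", [(39, False), (40, True)])
    def test_area_filter_is_strict_at_40(self, area, survives):
        m = np.zeros((12, 12), bool)
        m.ravel()[:area] = True  # one 8-connected raster-run component
        out = remove_small_objects(m, 40)
        assert out.pixels.any() == survives
        if survives:
            np.testing.assert_array_equal(out.pixels, m)

    def test_empty_mask_stays_empty(self):
        assert not remove_small_objects(np.zeros((5, 5), bool), 40).pixels.any()

    def test_monotonicity_properties(self, rng):
        m = rng.random((20, 20)) < 0.45
        assert not (remove_small_objects(m, 10).pixels & ~m).any()
        assert (fill_holes(m).pixels | ~m).all() or (fill_holes(m).pixels >= m).all()
        assert (morph_close(m, 2).pixels >= m).all()
        assert (morph_open(m, 1).pixels <= m).all()

    def test_refine_is_exact_stage_composition(self, rng):
        m = rng.random((25, 25)) < 0.5
        params = SeedParams(open_radius=1, min_area=5, close_radius=2)
        manual = morph_close(
            remove_small_objects(morph_open(fill_holes(m), 1), 5), 2
        ).pixels
        np.testing.assert_array_equal(refine_mask(m, params).pixels, manual)


class TestDistanceTransform:
    def test_all_background_is_zero(self):
        d = distance_transform(np.zeros((6, 6), bool))
        np.testing.assert_array_equal(d.values, 0.0)

    def test_single_pixel_gets_one_orthogonal_step(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        d = distance_transform(m, 5)
        assert d.values[2, 2] == pytest.approx(0.9866, abs=1e-6)

    def test_all_foreground_degenerate_unless_virtual_border(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(DegenerateImageError):
            distance_transform(m)
        d = distance_transform(m, 5, border_is_background=True)
        assert d.values[0, 0] == pytest.approx(0.9866, abs=1e-6)
        assert d.values.max() == pytest.approx(d.values[1:3, 1:3].max())

    @pytest.mark.parametrize("mask_size", [3, 5])
    def test_within_documented_bound_of_exact_euclidean(self, rng, mask_size):
        bound = CHAMFER_ERROR_BOUND[mask_size]
        for _ in range(100):
            m = rng.random((15, 15)) < rng.uniform(0.2, 0.9)
            if m.all() or not m.any():
                continue
            cham = distance_transform(m, mask_size).values
            exact = oracles.exact_edt_brute(m)
            fg = m & (exact > 0)
            assert np.all(np.abs(cham[fg] - exact[fg]) <= bound * exact[fg] + 1e-8)

    def test_square_in_canvas_close_to_exact(self):
        m = np.zeros((11, 11), bool)
        m[2:9, 2:9] = True
        cham = distance_transform(m, 5).values
        exact = oracles.exact_edt_brute(m)
        assert np.all(np.abs(cham[m] - exact[m]) <= CHAMFER_ERROR_BOUND[5] * exact[m] + 1e-8)


class TestNormalize:
    def test_linear_stretch_midpoint(self):
        d = DistanceMap(np.array([[0.0, 5.0], [10.0, 0.0]]))
        out = normalize_distance(d)
        assert out.normalized
        assert out.values[0, 1] == pytest.approx(127.5)
        assert out.values[1, 0] == pytest.approx(255.0)

    def test_already_spanning_map_unchanged(self):
        vals = np.array([[0.0, 100.0], [255.0, 30.0]])
        np.testing.assert_allclose(normalize_distance(DistanceMap(vals)).values, vals)

    def test_constant_foreground_convention(self):
        vals = np.full((3, 3), 4.0)
        out = normalize_distance(DistanceMap(vals))
        np.testing.assert_array_equal(out.values, 255.0)

    def test_double_normalization_rejected(self):
        d = normalize_distance(DistanceMap(np.array([[0.0, 1.0]])))
        with pytest.raises(ValueError):
            normalize_distance(d)


class TestRegionalMaxima:
    def norm(self, vals):
        return DistanceMap(np.asarray(vals, dtype=float), normalized=True)

    def test_single_strict_peak(self):
        v = np.zeros((7, 7))
        v[3, 3] = 10
        out = regional_maxima(self.norm(v), 5).pixels
        expected = np.zeros((7, 7), bool)
        expected[3, 3] = True
        np.testing.assert_array_equal(out, expected)

    def test_two_distant_equal_peaks_both_marked(self):
        v = np.zeros((7, 15))
        v[3, 3] = v[3, 11] = 9
        out = regional_maxima(self.norm(v), 5).pixels
        assert out[3, 3] and out[3, 11] and out.sum() == 2

    def test_monotone_ramp_marks_only_top(self):
        v = np.tile(np.arange(1.0, 11.0), (5, 1))
        out = regional_maxima(self.norm(v), 5).pixels
        np.testing.assert_array_equal(out, v == 10.0)

    def test_matches_plateau_oracle_on_random_maps(self, rng):
        for _ in range(50):
            v = rng.integers(0, 6, (12, 12)).astype(float)
            got = regional_maxima(self.norm(v), 5).pixels
            np.testing.assert_array_equal(got, oracles.regional_maxima_brute(v, 5))

    def test_background_never_marked(self):
        v = np.zeros((6, 6))
        out = regional_maxima(self.norm(v), 5).pixels
        assert not out.any()


class TestSeeds:
    def test_isolated_maximum_becomes_disk_seed(self):
        maxima = np.zeros((11, 11), bool)
        maxima[5, 5] = True
        seeds = seeds_from_maxima(maxima, 3)
        assert seeds.K == 1
        assert seeds.markers.sum() == oracles.disk(3).sum()  # one disk, label 1

    def test_close_maxima_merge_into_one_seed(self):
        maxima = np.zeros((11, 15), bool)
        maxima[5, 5] = maxima[5, 8] = True  # 3 px apart, dilation radius 3
        assert seeds_from_maxima(maxima, 3).K == 1

    def test_empty_maxima_give_empty_seed_set(self):
        seeds = seeds_from_maxima(np.zeros((5, 5), bool), 3)
        assert seeds.K == 0
        assert not seeds.markers.any()

    def test_seed_count_bounded_by_maxima_components(self, rng):
        from scipy import ndimage
        maxima = rng.random((30, 30)) < 0.1
        n_comp = ndimage.label(maxima, structure=np.ones((3, 3)))[1]
        d = DistanceMap(np.where(maxima, 255.0, 0.0), normalized=True)
        assert build_seeds(None, d, SeedParams()).K <= n_comp
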