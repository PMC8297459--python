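import numpy as np
import pytest

from nucseg import (
    LabelMap,
    PipelineConfig,
    SceneSpec,
    count_cells,
    dice,
    generate_scene,
    laplacian_edges,
    marker_watershed,
    segment_image,
    segment_stages,
)
from nucseg.config import BilateralParams, WatershedParams
from nucseg.image_io import GrayImage
from nucseg.seeds import SeedSet
from nucseg.synthetic import disk_pair_sample
from nucseg.watershed import draw_boundary_lines

import oracles


class TestLaplacian:
    def test_constant_image_is_zero(self):
        assert np.all(laplacian_edges(np.full((6, 6), 9.0)) == 0)

    def test_linear_ramp_zero_in_interior(self):
        ramp = np.outer(np.arange(8.0), np.ones(8)) + 2 * np.arange(8.0)
        lap = laplacian_edges(ramp)
        np.testing.assert_allclose(lap[1:-1, 1:-1], 0.0, atol=1e-12)

    def test_unit_impulse_response(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        lap = laplacian_edges(img)
        assert lap[2, 2] == -4
        assert lap[1, 2] == lap[3, 2] == lap[2, 1] == lap[2, 3] == 1
        assert lap.sum() == pytest.approx(0.0)


def seedset(markers):
    markers = np.asarray(markers, dtype=np.int64)
    return SeedSet(markers, int(markers.max()))


class TestMarkerWatershed:
    def test_single_marker_floods_everything(self):
        markers = np.zeros((6, 7), dtype=int)
        markers[2, 3] = 1
        out = marker_watershed(np.zeros((6, 7)), seedset(markers))
        assert np.all(out.labels == 1)

    def test_fifo_split_on_uniform_strip(self):
        markers = np.zeros((1, 9), dtype=int)
        markers[0, 1] = 1
        markers[0, 7] = 2
        out = marker_watershed(np.zeros((1, 9)), seedset(markers)).labels[0]
        ref = oracles.marker_watershed_brute(np.zeros((1, 9)), markers)[0]
        np.testing.assert_array_equal(out, ref)
        assert list(out[:4]) == [1, 1, 1, 1]
        assert list(out[5:]) == [2, 2, 2, 2]

    def test_ridge_separates_basins(self):
        edges = np.zeros((5, 11))
        edges[:, 5] = 10.0
        markers = np.zeros((5, 11), dtype=int)
        markers[2, 1] = 1
        markers[2, 9] = 2
        out = marker_watershed(edges, seedset(markers)).labels
        assert np.all(out[:, :5] == 1)
        assert np.all(out[:, 6:] == 2)

    def test_unimodal_ridge_split_matches_flood_oracle(self, rng):
        for _ in range(20):
            peak = rng.integers(2, 8)
            profile = np.concatenate([np.arange(peak + 1.0),
                                      np.arange(peak - 1.0, -1.0, -1.0)])
            edges = profile[None, :]
            markers = np.zeros_like(edges, dtype=int)
            markers[0, 0] = 1
            markers[0, -1] = 2
            out = marker_watershed(edges, seedset(markers)).labels
            ref = oracles.marker_watershed_brute(edges, markers)
            np.testing.assert_array_equal(out, ref)
            # split falls at the ridge maximum
            boundary = np.nonzero(np.diff(out[0]))[0]
            assert boundary.size == 1
            assert abs(int(boundary[0]) + 0.5 - peak) <= 1.0

    def test_matches_brute_flood_on_random_instances(self, rng):
        for _ in range(30):
            h, w = rng.integers(4, 12, 2)
            edges = rng.integers(0, 5, (h, w)).astype(float)
            markers = np.zeros((h, w), dtype=int)
            n_mark = rng.integers(1, 4)
            pos = rng.choice(h * w, size=n_mark, replace=False)
            markers.ravel()[pos] = np.arange(1, n_mark + 1)
            mask = rng.random((h, w)) < 0.8
            got = marker_watershed(edges, seedset(markers), mask=mask).labels
            ref = oracles.marker_watershed_brute(edges, markers, mask=mask)
            np.testing.assert_array_equal(got, ref)

    def test_markers_never_relabeled(self, rng):
        edges = rng.random((10, 10))
        markers = np.zeros((10, 10), dtype=int)
        markers[1, 1] = 1
        markers[8, 8] = 2
        out = marker_watershed(edges, seedset(markers)).labels
        assert out[1, 1] == 1 and out[8, 8] == 2

    def test_label_permutation_equivariance(self, rng):
        edges = rng.integers(0, 4, (9, 9)).astype(float)
        markers = np.zeros((9, 9), dtype=int)
        markers[1, 1], markers[4, 7], markers[7, 2] = 1, 2, 3
        base = marker_watershed(edges, seedset(markers)).labels
        perm = np.array([0, 3, 1, 2])  # relabel 1->3, 2->1, 3->2
        permuted = marker_watershed(edges, seedset(perm[markers])).labels
        np.testing.assert_array_equal(perm[base], permuted)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            marker_watershed(np.zeros((3, 3)), seedset(np.zeros((4, 4), dtype=int)))

    def test_no_markers_gives_background(self):
        out = marker_watershed(np.zeros((4, 4)), seedset(np.zeros((4, 4), dtype=int)))
        assert count_cells(out) == 0


class TestSegmentImage:
    def test_blank_image_yields_empty_map(self):
        img = GrayImage(np.full((64, 64), 50, dtype=np.uint8), bit_depth=8)
        assert count_cells(segment_image(img)) == 0

    def test_well_separated_disks_one_label_each(self, small_scene):
        lab = segment_image(small_scene.image)
        assert count_cells(lab) == small_scene.n_nuclei
        assert dice(lab, small_scene.truth) > 90.0

    def test_overlapping_pair_splits_into_two(self):
        sample = disk_pair_sample()  # centers 1.2 x radius apart
        lab = segment_image(sample.image)
        assert count_cells(lab) == 2

    def test_concentric_disks_yield_one(self):
        sample = disk_pair_sample(center_distance=0.0)
        assert count_cells(segment_image(sample.image)) == 1

    def test_labels_confined_to_foreground(self, small_scene):
        stages = segment_stages(small_scene.image)
        labels = stages["labels"]
        assert not labels[~stages["foreground"]].any()

    def test_boundary_lines_flag_adds_zero_dams(self):
        sample = disk_pair_sample()
        cfg = PipelineConfig(watershed=WatershedParams(boundary_lines=True))
        lab = segment_image(sample.image, cfg)
        plain = segment_image(sample.image)
        assert count_cells(lab) == 2
        assert (lab.labels > 0).sum() < (plain.labels > 0).sum()

    def test_count_cells_on_synthetic_maps(self):
        assert count_cells(LabelMap(np.zeros((3, 3), dtype=int))) == 0
        assert count_cells(LabelMap(np.array([[1, 2], [3, 0]]))) == 3


class TestBoundaryLines:
    def test_dam_separates_adjacent_labels(self):
        lab = LabelMap(np.array([[1, 1, 2, 2]] * 3))
        dammed = draw_boundary_lines(lab).labels
        assert (dammed[:, 1] == 1).all()
        assert (dammed[:, 2] == 0).all()  # larger label side cleared
        assert (dammed[:, 3] == 2).all()
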