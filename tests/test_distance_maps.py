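"""Distance-transform machinery against hand enumeration and brute-force
all-pairs oracles."""

import numpy as np
import pytest

from dtseg.distance_maps import (
    UndefinedDistanceError,
    classify_points,
    euclidean_distance_transform,
    extract_edge,
    make_map,
    method_a,
    method_b,
    method_c,
    to_grayscale,
)
from dtseg.volumes import BinaryMask, DistanceWeightMap

from conftest import brute_force_distance_to_set, brute_force_edge, brute_force_edt


def _mask2d(arr2d):
    return BinaryMask(np.asarray(arr2d)[None, :, :], (1, 1, 1))


class TestClassifyPoints:
    def test_solid_block_splits_into_interior_and_ring(self):
        mask = _mask2d(np.ones((5, 5), dtype=np.uint8))
        cls = classify_points(mask, "face_2d")
        expected_internal = np.zeros((5, 5), dtype=np.uint8)
        expected_internal[1:4, 1:4] = 1
        assert np.array_equal(cls.internal[0], expected_internal)
        assert np.array_equal(cls.boundary[0], 1 - expected_internal)
        assert cls.isolated.sum() == 0

    def test_single_voxel_is_isolated(self):
        data = np.zeros((3, 7, 7), dtype=np.uint8)
        data[1, 3, 3] = 1
        cls = classify_points(BinaryMask(data, (1, 1, 1)), "face_3d")
        assert cls.isolated[1, 3, 3] == 1
        assert cls.isolated.sum() == 1
        assert cls.internal.sum() == 0
        assert cls.boundary.sum() == 0

    def test_empty_mask_yields_empty_classes(self):
        cls = classify_points(BinaryMask(np.zeros((3, 4, 5)), (1, 1, 1)))
        assert cls.internal.sum() == cls.isolated.sum() == cls.boundary.sum() == 0

    @pytest.mark.parametrize("connectivity", ["face_2d", "face_3d"])
    def test_partition_of_target_set(self, random_mask, connectivity):
        mask = random_mask(seed=3)
        cls = classify_points(mask, connectivity)
        union = cls.internal | cls.isolated | cls.boundary
        assert np.array_equal(union, mask.data)
        overlap = cls.internal + cls.isolated + cls.boundary
        assert overlap.max() <= 1  # pairwise disjoint


class TestEuclideanDistanceTransform:
    def test_three_four_five_triangle(self):
        data = np.ones((1, 8, 8), dtype=np.uint8)
        data[0, 0, 0] = 0  # single background voxel
        d = euclidean_distance_transform(BinaryMask(data, (1, 1, 1)), "2d_slicewise")
        assert d.data[0, 3, 4] == pytest.approx(5.0)
        assert d.data[0, 0, 0] == 0.0

    @pytest.mark.parametrize("mode", ["2d_slicewise", "3d"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, random_mask, mode, seed):
        mask = random_mask(shape=(3, 9, 9), seed=seed)
        got = euclidean_distance_transform(mask, mode).data
        want = brute_force_edt(mask.data, mode)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_error_when_no_background(self):
        full = BinaryMask(np.ones((2, 4, 4), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(UndefinedDistanceError):
            euclidean_distance_transform(full, "3d")

    def test_slicewise_error_names_slice(self):
        data = np.zeros((3, 4, 4), dtype=np.uint8)
        data[1] = 1
        with pytest.raises(UndefinedDistanceError, match="slice 1"):
            euclidean_distance_transform(BinaryMask(data, (1, 1, 1)), "2d_slicewise")


class TestToGrayscale:
    def test_min_max_and_midpoint(self):
        grays = to_grayscale([1.0, 2.0, 3.0])
        np.testing.assert_allclose(grays, [0.0, 127.5, 255.0])

    def test_constant_set_maps_to_zero(self):
        np.testing.assert_array_equal(to_grayscale([2.0, 2.0]), [0.0, 0.0])

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            to_grayscale([])


class TestExtractEdge:
    def test_solid_block_perimeter(self):
        data = np.zeros((1, 9, 9), dtype=np.uint8)
        data[0, 2:7, 2:7] = 1
        edge = extract_edge(BinaryMask(data, (1, 1, 1)), "face_2d")
        assert edge.data.sum() == 16  # 5x5 block ring
        inner = np.zeros_like(data)
        inner[0, 3:6, 3:6] = 1
        assert np.array_equal(edge.data, data - inner)

    def test_single_voxel_is_all_edge(self):
        data = np.zeros((3, 5, 5), dtype=np.uint8)
        data[1, 2, 2] = 1
        edge = extract_edge(BinaryMask(data, (1, 1, 1)))
        assert np.array_equal(edge.data, data)

    def test_all_zero_mask(self):
        edge = extract_edge(BinaryMask(np.zeros((2, 4, 4)), (1, 1, 1)))
        assert edge.data.sum() == 0

    @pytest.mark.parametrize("connectivity", ["face_2d", "face_3d"])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, random_mask, connectivity, seed):
        mask = random_mask(seed=seed + 10)
        got = extract_edge(mask, connectivity).data
        np.testing.assert_array_equal(got, brute_force_edge(mask.data, connectivity))


def _block_label():
    data = np.zeros((1, 15, 15), dtype=np.uint8)
    data[0, 4:11, 4:11] = 1
    return BinaryMask(data, (1, 1, 1))


class TestMethodA:
    def test_edge_voxels_weighted_one_and_farthest_zero(self):
        label = _block_label()
        out = method_a(label, "2d_slicewise").data
        edge = brute_force_edge(label.data, "face_2d").astype(bool)
        np.testing.assert_allclose(out[edge], 1.0)
        dist = brute_force_distance_to_set(edge, "2d_slicewise")
        assert out[np.unravel_index(dist.argmax(), dist.shape)] == pytest.approx(0.0)

    def test_full_map_equals_brute_force_pipeline(self):
        label = _block_label()
        out = method_a(label, "2d_slicewise").data
        edge = brute_force_edge(label.data, "face_2d")
        dist = brute_force_distance_to_set(edge, "2d_slicewise")
        want = 1.0 - (dist - dist.min()) / (dist.max() - dist.min())
        np.testing.assert_allclose(out, want, atol=1e-10)

    def test_non_increasing_in_edge_distance(self, random_mask):
        mask = random_mask(shape=(3, 10, 10), p=0.3, seed=5)
        out = method_a(mask, "3d").data
        edge = brute_force_edge(mask.data, "face_3d")
        dist = brute_force_distance_to_set(edge, "3d")
        order = np.argsort(dist.ravel())
        values = out.ravel()[order]
        assert (np.diff(values) <= 1e-10).all()

    def test_requires_foreground_and_background(self):
        with pytest.raises(ValueError):
            method_a(BinaryMask(np.zeros((2, 8, 8)), (1, 1, 1)))
        with pytest.raises(ValueError):
            method_a(BinaryMask(np.ones((2, 8, 8)), (1, 1, 1)))


class TestMethodB:
    def test_values_in_unit_interval(self, random_mask):
        out = method_b(random_mask(seed=2), "3d").data
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_deepest_foreground_voxel_weighs_zero(self):
        label = _block_label()
        out = method_b(label, "2d_slicewise").data
        d1 = brute_force_edt(label.data, "2d_slicewise")
        deepest = np.unravel_index(d1.argmax(), d1.shape)
        assert out[deepest] == pytest.approx(0.0)

    def test_full_map_equals_brute_force_pipeline(self):
        label = _block_label()
        out = method_b(label, "2d_slicewise").data

        def minmax(x):
            return np.zeros_like(x) if x.max() == x.min() else (x - x.min()) / (x.max() - x.min())

        d1 = brute_force_edt(label.data, "2d_slicewise")
        fg_part = minmax(np.abs(d1.max() - d1) * label.data)
        rev = 1 - label.data
        d2 = brute_force_edt(rev, "2d_slicewise")
        bg_part = minmax(np.abs(d2.max() - d2) * rev)
        np.testing.assert_allclose(out, fg_part + bg_part, atol=1e-10)

    def test_asymmetric_across_edge_when_maxima_differ(self):
        # block off-centre: inside max distance != outside max distance
        label = _block_label()
        out = method_b(label, "2d_slicewise").data
        inside = out[0, 5, 5]  # two voxels deep inside the region
        outside = out[0, 2, 5]  # two voxels outside it, same column
        assert inside != pytest.approx(outside)


class TestMethodC:
    def test_equals_extract_edge(self, random_mask):
        mask = random_mask(seed=8)
        out = method_c(mask, "3d")
        np.testing.assert_array_equal(
            out.data, extract_edge(mask, "face_3d").data.astype(float)
        )
        assert out.method_tag == "C"

    def test_sum_equals_edge_count(self):
        label = _block_label()
        out = method_c(label, "2d_slicewise")
        assert out.data.sum() == brute_force_edge(label.data, "face_2d").sum()

    def test_all_zero_label_passes_through(self):
        out = method_c(BinaryMask(np.zeros((2, 6, 6)), (1, 1, 1)))
        assert out.data.sum() == 0


class TestPurity:
    @pytest.mark.parametrize("method", ["A", "B", "C"])
    def test_same_input_bit_identical_output(self, random_mask, method):
        mask = random_mask(seed=4)
        a = make_map(mask, method, "3d").data
        b = make_map(mask, method, "3d").data
        assert np.array_equal(a, b)

    def test_make_map_rejects_unknown_method(self, random_mask):
        with pytest.raises(ValueError):
            make_map(random_mask(), "Z")
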