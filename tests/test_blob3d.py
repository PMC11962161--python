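"""3D blob segmentation, object metrics, channel alignment, colocalization."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, shift as ndi_shift

from condtrack import (BlobParams, FilterParams, Phantom3DConfig,
                       PhantomObject, align_channels, blob_segment,
                       colocalize, filter_objects, object_metrics,
                       simulate_confocal_stack)

VOX = (0.26, 0.06, 0.06)  # (z, y, x) µm, Airyscan-like


def sphere_phantom(centers, radius=0.175, peak=1000.0, shape=(28, 96, 96)):
    cfg = Phantom3DConfig(shape=shape, voxel_size=VOX,
                          channels=([PhantomObject(c, radius, peak)
                                     for c in centers], []))
    stack, truth = simulate_confocal_stack(cfg)
    return stack[0], truth


class TestBlobSegment:
    def test_constant_stack_has_no_objects(self):
        labels = blob_segment(np.full((10, 32, 32), 7.0), VOX)
        assert labels.max() == 0

    def test_single_sphere_segmented_with_centroid_on_truth(self):
        stack, truth = sphere_phantom([(3.6, 2.9, 2.9)])
        labels = blob_segment(stack, VOX)
        assert labels.max() == 1
        obj = object_metrics(labels, stack, VOX)[0]
        assert np.all(np.abs(np.array(obj.centroid)
                             - truth["objects"][0][0].center) <= np.array(VOX))

    def test_split_sensitivity_controls_merging_of_distant_spheres(self):
        stack, _ = sphere_phantom([(3.6, 1.5, 1.5), (3.6, 3.5, 3.5)])
        two = blob_segment(stack, VOX, BlobParams(0.35, 45.0, 50.0))
        one = blob_segment(stack, VOX, BlobParams(0.35, 45.0, 0.0))
        assert two.max() == 2
        assert one.max() == 1

    def test_intensity_scale_invariance(self):
        stack, _ = sphere_phantom([(3.6, 2.0, 2.0), (3.6, 4.0, 4.0)])
        base = blob_segment(stack, VOX)
        for k in (0.25, 7.3):
            assert np.array_equal(base, blob_segment(stack * k, VOX))

    def test_stack_thinner_than_blob_scale_raises_naming_z(self):
        with pytest.raises(ValueError, match="z"):
            blob_segment(np.zeros((1, 64, 64)), VOX, BlobParams(diameter=0.35))


class TestFilterObjects:
    def test_ten_voxel_object_is_below_the_volume_floor(self):
        # 10 voxels x (0.26 * 0.06 * 0.06) = 0.00936 µm³ < 0.03 µm³
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[2:4, 2:4, 2:4] = 1
        labels[4, 2, 2] = 1
        labels[4, 3, 2] = 1
        assert 10 * np.prod(VOX) == pytest.approx(0.00936)
        out = filter_objects(labels, VOX)
        assert out.max() == 0

    def test_digitized_ball_passes_both_filters(self):
        # ball of radius 0.3 µm: volume ~0.113 µm³, high sphericity
        iso = (0.06, 0.06, 0.06)
        idx = np.arange(24)
        z, y, x = np.meshgrid(idx, idx, idx, indexing="ij")
        mask = ((z - 12) ** 2 + (y - 12) ** 2 + (x - 12) ** 2) <= 5.0 ** 2
        labels = mask.astype(np.int32)
        obj = object_metrics(labels, np.ones_like(labels, float), iso)[0]
        assert obj.volume == pytest.approx(4 / 3 * np.pi * 0.3 ** 3, rel=0.05)
        assert obj.sphericity >= 0.9
        assert filter_objects(labels, iso).max() == 1

    def test_thin_rod_fails_the_sphericity_floor(self):
        iso = (0.06, 0.06, 0.06)
        labels = np.zeros((40, 9, 9), dtype=np.int32)
        labels[3:37, 4, 4] = 1  # ~2 µm long, one voxel wide
        obj = object_metrics(labels, np.ones_like(labels, float), iso)[0]
        assert obj.sphericity < 0.6
        assert filter_objects(labels, iso).max() == 0

    def test_monotone_in_both_thresholds(self):
        stack, _ = sphere_phantom([(3.6, 1.5, 1.5), (3.6, 3.5, 3.5),
                                   (3.6, 1.5, 4.0)], radius=0.16)
        labels = blob_segment(stack, VOX)
        counts = []
        for mv in (0.0, 0.01, 0.05, 0.2):
            out = filter_objects(labels, VOX, FilterParams(mv, 0.3))
            counts.append(out.max())
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        counts = []
        for ms in (0.1, 0.4, 0.7, 0.95):
            out = filter_objects(labels, VOX, FilterParams(0.0, ms))
            counts.append(out.max())
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nucleus_mask_removes_outside_objects(self):
        stack, _ = sphere_phantom([(3.6, 1.5, 1.5), (3.6, 3.5, 3.5)])
        labels = blob_segment(stack, VOX)
        nucleus = np.zeros_like(labels, dtype=bool)
        nucleus[:, :40, :40] = True  # only the first sphere's corner
        out = filter_objects(labels, VOX, FilterParams(0.0, 0.1),
                             nucleus_mask=nucleus)
        assert out.max() == 1


class TestObjectMetrics:
    def test_single_voxel_object_intensities(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[2, 2, 2] = 1
        stack = np.zeros((5, 5, 5))
        stack[2, 2, 2] = 7.0
        obj = object_metrics(labels, stack, VOX)[0]
        assert obj.total_intensity == 7.0
        assert obj.mean_intensity == 7.0
        assert obj.voxel_count == 1

    def test_sphere_volume_centroid_intensity_match_closed_form(self):
        iso = (0.06, 0.06, 0.06)
        idx = np.arange(28)
        z, y, x = np.meshgrid(idx, idx, idx, indexing="ij")
        mask = ((z - 14) ** 2 + (y - 14) ** 2 + (x - 14) ** 2) <= 8.0 ** 2
        labels = mask.astype(np.int32)
        obj = object_metrics(labels, np.full(labels.shape, 3.0), iso)[0]
        r_um = 8.0 * 0.06
        assert obj.volume == pytest.approx(4 / 3 * np.pi * r_um ** 3, rel=0.05)
        # marching cubes on a binary mask carries a small staircase bias
        assert obj.surface_area == pytest.approx(4 * np.pi * r_um ** 2,
                                                 rel=0.10)
        assert np.allclose(obj.centroid, (14.5 * 0.06,) * 3, atol=0.06)
        assert obj.mean_intensity == 3.0

    def test_intensity_scaling_affects_only_intensities(self):
        stack, _ = sphere_phantom([(3.6, 2.9, 2.9)])
        labels = blob_segment(stack, VOX)
        a = object_metrics(labels, stack, VOX)[0]
        b = object_metrics(labels, stack * 2.0, VOX)[0]
        assert b.total_intensity == pytest.approx(2 * a.total_intensity)
        assert b.mean_intensity == pytest.approx(2 * a.mean_intensity)
        assert b.volume == a.volume
        assert b.sphericity == a.sphericity

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            object_metrics(np.zeros((4, 4, 4), dtype=int),
                           np.zeros((4, 4, 5)), VOX)


def bead_stack():
    stack = np.zeros((20, 40, 40))
    stack[10, 20, 20] = 100.0
    stack[6, 8, 30] = 80.0
    return gaussian_filter(stack, 2.0)


class TestAlignChannels:
    def test_identical_stacks_have_zero_shift(self):
        s = bead_stack()
        res = align_channels(s, s, VOX)
        assert np.allclose(res.shift_voxels, 0.0)
        assert res.confident

    def test_integer_two_voxel_shift_recovered(self):
        s = bead_stack()
        res = align_channels(s, np.roll(s, 2, axis=2), VOX)
        assert np.allclose(res.shift_voxels, [0, 0, 2], atol=0.05)

    def test_subvoxel_shift_recovered_within_a_tenth(self):
        s = bead_stack()
        moved = ndi_shift(s, (0, 0, 0.3), order=3)
        res = align_channels(s, moved, VOX)
        assert res.shift_voxels[2] == pytest.approx(0.3, abs=0.1)

    def test_uncorrelated_stacks_fall_back_to_zero_shift(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 16, 16))
        b = rng.normal(size=(10, 16, 16))
        with pytest.warns(UserWarning):
            res = align_channels(a, b, VOX)
        assert not res.confident
        assert np.allclose(res.shift_voxels, 0.0)


class TestColocalize:
    def test_identical_volumes_fully_colocalized(self):
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[1:3, 1:3, 1:3] = 1
        labels[4:6, 4:6, 4:6] = 2
        res = colocalize(labels, labels)
        assert res.fraction_a == 1.0
        assert res.fraction_b == 1.0
        assert np.array_equal(res.intersection_labels > 0, labels > 0)

    def test_disjoint_volumes_have_no_colocalization(self):
        a = np.zeros((6, 6, 6), dtype=np.int32)
        b = np.zeros((6, 6, 6), dtype=np.int32)
        a[0:2, 0:2, 0:2] = 1
        b[4:6, 4:6, 4:6] = 1
        res = colocalize(a, b)
        assert res.fraction_a == 0.0
        assert len(res.colocalized_a) == 0

    def test_constructed_thirty_percent_overlap_is_exact(self):
        a = np.zeros((4, 50, 10), dtype=np.int32)
        b = np.zeros((4, 50, 10), dtype=np.int32)
        for i in range(10):  # ten A objects, three touched by B
            a[1:3, 5 * i:5 * i + 2, 2:4] = i + 1
        for i in range(3):
            b[1:3, 5 * i:5 * i + 2, 3:6] = i + 1
        res = colocalize(a, b)
        assert res.n_a == 10
        assert res.fraction_a == pytest.approx(0.3)

    def test_voxelwise_symmetry_of_intersection(self):
        rng = np.random.default_rng(5)
        a = (rng.random((8, 12, 12)) < 0.2).astype(np.int32)
        b = (rng.random((8, 12, 12)) < 0.2).astype(np.int32)
        ab = colocalize(a, b).intersection_labels > 0
        ba = colocalize(b, a).intersection_labels > 0
        assert np.array_equal(ab, ba)

    def test_per_nucleus_counts(self):
        a = np.zeros((4, 10, 20), dtype=np.int32)
        b = np.zeros((4, 10, 20), dtype=np.int32)
        nuclei = np.zeros((4, 10, 20), dtype=np.int32)
        nuclei[:, :, :10] = 1
        nuclei[:, :, 10:] = 2
        a[1:3, 2:4, 2:4] = 1      # nucleus 1, colocalized
        b[1:3, 3:5, 3:5] = 1
        a[1:3, 2:4, 14:16] = 2    # nucleus 2, alone
        res = colocalize(a, b, nucleus_labels=nuclei)
        assert res.per_nucleus[1] == {"n_a": 1, "n_b": 1, "n_coloc_a": 1}
        assert res.per_nucleus[2] == {"n_a": 1, "n_b": 0, "n_coloc_a": 0}
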