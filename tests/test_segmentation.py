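"""Segmentation pipeline stages and overlap-based linking."""

import numpy as np
import pytest
from scipy import ndimage

from nucdyn import (SegmentationParams, VolumeSeries, link_tracks, preprocess,
                    resample_isotropic, rough_mask, seeds_from_mask,
                    watershed_labels)


def ball_mask(shape, center, radius):
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius**2


class TestResample:
    def test_z_slices_scale_by_anisotropy_factor(self):
        v = VolumeSeries(np.random.default_rng(0).random((2, 20, 8, 8)),
                         (1.0, 0.5, 0.5), 15.0)
        out = resample_isotropic(v)
        assert out.data.shape == (2, 40, 8, 8)
        assert out.voxel_size == (0.5, 0.5, 0.5)
        # physical z extent preserved: 20 * 1.0 um == 40 * 0.5 um
        assert out.data.shape[1] * out.voxel_size[0] == pytest.approx(20.0)

    def test_isotropic_returned_unchanged(self):
        data = np.random.default_rng(1).random((1, 8, 8, 8))
        v = VolumeSeries(data, (0.5, 0.5, 0.5), 10.0)
        assert resample_isotropic(v) is v

    def test_constant_volume_preserved_exactly(self):
        v = VolumeSeries(np.full((1, 20, 6, 6), 3.75), (1.0, 0.5, 0.5), 10.0)
        np.testing.assert_allclose(resample_isotropic(v).data, 3.75, atol=1e-12)

    def test_rejects_nonpositive_voxel(self):
        with pytest.raises(ValueError):
            VolumeSeries(np.zeros((1, 4, 4, 4)), (0.0, 0.5, 0.5), 10.0)


class TestPreprocess:
    def test_sigma_zero_is_identity(self):
        v = VolumeSeries(np.random.default_rng(2).random((1, 6, 6, 6)),
                         (0.5, 0.5, 0.5), 10.0)
        assert preprocess(v, 0.0) is v

    def test_constant_volume_unchanged(self):
        v = VolumeSeries(np.full((1, 10, 10, 10), 2.0), (0.5, 0.5, 0.5), 10.0)
        np.testing.assert_allclose(preprocess(v, 1.0).data, 2.0, atol=1e-9)

    def test_interior_point_source_conserves_total_intensity(self):
        data = np.zeros((1, 31, 31, 31))
        data[0, 15, 15, 15] = 100.0
        v = VolumeSeries(data, (0.5, 0.5, 0.5), 10.0)
        out = preprocess(v, 0.8)
        assert out.data.sum() == pytest.approx(100.0, rel=1e-6)


class TestRoughMask:
    def test_uniform_volume_gives_empty_mask(self):
        v = VolumeSeries(np.full((1, 10, 16, 16), 5.0), (0.5, 0.5, 0.5), 10.0)
        assert not rough_mask(v, window=4.0, offset=0.1).any()

    def test_bright_sphere_recovered(self):
        rng = np.random.default_rng(3)
        truth = ball_mask((24, 48, 48), (12, 24, 24), 8)
        data = 100.0 * truth + rng.normal(0, 10.0, truth.shape)  # SNR 10
        v = preprocess(VolumeSeries(np.clip(data, 0, None)[None], (0.5, 0.5, 0.5), 10.0), 0.5)
        mask = rough_mask(v, window=9.0, offset=0.25)[0]
        recall = (mask & truth).sum() / truth.sum()
        dilated = ndimage.binary_dilation(truth, iterations=2)
        assert recall >= 0.90
        assert (mask & ~dilated).sum() == 0  # mask within sphere dilated by 2

    def test_two_separated_spheres_two_components(self):
        truth = ball_mask((24, 64, 64), (12, 16, 16), 6) | ball_mask((24, 64, 64), (12, 48, 48), 6)
        v = preprocess(VolumeSeries(100.0 * truth[None], (0.5, 0.5, 0.5), 10.0), 0.5)
        mask = rough_mask(v, window=8.0, offset=0.2)[0]
        _, n = ndimage.label(mask)
        assert n == 2


class TestSeeds:
    def test_sphere_erodes_to_smaller_sphere(self):
        mask = ball_mask((32, 32, 32), (16, 16, 16), 8)
        seeds, info = seeds_from_mask(mask, erosion_radius_vox=3, peak_separation_vox=8)
        assert seeds.max() == 1
        size = (seeds == 1).sum()
        expected = ball_mask((32, 32, 32), (16, 16, 16), 5).sum()
        assert size == pytest.approx(expected, rel=0.15)
        assert not info["split_components"]

    def test_fused_spheres_split_into_two_seeds(self):
        shape = (32, 32, 64)
        mask = ball_mask(shape, (16, 16, 20), 8) | ball_mask(shape, (16, 16, 42), 8)
        # thin neck bridging the two
        mask |= ball_mask(shape, (16, 16, 31), 3)
        assert ndimage.label(mask)[1] == 1  # genuinely fused
        seeds, info = seeds_from_mask(mask, erosion_radius_vox=3, peak_separation_vox=8)
        n_seeds = len(np.unique(seeds)) - 1
        assert n_seeds == 2

    def test_thin_component_reseeded_not_lost(self):
        mask = np.zeros((16, 16, 32), bool)
        mask[7:9, 7:10, 4:28] = True  # thinner than the erosion ball
        seeds, info = seeds_from_mask(mask, erosion_radius_vox=3,
                                      min_seed_voxels=20, peak_separation_vox=30)
        assert len(np.unique(seeds)) - 1 == 1
        assert info["reseeded_components"]

    def test_empty_mask_empty_seeds(self):
        seeds, _ = seeds_from_mask(np.zeros((8, 8, 8), bool), 2)
        assert not seeds.any()


class TestWatershed:
    def test_single_seed_fills_blob(self):
        blob = ball_mask((24, 24, 24), (12, 12, 12), 7)
        vol = ndimage.gaussian_filter(100.0 * blob, 1.0)
        seeds = np.zeros(blob.shape, np.int32)
        seeds[12, 12, 12] = 1
        labels = watershed_labels(vol, seeds, blob)
        assert set(np.unique(labels)) == {0, 1}
        np.testing.assert_array_equal(labels > 0, blob)

    def test_dumbbell_splits_at_neck(self):
        # two overlapping spheres: the waist (narrowest cross-section and
        # hence steepest-gradient ridge of the blurred solid) is at x=24
        shape = (32, 32, 48)
        a = ball_mask(shape, (16, 16, 16), 11)
        b = ball_mask(shape, (16, 16, 32), 11)
        mask = a | b
        vol = ndimage.gaussian_filter(100.0 * mask, 1.5)
        seeds = np.zeros(shape, np.int32)
        seeds[16, 16, 16] = 1
        seeds[16, 16, 32] = 2
        labels = watershed_labels(vol, seeds, mask)
        assert (labels == 1).any() and (labels == 2).any()
        np.testing.assert_array_equal(labels > 0, mask)  # partition property
        # split plane near the neck center x=24 (within 1 voxel)
        boundary_x = [x for x in range(shape[2] - 1)
                      if ((labels[:, :, x] == 1) & (labels[:, :, x + 1] == 2)).any()]
        assert boundary_x and min(abs(x + 0.5 - 24) for x in boundary_x) <= 1.5

    def test_no_seeds_gives_empty_labeling(self):
        vol = np.random.default_rng(0).random((8, 8, 8))
        labels = watershed_labels(vol, np.zeros((8, 8, 8), np.int32),
                                  np.ones((8, 8, 8), bool))
        assert not labels.any()


class TestLinkTracks:
    def test_identical_frames_identity_mapping(self):
        frame = np.zeros((16, 16, 16), np.int32)
        frame[ball_mask(frame.shape, (8, 5, 5), 3)] = 1
        frame[ball_mask(frame.shape, (8, 11, 11), 3)] = 2
        mapping, nxt = link_tracks(frame, frame, {1: 1, 2: 2})
        assert mapping == {1: 1, 2: 2}
        assert nxt == 3

    def test_small_translation_keeps_identity(self):
        shape = (24, 24, 24)
        a = np.zeros(shape, np.int32)
        a[ball_mask(shape, (12, 12, 12), 6)] = 1
        b = np.zeros(shape, np.int32)
        b[ball_mask(shape, (12, 12, 13), 6)] = 7  # shifted < 1/3 radius
        mapping, _ = link_tracks(a, b, {1: 1})
        assert mapping[7] == 1

    def test_disappearance_and_birth(self):
        shape = (16, 24, 24)
        a = np.zeros(shape, np.int32)
        a[ball_mask(shape, (8, 6, 6), 3)] = 1
        b = np.zeros(shape, np.int32)
        b[ball_mask(shape, (8, 18, 18), 3)] = 5  # no overlap with label 1
        mapping, nxt = link_tracks(a, b, {1: 1})
        assert mapping[5] == 2  # fresh track id, track 1 terminated
        assert nxt == 3

    def test_rejects_mismatched_shapes(self):
        with pytest.raises(ValueError):
            link_tracks(np.zeros((4, 4, 4), int), np.zeros((4, 4, 5), int), {})

    def test_track_never_assigned_twice_per_frame(self):
        shape = (16, 24, 48)
        a = np.zeros(shape, np.int32)
        a[ball_mask(shape, (8, 12, 16), 6)] = 1
        b = np.zeros(shape, np.int32)
        b[ball_mask(shape, (8, 12, 13), 5)] = 3
        b[ball_mask(shape, (8, 12, 22), 5)] = 4  # both overlap label 1
        mapping, _ = link_tracks(a, b, {1: 1}, min_overlap_fraction=0.1)
        assert sorted(mapping.values()) == [1, 2]  # injective inheritance
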