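"""Cropping, padding, normalization, resizing, slice fusion, augmentation."""

import numpy as np
import pytest

from spinegraph.preprocess import (PreprocessConfig, augment_sample,
                                   central_bbox, crop_and_pad,
                                   locate_spine_bbox, normalize_intensity,
                                   prepare_refine_slices, resize_labelmap,
                                   resize_probmap, resize_volume)


class TestBbox:
    def test_single_voxel_with_margin(self):
        lab = np.zeros((10, 10, 10), dtype=np.int16)
        lab[5, 5, 5] = 3
        assert locate_spine_bbox(lab, margin=2) == ((3, 8),) * 3

    def test_full_foreground_is_whole_grid(self):
        lab = np.ones((4, 6, 5), dtype=np.int16)
        assert locate_spine_bbox(lab) == ((0, 4), (0, 6), (0, 5))

    def test_tight_box_matches_brute_force(self):
        rng = np.random.default_rng(1)
        lab = (rng.random((9, 7, 8)) > 0.8).astype(np.int16)
        box = locate_spine_bbox(lab, margin=0)
        fg = np.argwhere(lab > 0)
        expect = tuple((int(fg[:, a].min()), int(fg[:, a].max()) + 1)
                       for a in range(3))
        assert box == expect

    def test_all_background_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            locate_spine_bbox(np.zeros((4, 4, 4), dtype=np.int16))

    def test_central_box_for_inference(self):
        assert central_bbox((10, 10, 10), (4, 20, 10)) == ((3, 7), (0, 10), (0, 10))


class TestCropPad:
    def test_output_shape_is_pad_shape(self):
        vol = np.ones((100, 100, 100))
        out = crop_and_pad(vol, ((0, 100),) * 3, (182, 256, 128))
        assert out.shape == (182, 256, 128)

    def test_exact_fit_is_identity(self):
        vol = np.random.default_rng(0).standard_normal((5, 6, 7))
        out = crop_and_pad(vol, ((0, 5), (0, 6), (0, 7)), (5, 6, 7))
        assert np.array_equal(out, vol)

    def test_zero_voxel_count(self):
        vol = np.ones((3, 3, 3))
        out = crop_and_pad(vol, ((0, 3),) * 3, (5, 5, 5))
        assert int((out == 0).sum()) == 125 - 27

    def test_oversized_content_center_cropped_with_warning(self):
        vol = np.ones((6, 6, 6))
        with pytest.warns(UserWarning, match="center-cropping"):
            out = crop_and_pad(vol, ((0, 6),) * 3, (4, 4, 4))
        assert out.shape == (4, 4, 4) and np.all(out == 1)

    def test_foreground_count_preserved(self):
        rng = np.random.default_rng(2)
        lab = (rng.random((8, 8, 8)) > 0.7).astype(np.int16)
        box = locate_spine_bbox(lab)
        out = crop_and_pad(lab, box, (12, 12, 12))
        assert int((out > 0).sum()) == int((lab > 0).sum())


class TestNormalize:
    def test_zscore_two_values(self):
        out = normalize_intensity(np.array([[[2.0, 4.0]]]), mode="zscore")
        assert np.allclose(np.asarray(out), [[[-1.0, 1.0]]])

    def test_mean_ratio_two_values(self):
        out = normalize_intensity(np.array([[[2.0, 4.0]]]), mode="mean_ratio")
        assert np.allclose(np.asarray(out), [[[-1 / 3, 1 / 3]]])

    def test_constant_volume_gives_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            out = normalize_intensity(np.full((3, 3, 3), 7.0), mode="zscore")
        assert np.all(np.asarray(out) == 0)

    def test_zscore_statistics_within_tolerance(self):
        vol = np.random.default_rng(3).random((10, 12, 8)) * 50 + 7
        out = np.asarray(normalize_intensity(vol, mode="zscore"))
        assert abs(out.mean()) < 1e-5 and abs(out.std() - 1) < 1e-5


class TestResize:
    def test_same_shape_identity(self):
        vol = np.random.default_rng(4).standard_normal((6, 6, 6))
        assert np.abs(np.asarray(resize_volume(vol, (6, 6, 6))) - vol).max() < 1e-6

    def test_probmap_renormalized_after_upsampling(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 4, (4, 4, 4))
        onehot = np.eye(4)[labels].transpose(3, 0, 1, 2)
        up = resize_probmap(onehot, (8, 8, 8))
        assert np.abs(up.sum(axis=0) - 1.0).max() < 1e-6

    def test_nearest_resize_introduces_no_new_labels(self):
        rng = np.random.default_rng(6)
        lab = rng.integers(0, 20, (9, 7, 5)).astype(np.int16)
        out = np.asarray(resize_labelmap(lab, (5, 11, 8)))
        assert set(np.unique(out)) <= set(np.unique(lab))

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            resize_volume(np.zeros((4, 4, 4)), (0, 4, 4))


class TestRefineSlices:
    def test_pair_count_and_alignment(self):
        rng = np.random.default_rng(7)
        vol = rng.standard_normal((18, 16, 12))
        probs = rng.random((5, 18, 16, 12))
        probs /= probs.sum(axis=0, keepdims=True)
        pairs = prepare_refine_slices(vol, probs)
        assert len(pairs) == 18
        # argmax of slice k equals slice k of the argmax volume
        vol_argmax = np.argmax(probs, axis=0)
        for k in (0, 9, 17):
            img, pk = pairs[k]
            assert np.array_equal(img, vol[k])
            assert np.array_equal(np.argmax(pk, axis=0), vol_argmax[k])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            prepare_refine_slices(np.zeros((4, 4, 4)), np.zeros((5, 4, 4, 5)))

    def test_wrong_rank_rejected(self):
        with pytest.raises(ValueError, match="4D"):
            prepare_refine_slices(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)))


class TestAugment:
    def test_no_rotation_no_jitter_is_identity(self):
        cfg = PreprocessConfig(rotation_limit=0, brightness_limit=0,
                               contrast_limit=0)
        vol = np.random.default_rng(8).random((6, 6, 6))
        lab = np.ones((6, 6, 6), dtype=np.int16)
        av, al = augment_sample(vol, lab, np.random.default_rng(0), cfg)
        assert np.allclose(np.asarray(av), vol)
        assert np.array_equal(np.asarray(al), lab)

    def test_deterministic_under_fixed_seed(self, phantom_pair):
        vol, lab = phantom_pair
        cfg = PreprocessConfig.phantom_scale()
        a1 = augment_sample(vol, lab, np.random.default_rng(42), cfg)
        a2 = augment_sample(vol, lab, np.random.default_rng(42), cfg)
        assert np.array_equal(a1[0].data, a2[0].data)
        assert np.array_equal(a1[1].data, a2[1].data)

    def test_rotated_labels_subset_of_original(self, phantom_pair):
        vol, lab = phantom_pair
        cfg = PreprocessConfig.phantom_scale()
        _, al = augment_sample(vol, lab, np.random.default_rng(9), cfg)
        assert set(np.unique(al.data)) <= set(np.unique(lab.data))

    def test_rotation_angle_bounded_by_limit(self, phantom_pair):
        # the angle is the first uniform draw from the generator; replaying
        # the generator exposes it for the bound check
        vol, lab = phantom_pair
        cfg = PreprocessConfig.phantom_scale()
        for seed in range(10):
            angle = np.random.default_rng(seed).uniform(-cfg.rotation_limit,
                                                        cfg.rotation_limit)
            assert abs(angle) <= 15.0
            from scipy import ndimage
            expect = ndimage.rotate(lab.data, angle, axes=(1, 2), reshape=False,
                                    order=0, mode="constant", cval=0)
            _, al = augment_sample(vol, lab, np.random.default_rng(seed), cfg)
            assert np.array_equal(al.data, expect)
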