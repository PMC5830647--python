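"""Image/mask I/O, the 3-class codec, resampling, patching, normalization."""

import numpy as np
import pytest

from fiberseg.imagery import (PatchSet, ScalarImage, SegmentationMask,
                              decode_mask, encode_mask, extract_patches,
                              normalize_patch, read_image, read_mask,
                              resample_image, resample_mask, split_train_val,
                              write_image, write_mask)


class TestScalarImage:
    def test_rejects_nonpositive_pixel_size(self):
        with pytest.raises(ValueError, match="pixel_size"):
            ScalarImage(np.zeros((4, 4)), 0.0)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            ScalarImage(np.zeros((0, 4)), 0.1)


class TestIO:
    def test_round_trip_preserves_pixels_and_pixel_size(self, tmp_path, rng):
        arr = rng.integers(0, 256, size=(100, 80)).astype(np.uint8)
        img = ScalarImage(arr, 0.1)
        write_image(img, tmp_path / "img.png")
        back = read_image(tmp_path / "img.png")  # pixel size from sidecar
        assert back.pixel_size == 0.1
        assert back.shape == (100, 80)
        np.testing.assert_array_equal(back.pixels, arr)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image(tmp_path / "nope.png", 0.1)

    def test_explicit_pixel_size_overrides_sidecar(self, tmp_path):
        write_image(ScalarImage(np.zeros((8, 8)), 0.1), tmp_path / "a.png")
        assert read_image(tmp_path / "a.png", 0.25).pixel_size == 0.25

    def test_mask_round_trip(self, tmp_path, rng):
        mask = SegmentationMask(rng.integers(0, 3, size=(32, 32)).astype(np.uint8), 0.1)
        write_mask(mask, tmp_path / "m.png")
        back = read_mask(tmp_path / "m.png")
        np.testing.assert_array_equal(back.classes, mask.classes)


class TestMaskCodec:
    @pytest.mark.parametrize("level,cls", [(0, 0), (127, 1), (255, 2)])
    def test_levels_map_to_classes(self, level, cls):
        mask = decode_mask(np.full((5, 5), level, dtype=np.uint8))
        assert (mask.classes == cls).all()

    def test_encode_decode_identity(self, rng):
        label = np.array([0, 127, 255], dtype=np.uint8)[rng.integers(0, 3, size=(16, 16))]
        assert (encode_mask(decode_mask(label)) == label).all()

    def test_decode_encode_identity(self, rng):
        mask = SegmentationMask(rng.integers(0, 3, size=(16, 16)).astype(np.uint8), 0.1)
        np.testing.assert_array_equal(decode_mask(encode_mask(mask)).classes, mask.classes)

    def test_out_of_alphabet_value_named_in_error(self):
        bad = np.full((3, 3), 64, dtype=np.uint8)
        with pytest.raises(ValueError, match="64"):
            decode_mask(bad)


class TestResampling:
    def test_scale_factor_two(self):
        img = ScalarImage(np.random.default_rng(0).random((100, 100)), 0.2)
        out = resample_image(img, 0.1)
        assert out.shape == (200, 200)
        assert out.pixel_size == 0.1

    def test_identity_is_bitwise(self):
        arr = np.arange(64, dtype=np.uint8).reshape(8, 8)
        out = resample_image(ScalarImage(arr, 0.13), 0.13)
        np.testing.assert_array_equal(out.pixels, arr)

    def test_noninteger_factor_shape(self):
        # round(512 * 0.13 / 0.1) = 666
        img = ScalarImage(np.zeros((512, 512)), 0.13)
        assert resample_image(img, 0.1).shape == (666, 666)

    def test_mask_values_stay_in_alphabet(self, rng):
        mask = SegmentationMask(rng.integers(0, 3, size=(50, 50)).astype(np.uint8), 0.2)
        out = resample_mask(mask, 0.13)
        assert set(np.unique(out.classes)) <= {0, 1, 2}

    def test_mask_round_trip_even_factor(self, rng):
        mask = SegmentationMask(rng.integers(0, 3, size=(40, 40)).astype(np.uint8), 0.1)
        back = resample_mask(resample_mask(mask, 0.05), 0.1)
        np.testing.assert_array_equal(back.classes, mask.classes)

    def test_single_class_mask_uniform(self):
        mask = SegmentationMask(np.ones((30, 30), dtype=np.uint8), 0.1)
        assert (resample_mask(mask, 0.07).classes == 1).all()

    def test_degenerate_output_rejected(self):
        with pytest.raises(ValueError):
            resample_image(ScalarImage(np.zeros((4, 4)), 0.1), 100.0)


class TestPatching:
    @pytest.mark.parametrize("side,n_expected", [(1024, 4), (600, 4), (512, 1)])
    def test_patch_counts(self, side, n_expected, rng):
        img = ScalarImage(rng.random((side, side)), 0.1)
        mask = SegmentationMask(rng.integers(0, 3, size=(side, side)).astype(np.uint8), 0.1)
        assert len(extract_patches(img, mask)) == n_expected

    def test_restitch_reproduces_input(self, rng):
        shape = (700, 900)
        img = ScalarImage(rng.random(shape), 0.1)
        mask = SegmentationMask(rng.integers(0, 3, size=shape).astype(np.uint8), 0.1)
        pset = extract_patches(img, mask)
        canvas = np.zeros((1024, 1024))
        for (im, _), (r, c) in zip(pset.patches, pset.origins):
            canvas[r:r + 512, c:c + 512] = im
        np.testing.assert_array_equal(canvas[:shape[0], :shape[1]], img.pixels)

    def test_single_patch_is_identity(self, rng):
        arr = rng.random((512, 512))
        pset = extract_patches(ScalarImage(arr, 0.1),
                               SegmentationMask(np.zeros((512, 512), np.uint8), 0.1))
        np.testing.assert_array_equal(pset.patches[0][0], arr)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            extract_patches(ScalarImage(np.zeros((512, 512)), 0.1),
                            SegmentationMask(np.zeros((500, 512), np.uint8), 0.1))

    def test_save_load_round_trip(self, tmp_path, rng):
        img = ScalarImage(rng.integers(0, 256, size=(512, 1024)).astype(np.uint8), 0.1)
        mask = SegmentationMask(rng.integers(0, 3, size=(512, 1024)).astype(np.uint8), 0.1)
        pset = split_train_val(extract_patches(img, mask), seed=1)
        pset.save(tmp_path / "ps")
        back = PatchSet.load(tmp_path / "ps")
        assert back.splits == pset.splits
        assert back.origins == pset.origins
        for (a, am), (b, bm) in zip(pset.patches, back.patches):
            np.testing.assert_array_equal(a, b)
            np.testing.assert_array_equal(am, bm)


class TestNormalizePatch:
    def test_zero_mean_unit_variance(self, rng):
        out = normalize_patch(rng.integers(0, 256, size=(512, 512)))
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1) < 1e-6

    def test_constant_patch_maps_to_zeros(self):
        assert (normalize_patch(np.full((64, 64), 37.0)) == 0).all()

    def test_two_level_patch_symmetric(self):
        patch = np.zeros((64, 64))
        patch[:, 32:] = 255
        out = normalize_patch(patch)
        levels = np.unique(np.round(out, 6))
        # equalized CDF gives 0.5/1.0, standardization centers them at -1/+1
        np.testing.assert_allclose(levels, [-1.0, 1.0], atol=1e-6)
        assert (out < 0).sum() == (out > 0).sum()


class TestSplit:
    def test_seventy_thirty(self, rng):
        patches = [(np.zeros((512, 512)), np.zeros((512, 512), np.uint8))] * 10
        pset = PatchSet(list(patches), [(0, 0)] * 10)
        out = split_train_val(pset, seed=0)
        assert sum(s == "train" for s in out.splits) == 7
        assert sum(s == "validation" for s in out.splits) == 3

    def test_deterministic_under_seed(self):
        patches = [(np.zeros((512, 512)), np.zeros((512, 512), np.uint8))] * 9
        pset = PatchSet(list(patches), [(0, 0)] * 9)
        assert split_train_val(pset, seed=5).splits == split_train_val(pset, seed=5).splits

    def test_full_fraction_warns(self):
        patches = [(np.zeros((512, 512)), np.zeros((512, 512), np.uint8))] * 4
        pset = PatchSet(list(patches), [(0, 0)] * 4)
        with pytest.warns(UserWarning, match="validation split is empty"):
            out = split_train_val(pset, fraction=1.0, seed=0)
        assert all(s == "train" for s in out.splits)

    def test_too_few_patches(self):
        pset = PatchSet([(np.zeros((512, 512)), np.zeros((512, 512), np.uint8))], [(0, 0)])
        with pytest.raises(ValueError):
            split_train_val(pset)
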