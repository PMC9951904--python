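"""Preprocessing pipeline: windowing, equalization, resizing, normalization,
six-view augmentation and patient-level splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from aimunet.config import AugmentationPolicy, SplitSpec
from aimunet.imaging_io import BinaryMask, CTSlice
from aimunet.preprocess import (augment_dataset, augment_pair, equalize_histogram,
                                normalize_unit, preprocess_slice, resize_to_network,
                                split_patients, window_hounsfield)


def _raw(pixels):
    return CTSlice(pixels=np.asarray(pixels, dtype=float), intensity_state="raw_hu")


class TestWindow:
    @pytest.mark.parametrize("value,expected", [(-300, -100), (500, 200), (150, 150)])
    def test_clamping(self, value, expected):
        out = window_hounsfield(_raw([[value]]))
        assert out.pixels[0, 0] == expected
        assert out.intensity_state == "windowed"

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            window_hounsfield(_raw([[0]]), lo=10, hi=10)

    def test_requires_raw_state(self):
        windowed = window_hounsfield(_raw([[0]]))
        with pytest.raises(ValueError):
            window_hounsfield(windowed)


class TestEqualize:
    def test_constant_image(self):
        out = equalize_histogram(window_hounsfield(_raw(np.full((8, 8), 40.0))))
        assert np.unique(out.pixels).size == 1

    def test_two_level_cdf_oracle(self):
        # 25% at level a < 75% at level b: outputs are the normalized
        # cumulative histogram evaluated at a (0.25) and b (1.0)
        img = np.full((4, 4), 100.0)
        img.ravel()[:4] = -50.0
        out = equalize_histogram(window_hounsfield(_raw(img)))
        low = out.pixels.ravel()[:4]
        high = out.pixels.ravel()[4:]
        assert np.allclose(low, 0.25)
        assert np.allclose(high, 1.0)

    @settings(max_examples=25, deadline=None)
    @given(hnp.arrays(np.float64, (6, 6), elements=st.floats(-100, 200)))
    def test_rank_preserved(self, pixels):
        ct = window_hounsfield(_raw(pixels))
        out = equalize_histogram(ct)
        a, b = ct.pixels.ravel(), out.pixels.ravel()
        order = np.argsort(a, kind="stable")
        diffs = np.diff(b[order])
        # monotone non-decreasing in input intensity: no inversions
        assert np.all(diffs >= -1e-12)


class TestResize:
    def test_512_to_256(self):
        ct = window_hounsfield(_raw(np.random.default_rng(0).random((512, 512))))
        out = resize_to_network(ct, 256)
        assert out.pixels.shape == (256, 256)

    def test_identity_at_target_size(self):
        ct = _raw(np.zeros((256, 256)))
        assert resize_to_network(ct, 256) is ct

    def test_checkerboard_mask_stays_binary(self):
        mask = BinaryMask(pixels=(np.indices((512, 512)).sum(axis=0) % 2).astype(np.uint8))
        out = resize_to_network(mask, 256)
        assert set(np.unique(out.pixels)) <= {0, 1}
        assert out.pixels.shape == (256, 256)

    def test_small_side_rejected(self):
        with pytest.raises(ValueError):
            resize_to_network(_raw(np.zeros((32, 32))), 8)


class TestNormalize:
    def test_endpoints(self):
        ct = equalize_histogram(window_hounsfield(_raw([[0.0, 50.0], [100.0, 200.0]])))
        out = normalize_unit(ct)
        assert out.pixels.min() == 0.0
        assert out.pixels.max() == 1.0
        assert out.intensity_state == "normalized"

    def test_constant_maps_to_zero(self):
        ct = equalize_histogram(window_hounsfield(_raw(np.full((4, 4), 7.0))))
        assert np.all(normalize_unit(ct).pixels == 0.0)

    def test_linear_ramp_affine(self):
        # normalization alone is affine: check on an equalized-state ramp
        ramp = np.linspace(0.25, 0.75, 16).reshape(4, 4)
        ct = CTSlice(pixels=ramp, intensity_state="equalized")
        out = normalize_unit(ct)
        assert np.allclose(out.pixels, (ramp - 0.25) / 0.5)

    def test_full_pipeline_contract(self):
        rng = np.random.default_rng(5)
        ct = _raw(rng.uniform(-500, 500, (96, 96)))
        out = preprocess_slice(ct, side=64)
        assert out.pixels.shape == (64, 64)
        assert out.intensity_state == "normalized"
        assert 0.0 <= out.pixels.min() and out.pixels.max() <= 1.0


class TestAugmentation:
    @pytest.fixture()
    def pair(self):
        rng = np.random.default_rng(8)
        img = CTSlice(pixels=rng.random((64, 64)), patient_id="p", slice_index=1,
                      intensity_state="normalized")
        mask = BinaryMask(pixels=(rng.random((64, 64)) > 0.7).astype(np.uint8))
        return img, mask

    def test_six_views_and_sevenfold_dataset(self, pair):
        policy = AugmentationPolicy(seed=4)
        views = augment_pair(*pair, policy)
        assert len(views) == len(policy.transforms) == 6
        dataset = augment_dataset([pair, pair, pair], policy)
        assert len(dataset) == 7 * 3

    def test_vertical_flip_is_involution(self, pair):
        policy = AugmentationPolicy(seed=4)
        views = dict(zip(policy.transforms, augment_pair(*pair, policy)))
        flipped_img, flipped_mask = views["vertical_flip"]
        assert np.array_equal(np.flipud(flipped_img.pixels), pair[0].pixels)
        assert np.array_equal(np.flipud(flipped_mask.pixels), pair[1].pixels)

    def test_photometric_leaves_mask_untouched(self, pair):
        policy = AugmentationPolicy(seed=4)
        views = dict(zip(policy.transforms, augment_pair(*pair, policy)))
        img, mask = views["random_brightness_contrast"]
        assert np.array_equal(mask.pixels, pair[1].pixels)
        assert not np.array_equal(img.pixels, pair[0].pixels)

    def test_all_views_keep_masks_binary_and_deterministic(self, pair):
        policy = AugmentationPolicy(seed=4)
        views1 = augment_pair(*pair, policy)
        views2 = augment_pair(*pair, policy)
        for (i1, m1), (i2, m2) in zip(views1, views2):
            assert set(np.unique(m1.pixels)) <= {0, 1}
            assert np.array_equal(i1.pixels, i2.pixels)
            assert np.array_equal(m1.pixels, m2.pixels)


class TestSplit:
    def test_fifty_patients_five_test(self):
        ids = [f"p{i}" for i in range(50)]
        split = split_patients(ids, SplitSpec(seed=1))
        assert len(split["test"]) == 5
        # 45 remaining: 30% validation
        assert len(split["val"]) == round(0.3 * 45)

    def test_partition(self):
        ids = [f"p{i}" for i in range(17)]
        split = split_patients(ids, SplitSpec(seed=2))
        union = split["train"] | split["val"] | split["test"]
        assert union == set(ids)
        assert not (split["train"] & split["val"])
        assert not (split["train"] & split["test"])
        assert not (split["val"] & split["test"])

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(20)]
        assert split_patients(ids, SplitSpec(seed=9)) == split_patients(ids, SplitSpec(seed=9))
        assert split_patients(ids, SplitSpec(seed=9)) != split_patients(ids, SplitSpec(seed=10))

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            split_patients(["a", "b"], SplitSpec())
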