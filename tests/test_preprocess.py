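"""Preprocessing chain: slice selection, crop, binarize, dilate, foreground."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octlam.phantom import BScanStack, PhantomSpec, generate_stack
from octlam.preprocess import (
    PreprocessConfig,
    assemble_volume,
    binarize_slice,
    center_crop,
    dilate,
    extract_foreground,
    select_slices,
)

DEFAULTS = PreprocessConfig()


def _stack(n_slices, h=16, w=16, fill=0):
    return BScanStack(
        slices=[np.full((h, w), fill, np.uint8) for _ in range(n_slices)],
        patient_id="P", eye_id="OD", label=0,
    )


class TestSelectSlices:
    def test_macular_window_before_stride_is_140(self):
        cfg = dataclasses.replace(DEFAULTS, sample_stride=1)
        assert len(select_slices(_stack(400), cfg)) == 140

    def test_stride_two_yields_70(self):
        assert len(select_slices(_stack(400), DEFAULTS)) == 70

    def test_identity_selection(self):
        cfg = dataclasses.replace(DEFAULTS, slice_lo=0, slice_hi=400, sample_stride=1)
        assert len(select_slices(_stack(400), cfg)) == 400

    def test_short_stack_error_names_required_length(self):
        with pytest.raises(ValueError, match="270"):
            select_slices(_stack(200), DEFAULTS)


class TestCenterCrop:
    def test_middle_140_of_400(self):
        out = center_crop(np.zeros((640, 400), np.uint8), 140)
        assert out.shape == (640, 140)

    def test_full_width_is_identity(self):
        sl = np.arange(20, dtype=np.uint8).reshape(4, 5)
        np.testing.assert_array_equal(center_crop(sl, 5), sl)

    def test_centered_column_arithmetic(self):
        sl = np.zeros((8, 400), np.uint8)
        sl[:, 200] = 255
        out = center_crop(sl, 140)
        assert np.all(out[:, 70] == 255)
        assert out.sum() == 8 * 255

    def test_too_wide_crop_rejected(self):
        with pytest.raises(ValueError):
            center_crop(np.zeros((4, 4), np.uint8), 5)


class TestBinarize:
    FIXED = dataclasses.replace(DEFAULTS, binarize_method="fixed")

    def test_all_zero_slice_gives_empty_mask(self):
        assert binarize_slice(np.zeros((6, 6), np.uint8), self.FIXED).sum() == 0

    def test_checkerboard_thresholds_exactly(self):
        sl = np.indices((6, 6)).sum(axis=0) % 2 * 255
        np.testing.assert_array_equal(binarize_slice(sl, self.FIXED), sl // 255)

    def test_constant_slice_otsu_falls_back(self, caplog):
        sl = np.full((5, 5), 99, np.uint8)
        with caplog.at_level("WARNING"):
            out = binarize_slice(sl, DEFAULTS)
        assert "fall" in caplog.text
        assert np.all(out == 1)  # 99 >= fixed threshold 25

    @given(st.integers(0, 255), st.integers(0, 255))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_ones_count_monotone_in_threshold(self, t1, t2):
        sl = (np.arange(64).reshape(8, 8) * 4 % 256).astype(np.uint8)
        lo, hi = sorted((t1, t2))
        n_lo = binarize_slice(sl, dataclasses.replace(self.FIXED, fixed_threshold=lo)).sum()
        n_hi = binarize_slice(sl, dataclasses.replace(self.FIXED, fixed_threshold=hi)).sum()
        assert n_hi <= n_lo


def _brute_force_dilate(mask, kernel, iters):
    """Independent oracle: set union of elliptical neighborhoods."""
    r = (kernel - 1) // 2
    offs = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if r == 0 or (dy / r) ** 2 + (dx / r) ** 2 <= 1
    ]
    out = mask.astype(bool)
    h, w = mask.shape
    for _ in range(iters):
        nxt = np.zeros_like(out)
        for y, x in zip(*np.nonzero(out)):
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    nxt[yy, xx] = True
        out = nxt
    return out.astype(np.uint8)


class TestDilate:
    def test_empty_mask_stays_empty(self):
        assert dilate(np.zeros((7, 7), np.uint8), DEFAULTS).sum() == 0

    def test_single_pixel_matches_brute_force_oracle(self):
        mask = np.zeros((11, 11), np.uint8)
        mask[5, 5] = 1
        cfg = dataclasses.replace(DEFAULTS, dilation_kernel=5, dilation_iters=1)
        np.testing.assert_array_equal(dilate(mask, cfg), _brute_force_dilate(mask, 5, 1))

    def test_iterated_dilation_matches_oracle(self):
        rng = np.random.default_rng(5)
        mask = (rng.random((12, 12)) > 0.85).astype(np.uint8)
        np.testing.assert_array_equal(dilate(mask, DEFAULTS), _brute_force_dilate(mask, 5, 2))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_extensivity(self, seed):
        mask = (np.random.default_rng(seed).random((10, 10)) > 0.8).astype(np.uint8)
        out = dilate(mask, DEFAULTS)
        assert np.all(out >= mask)


class TestExtractForeground:
    def test_rectangle_component_masks_exactly(self):
        sl = np.full((10, 10), 37, np.uint8)
        mask = np.zeros((10, 10), np.uint8)
        mask[2:5, 3:8] = 1
        out = extract_foreground(sl, mask)
        assert np.all(out[2:5, 3:8] == 37)
        outside = np.ones((10, 10), bool)
        outside[2:5, 3:8] = False
        assert out[outside].sum() == 0

    def test_largest_component_survives(self):
        sl = np.full((20, 20), 50, np.uint8)
        mask = np.zeros((20, 20), np.uint8)
        mask[0:10, 0:10] = 1  # area 100
        mask[15:17, 15:20] = 1  # area 10
        out = extract_foreground(sl, mask)
        assert np.all(out[0:10, 0:10] == 50)
        assert out[15:17, 15:20].sum() == 0

    def test_holes_in_largest_component_are_filled(self):
        sl = np.full((9, 9), 80, np.uint8)
        mask = np.zeros((9, 9), np.uint8)
        mask[1:8, 1:8] = 1
        mask[4, 4] = 0  # interior hole
        out = extract_foreground(sl, mask)
        assert out[4, 4] == 80

    def test_empty_mask_returns_slice_unchanged(self, caplog):
        sl = np.arange(16, dtype=np.uint8).reshape(4, 4)
        with caplog.at_level("WARNING"):
            out = extract_foreground(sl, np.zeros((4, 4), np.uint8))
        np.testing.assert_array_equal(out, sl)
        assert "empty mask" in caplog.text

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_foreground(np.zeros((4, 4)), np.zeros((5, 4)))


@pytest.fixture(scope="module")
def phantom_stack():
    spec = PhantomSpec(width=200, height=320, n_slices=280, n_layers=4)
    return generate_stack(spec)


class TestAssembleVolume:
    def test_default_output_shape(self, phantom_stack):
        cfg = dataclasses.replace(DEFAULTS, slice_hi=270)
        v = assemble_volume(phantom_stack, cfg)
        assert v.data.shape == (100, 100, 70)
        assert np.isfinite(v.data).all()
        assert v.data.min() >= 0.0 and v.data.max() <= 1.0

    def test_determinism(self, phantom_stack):
        cfg = dataclasses.replace(DEFAULTS, slice_hi=270)
        a = assemble_volume(phantom_stack, cfg)
        b = assemble_volume(phantom_stack, cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_all_black_stack_gives_zero_volume(self):
        st = BScanStack(
            slices=[np.zeros((320, 200), np.uint8) for _ in range(280)],
            patient_id="P", eye_id="OD", label=0,
        )
        cfg = dataclasses.replace(DEFAULTS, slice_hi=270)
        v = assemble_volume(st, cfg)
        assert v.data.sum() == 0.0
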