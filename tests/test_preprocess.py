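"""Sobel/Hough boundary detection, HSV masking, morphological cleanup."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endoattn import preprocess as pp
from endoattn.synthetic import FrameSpec, generate_frame, random_frame_spec


def uniform_frame(r, g, b, side=64):
    return np.full((side, side, 3), (r, g, b), dtype=np.uint8)


class TestSobel:
    def test_constant_image_has_zero_gradients(self):
        gx, gy = pp.sobel_gradients(uniform_frame(120, 120, 120))
        assert np.all(gx == 0) and np.all(gy == 0)

    def test_vertical_step_localises_gx(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        img[:, 32:] = 255
        gx, gy = pp.sobel_gradients(img)
        # |gx| is maximal exactly on the two columns flanking the step
        peak_cols = np.unique(np.argwhere(np.abs(gx) == np.abs(gx).max())[:, 1])
        assert set(peak_cols) == {31, 32}
        assert np.all(gy[1:-1, :] == 0)

    def test_transpose_swaps_gradient_roles(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (48, 48, 3), dtype=np.uint8)
        gx, gy = pp.sobel_gradients(img)
        gxt, gyt = pp.sobel_gradients(img.transpose(1, 0, 2))
        assert np.allclose(gxt, gy.T)
        assert np.allclose(gyt, gx.T)


class TestDetectROI:
    def test_left_right_strips_recovered(self):
        spec = FrameSpec(border_columns_left=20, border_columns_right=20)
        frame, truth = generate_frame(spec)
        box = pp.detect_roi_boundaries(frame)
        assert abs(box.left - 20) <= 2
        assert abs(box.right - 236) <= 2
        assert box.top == 0 and box.bottom == 256

    def test_borderless_frame_falls_back_to_full_box(self):
        spec = FrameSpec(border_columns_left=0, border_columns_right=0)
        frame, _ = generate_frame(spec)
        box = pp.detect_roi_boundaries(frame)
        assert (box.left, box.top, box.right, box.bottom) == (0, 0, 256, 256)

    def test_four_sided_border_recovered(self):
        spec = FrameSpec(border_columns_left=24, border_columns_right=24,
                         border_rows_top=20, border_rows_bottom=20)
        frame, truth = generate_frame(spec)
        box = pp.detect_roi_boundaries(frame)
        gt = truth.roi_box
        for got, want in ((box.left, gt.left), (box.right, gt.right),
                          (box.top, gt.top), (box.bottom, gt.bottom)):
            assert abs(got - want) <= 2


class TestMasks:
    def test_uniform_dark_image_fully_flagged(self):
        assert pp.mask_dark(uniform_frame(50, 40, 30)).all()  # V = 50

    def test_uniform_bright_image_not_flagged_dark(self):
        assert not pp.mask_dark(uniform_frame(200, 150, 120)).any()

    def test_white_fully_flagged_reflective(self):
        assert pp.mask_reflective(uniform_frame(255, 255, 255)).all()

    def test_saturated_red_not_flagged_reflective(self):
        assert not pp.mask_reflective(uniform_frame(255, 0, 0)).any()

    def test_synthetic_patch_areas_within_five_percent(self):
        spec = FrameSpec(dark_patches=((100, 100, 11, 40),),
                         specular_spots=((170, 150, 8),))
        frame, truth = generate_frame(spec)
        crop = truth.roi_box.crop(frame)
        dark = pp.mask_dark(crop)
        refl = pp.mask_reflective(crop)
        gt_dark = truth.roi_box.crop(truth.dark_mask).sum()
        gt_refl = truth.roi_box.crop(truth.reflective_mask).sum()
        assert abs(dark.sum() - gt_dark) <= 0.05 * gt_dark
        assert abs(refl.sum() - gt_refl) <= 0.05 * gt_refl

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 254), st.data())
    def test_threshold_monotonicity(self, lo, data):
        hi = data.draw(st.integers(lo + 1, 255))
        rng = np.random.default_rng(data.draw(st.integers(0, 10)))
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        low_cfg = pp.PreprocessConfig(value_threshold=lo,
                                      saturation_threshold=lo,
                                      reflective_value_floor=255)
        high_cfg = pp.PreprocessConfig(value_threshold=hi,
                                       saturation_threshold=hi,
                                       reflective_value_floor=255)
        assert not (pp.mask_dark(img, low_cfg)
                    & ~pp.mask_dark(img, high_cfg)).any()
        assert not (pp.mask_reflective(img, low_cfg)
                    & ~pp.mask_reflective(img, high_cfg)).any()

    def test_final_masks_disjoint_by_construction(self):
        with pytest.raises(ValueError):
            pp.PreprocessConfig(value_threshold=150,
                                reflective_value_floor=140)


class TestMorphClean:
    def test_empty_mask_stays_empty(self):
        cfg = pp.PreprocessConfig()
        assert not pp.morph_clean(np.zeros((40, 40), bool), cfg).any()

    def test_isolated_pixel_removed(self):
        mask = np.zeros((40, 40), bool)
        mask[20, 20] = True
        cfg = pp.PreprocessConfig(morph_kernel_radius=1, morph_cycles=1,
                                  min_component_area=1)
        assert not pp.morph_clean(mask, cfg).any()

    def test_large_solid_block_survives_intact(self):
        mask = np.zeros((80, 80), bool)
        mask[10:60, 10:60] = True
        cfg = pp.PreprocessConfig(morph_kernel_radius=1, morph_cycles=1,
                                  min_component_area=1)
        out = pp.morph_clean(mask, cfg)
        # opening with a diamond element keeps the block except the four
        # extreme corner pixels, which the disc cannot reach
        assert not (out & ~mask).any()
        assert (mask & ~out).sum() <= 4
        assert out[11:59, 11:59].all()

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 1000))
    def test_cleanup_never_creates_pixels(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48)) < 0.3
        out = pp.morph_clean(mask, pp.PreprocessConfig())
        assert not (out & ~mask).any()


class TestPreprocessFrame:
    def test_recovery_on_synthetic_frame(self):
        spec = random_frame_spec(FrameSpec(), 1, seed=77)
        frame, truth = generate_frame(spec)
        crop, masks = pp.preprocess_frame(frame)
        box = pp.detect_roi_boundaries(frame)
        gt = truth.roi_box
        assert abs(box.left - gt.left) <= 2 and abs(box.right - gt.right) <= 2
        pred = np.zeros(frame.shape[:2], bool)
        pred[box.top:box.bottom, box.left:box.right] = masks.interference
        inter = (pred & truth.interference_mask).sum()
        union = (pred | truth.interference_mask).sum()
        assert inter / union >= 0.90

    def test_idempotent_on_clean_crop(self):
        spec = FrameSpec(border_columns_left=0, border_columns_right=0)
        frame, _ = generate_frame(spec)
        crop, masks = pp.preprocess_frame(frame)
        assert np.array_equal(crop.pixels, frame)
        assert not masks.interference.any()

    def test_second_pass_changes_almost_nothing(self):
        spec = random_frame_spec(FrameSpec(), 0, seed=5)
        frame, _ = generate_frame(spec)
        crop1, _ = pp.preprocess_frame(frame)
        crop2, _ = pp.preprocess_frame(crop1)
        assert crop2.pixels.shape == crop1.pixels.shape
        changed = (crop2.pixels != crop1.pixels).any(axis=-1).mean()
        assert changed < 0.01

    def test_degenerate_roi_raises(self):
        tiny = np.full((40, 40, 3), 150, dtype=np.uint8)
        tiny[:, :18] = 5
        tiny[:, -18:] = 5
        with pytest.raises(pp.DegenerateROIError):
            pp.preprocess_frame(tiny, pp.PreprocessConfig(
                hough_vote_threshold=10))
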