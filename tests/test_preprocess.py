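"""Contrast, segmentation/crop, padding, dihedral augmentation."""

import numpy as np
import pytest

from stedlite.imagecore import MicroImage, PairedSample
from stedlite.preprocess import (
    CropBox,
    PreprocessConfig,
    augment,
    dihedral,
    enhance_contrast,
    pad_to,
    run_preprocess,
    segment_crop,
)
from stedlite.synthdata import PhantomConfig, generate_dataset


def _pair(src, tgt, **kw):
    return PairedSample(source=MicroImage(src), target=MicroImage(tgt), **kw)


class TestEnhanceContrast:
    def test_full_range_ramp_unchanged(self):
        px = np.tile(np.linspace(0, 1, 100), (4, 1))
        out = enhance_contrast(MicroImage(px), 0.0)
        np.testing.assert_allclose(out.pixels, px, atol=1e-12)

    def test_hot_pixel_clipped_against_quantile_oracle(self):
        rng = np.random.default_rng(0)
        px = rng.random((50, 50))  # background <= 1
        px[10, 10] = 100.0
        sat = 0.02
        out = enhance_contrast(MicroImage(px), sat)
        # independent oracle: sorted-array quantiles
        srt = np.sort(px.ravel())
        lo = np.quantile(srt, sat / 2)
        hi = np.quantile(srt, 1 - sat / 2)
        np.testing.assert_allclose(
            out.pixels, np.clip((px - lo) / (hi - lo), 0, 1), atol=1e-12
        )
        assert out.pixels[10, 10] == 1.0

    def test_idempotent_within_clipping(self):
        rng = np.random.default_rng(1)
        img = MicroImage(rng.random((40, 40)))
        once = enhance_contrast(img, 0.01)
        twice = enhance_contrast(once, 0.01)
        assert np.quantile(np.abs(twice.pixels - once.pixels), 0.98) < 0.05

    def test_constant_returns_zeros(self):
        out = enhance_contrast(MicroImage(np.full((5, 5), 3.0)), 0.01)
        np.testing.assert_array_equal(out.pixels, 0.0)


class TestSegmentCrop:
    def test_rectangle_bbox_exact(self):
        tgt = np.zeros((64, 64))
        tgt[20:30, 15:35] = 1.0  # 10 x 20 rectangle
        pair = _pair(tgt.copy(), tgt)
        cfg = PreprocessConfig(crop_margin_px=0, smooth_sigma_px=0.0)
        box, cropped = segment_crop(pair, cfg)
        assert (box.row0, box.col0, box.height, box.width) == (20, 15, 10, 20)
        assert cropped.source.pixels.shape == (10, 20)

    def test_largest_component_wins(self):
        tgt = np.zeros((96, 96))
        tgt[5:10, 5:15] = 1.0        # 50 px blob
        tgt[40:60, 40:60] = 1.0      # 400 px blob
        box, _ = segment_crop(_pair(tgt.copy(), tgt),
                              PreprocessConfig(crop_margin_px=0, smooth_sigma_px=0.0))
        assert (box.row0, box.col0) == (40, 40)
        assert (box.height, box.width) == (20, 20)

    def test_empty_target_errors(self):
        with pytest.raises(ValueError, match="no object found"):
            segment_crop(_pair(np.zeros((32, 32)), np.zeros((32, 32))))

    def test_oversize_object_errors(self):
        tgt = np.zeros((256, 256))
        tgt[10:200, 10:200] = 1.0
        with pytest.raises(ValueError, match="pad_size"):
            segment_crop(_pair(tgt.copy(), tgt), PreprocessConfig())

    def test_same_box_applied_to_both(self):
        rng = np.random.default_rng(2)
        src = rng.random((64, 64))
        tgt = np.zeros((64, 64))
        tgt[10:30, 12:40] = 1.0
        box, cropped = segment_crop(_pair(src, tgt),
                                    PreprocessConfig(crop_margin_px=2,
                                                     smooth_sigma_px=0.0))
        np.testing.assert_array_equal(cropped.source.pixels, src[box.slices()])


class TestPadTo:
    def test_offsets_floor_centered(self):
        img = MicroImage(np.ones((40, 90)))
        out = pad_to(img, 128)
        assert out.pixels.shape == (128, 128)
        assert out.pixels[44:84, 19:109].sum() == 40 * 90
        assert out.pixels.sum() == 40 * 90  # zero padding conserves mass
        assert out.pixels[43, 19] == 0 and out.pixels[44, 18] == 0

    def test_exact_size_identity(self):
        img = MicroImage(np.random.default_rng(0).random((128, 128)))
        assert pad_to(img, 128) is img

    def test_oversize_rejected(self):
        with pytest.raises(ValueError):
            pad_to(MicroImage(np.zeros((130, 10))), 128)


class TestAugment:
    def test_rot90_four_times_is_identity(self):
        px = np.random.default_rng(0).random((16, 16))
        out = px
        for _ in range(4):
            out = dihedral(out, 1)
        np.testing.assert_array_equal(out, px)

    def test_hflip_is_involution(self):
        px = np.random.default_rng(1).random((16, 16))
        np.testing.assert_array_equal(dihedral(dihedral(px, 4), 4), px)

    def test_group_orbit_sizes(self):
        # asymmetric image: all 8 transforms distinct; symmetric: all equal
        asym = np.arange(16.0).reshape(4, 4)
        orbit = {dihedral(asym, e).tobytes() for e in range(8)}
        assert len(orbit) == 8
        sym = np.ones((4, 4))
        orbit_sym = {dihedral(sym, e).tobytes() for e in range(8)}
        assert len(orbit_sym) == 1

    def test_same_element_both_members(self):
        rng = np.random.default_rng(3)
        src, tgt = rng.random((8, 8)), rng.random((8, 8))
        pair = _pair(src, tgt)
        out = augment(pair, seed=9)
        # find which element was applied to the source; target must match
        matches = [
            e for e in range(8)
            if np.array_equal(out.source.pixels, dihedral(src, e))
        ]
        assert len(matches) >= 1
        np.testing.assert_array_equal(out.target.pixels, dihedral(tgt, matches[0]))

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError, match="square"):
            augment(_pair(np.zeros((4, 8)), np.zeros((4, 8))), seed=0)

    def test_intensities_untouched(self):
        px = np.random.default_rng(4).random((8, 8))
        out = augment(_pair(px, px), seed=1)
        assert np.sort(out.source.pixels.ravel()).tolist() == np.sort(px.ravel()).tolist()


class TestRunPreprocess:
    @pytest.fixture()
    def synth_pair(self):
        return generate_dataset(1, PhantomConfig(size_px=96, seed=3))[0]

    def test_pipeline_contract(self, synth_pair):
        cfg = PreprocessConfig(pad_size=128)
        out = run_preprocess(synth_pair, cfg)
        assert out.source.pixels.shape == (128, 128)
        assert out.target.pixels.shape == (128, 128)
        assert 0 <= out.source.pixels.min() and out.source.pixels.max() <= 1
        assert 0 <= out.target.pixels.min() and out.target.pixels.max() <= 1
        assert isinstance(out.crop_box, CropBox)

    def test_identical_pipeline_for_both_members(self, synth_pair):
        # the crop geometry recorded for the source equals the target's
        out = run_preprocess(synth_pair, PreprocessConfig(pad_size=128))
        box = out.crop_box
        src_crop = enhance_contrast(synth_pair.source, 0.0035).pixels[box.slices()]
        # nonzero support of the padded source equals the crop placed centrally
        h, w = src_crop.shape
        r0, c0 = (128 - h) // 2, (128 - w) // 2
        sup = out.source.pixels[r0 : r0 + h, c0 : c0 + w]
        assert sup.max() > 0
        assert np.count_nonzero(out.source.pixels) == np.count_nonzero(sup)

    def test_deterministic(self, synth_pair):
        a = run_preprocess(synth_pair, PreprocessConfig())
        b = run_preprocess(synth_pair, PreprocessConfig())
        np.testing.assert_array_equal(a.source.pixels, b.source.pixels)
        np.testing.assert_array_equal(a.target.pixels, b.target.pixels)


class TestConfigValidation:
    def test_pad_size_must_be_even(self):
        with pytest.raises(ValueError):
            PreprocessConfig(pad_size=127)

    def test_saturation_range(self):
        with pytest.raises(ValueError):
            PreprocessConfig(saturation_fraction=0.6)
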