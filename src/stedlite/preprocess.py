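"""Preprocessing pipeline: contrast, segmentation/crop, padding, augmentation.

The stages mirror the standard microscopy preparation for patch-based
translation networks: a saturated-quantile contrast stretch (the ImageJ
"Enhance Contrast" convention, default 0.35% saturated pixels), Otsu
segmentation of the target to isolate the brightest structure, a joint
crop of both pair members around it, zero-padding to a fixed 128x128 tile,
and unit normalization.  Nothing in this module interpolates or rescales:
resampling would distort morphology and apparent pixel size, so oversize
crops are an error rather than a resize.

Geometric augmentation is the 8-element dihedral group of the square
(rotations by multiples of 90 degrees, optionally mirrored), applied
identically to source and target; it is sampled per training iteration by
the data loaders, not baked onto disk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .imagecore import MicroImage, PairedSample, normalize_unit

__all__ = [
    "PreprocessConfig",
    "CropBox",
    "enhance_contrast",
    "segment_crop",
    "pad_to",
    "dihedral",
    "augment",
    "run_preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    saturation_fraction: float = 0.0035
    pad_size: int = 128
    crop_margin_px: int = 8
    smooth_sigma_px: float = 1.0

    def __post_init__(self):
        if not 0 <= self.saturation_fraction < 0.5:
            raise ValueError("saturation_fraction must be in [0, 0.5)")
        if self.pad_size < 16 or self.pad_size % 2:
            raise ValueError("pad_size must be even and >= 16")
        if self.crop_margin_px < 0:
            raise ValueError("crop_margin_px must be >= 0")


@dataclass(frozen=True)
class CropBox:
    """Half-open box [row0, row0+height) x [col0, col0+width), 0-based."""

    row0: int
    col0: int
    height: int
    width: int

    def slices(self) -> Tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.height),
                slice(self.col0, self.col0 + self.width))


def enhance_contrast(img: MicroImage, saturation_fraction: float = 0.0035) -> MicroImage:
    """Saturated-quantile linear stretch.

    Maps the ``saturation_fraction/2`` lower and upper intensity quantiles
    to 0 and 1 with clipping, so a configurable fraction of pixels
    saturates at each end — the behavior of the ImageJ global contrast
    enhancement.  A constant image returns all zeros.
    """
    px = img.pixels
    lo = np.quantile(px, saturation_fraction / 2)
    hi = np.quantile(px, 1 - saturation_fraction / 2)
    if hi <= lo:
        return img.with_pixels(np.zeros_like(px))
    return img.with_pixels(np.clip((px - lo) / (hi - lo), 0.0, 1.0))


def segment_crop(
    pair: PairedSample, config: Optional[PreprocessConfig] = None
) -> Tuple[CropBox, PairedSample]:
    """Locate the dominant structure in the target and crop both images.

    Gaussian-smooth the target, threshold with Otsu's criterion, keep the
    largest connected component, and take its bounding box plus
    ``crop_margin_px`` (clipped to the image).  The identical box is
    applied to source and target, preserving registration.
    """
    config = config or PreprocessConfig()
    if not pair.registered:
        raise ValueError("pair must be registered before cropping")
    tgt = pair.target.pixels
    if config.smooth_sigma_px > 0:
        smooth = ndimage.gaussian_filter(tgt, config.smooth_sigma_px)
    else:
        smooth = tgt
    if np.ptp(smooth) == 0:
        raise ValueError("no object found: target has no signal")
    thr = threshold_otsu(smooth)
    fg = smooth > thr
    if not fg.any():
        raise ValueError("no object found: all pixels below threshold")
    lab = label(fg)
    regions = regionprops(lab)
    biggest = max(regions, key=lambda r: r.area)
    r0, c0, r1, c1 = biggest.bbox
    m = config.crop_margin_px
    r0, c0 = max(0, r0 - m), max(0, c0 - m)
    r1, c1 = min(tgt.shape[0], r1 + m), min(tgt.shape[1], c1 + m)
    box = CropBox(r0, c0, r1 - r0, c1 - c0)
    if box.height > config.pad_size or box.width > config.pad_size:
        raise ValueError(
            f"object box {box.height}x{box.width} exceeds pad_size "
            f"{config.pad_size}; increase pad_size or center-crop manually"
        )
    sl = box.slices()
    cropped = PairedSample(
        source=pair.source.with_pixels(pair.source.pixels[sl]),
        target=pair.target.with_pixels(pair.target.pixels[sl]),
        registered=True,
        sample_id=pair.sample_id,
        crop_box=box,
    )
    return box, cropped


def pad_to(img: MicroImage, pad_size: int = 128) -> MicroImage:
    """Zero-pad to ``pad_size`` square, centering with floor offsets.

    Padding value 0, no rescaling ever; mass (pixel sum) is conserved.
    """
    h, w = img.pixels.shape
    if h > pad_size or w > pad_size:
        raise ValueError(f"input {h}x{w} exceeds pad_size {pad_size}")
    if (h, w) == (pad_size, pad_size):
        return img
    out = np.zeros((pad_size, pad_size), dtype=img.pixels.dtype)
    r0 = (pad_size - h) // 2
    c0 = (pad_size - w) // 2
    out[r0 : r0 + h, c0 : c0 + w] = img.pixels
    return img.with_pixels(out)


def dihedral(pixels: np.ndarray, element: int) -> np.ndarray:
    """Apply element 0..7 of the square's symmetry group: ``element % 4``
    quarter-turn rotations, then a horizontal flip if ``element >= 4``."""
    if not 0 <= element < 8:
        raise ValueError("dihedral element must be in 0..7")
    out = np.rot90(pixels, k=element % 4)
    if element >= 4:
        out = np.fliplr(out)
    return np.ascontiguousarray(out)


def augment(pair: PairedSample, seed: Optional[int] = None,
            rng: Optional[np.random.Generator] = None,
            element: Optional[int] = None) -> PairedSample:
    """Apply one uniformly drawn dihedral transform to both pair members.

    Requires square images (rotations would otherwise change the shape);
    intensities are untouched.
    """
    h, w = pair.source.pixels.shape
    if h != w:
        raise ValueError("augmentation requires square images")
    if element is None:
        if rng is None:
            rng = np.random.default_rng(seed) if seed is not None else None
        if rng is None:
            from ._rng import get_rng

            rng = get_rng()
        element = int(rng.integers(0, 8))
    return PairedSample(
        source=pair.source.with_pixels(dihedral(pair.source.pixels, element)),
        target=pair.target.with_pixels(dihedral(pair.target.pixels, element)),
        registered=pair.registered,
        sample_id=pair.sample_id,
        crop_box=pair.crop_box,
    )


def run_preprocess(
    pair: PairedSample, config: Optional[PreprocessConfig] = None
) -> PairedSample:
    """Full deterministic pipeline: contrast -> segment/crop -> pad ->
    unit-normalize, with identical geometry for source and target.

    Augmentation is *not* applied here — it is sampled per iteration by
    the training loader.
    """
    config = config or PreprocessConfig()
    enhanced = PairedSample(
        source=enhance_contrast(pair.source, config.saturation_fraction),
        target=enhance_contrast(pair.target, config.saturation_fraction),
        registered=pair.registered,
        sample_id=pair.sample_id,
    )
    box, cropped = segment_crop(enhanced, config)
    padded = PairedSample(
        source=pad_to(cropped.source, config.pad_size),
        target=pad_to(cropped.target, config.pad_size),
        registered=True,
        sample_id=pair.sample_id,
        crop_box=box,
    )
    return PairedSample(
        source=normalize_unit(padded.source),
        target=normalize_unit(padded.target),
        registered=True,
        sample_id=pair.sample_id,
        crop_box=box,
    )
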