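"""Core domain types and intensity-range conventions.

Every stage of the pipeline exchanges :class:`MicroImage` objects: a single
2-D grayscale intensity grid plus the metadata needed downstream (modality,
acquisition quality, pixel size).  Two intensity conventions are used
throughout the package:

* *unit range* ``[0, 1]`` — the range in which all metrics operate;
* *network range* ``[-1, 1]`` — the range matching the tanh output of the
  generators, reached via :func:`to_net_range` / :func:`from_net_range`.

Images are stored as floating point regardless of the TIFF bit depth on
disk; integer data is converted on read, never truncated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import tifffile

MODALITIES = ("confocal", "sted", "dsted", "generated", "unknown")
QUALITIES = ("high", "low", "unknown")

__all__ = [
    "MicroImage",
    "PairedSample",
    "ImageDataset",
    "read_image",
    "write_image",
    "normalize_unit",
    "to_net_range",
    "from_net_range",
]


@dataclass
class MicroImage:
    """A single-channel 2-D fluorescence image with metadata.

    Parameters
    ----------
    pixels:
        Rectangular, finite-valued intensity grid (height x width).
    pixel_size_nm:
        Physical pixel pitch, if known.
    modality:
        One of ``confocal``, ``sted``, ``dsted``, ``generated``, ``unknown``.
    quality:
        Acquisition quality class: ``high``, ``low`` or ``unknown``.
    id:
        Identifier, typically derived from the file name.
    """

    pixels: np.ndarray
    pixel_size_nm: Optional[float] = None
    modality: str = "unknown"
    quality: str = "unknown"
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"single-channel required: got array of ndim {self.pixels.ndim}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains NaN or Inf values")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.quality not in QUALITIES:
            raise ValueError(f"unknown quality {self.quality!r}")
        if self.pixel_size_nm is not None and self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, **meta) -> "MicroImage":
        """Return a copy holding new pixel data (metadata carried over)."""
        out = replace(self, pixels=np.asarray(pixels, dtype=np.float64))
        for k, v in meta.items():
            setattr(out, k, v)
        return out


@dataclass
class PairedSample:
    """Co-registered (confocal source, STED/dSTED target) image pair."""

    source: MicroImage
    target: MicroImage
    registered: bool = True
    sample_id: str = ""
    crop_box: Optional[object] = None  # preprocess.CropBox once cropped

    def __post_init__(self) -> None:
        if self.source.shape != self.target.shape:
            raise ValueError(
                f"source/target shape mismatch: {self.source.shape} vs "
                f"{self.target.shape}"
            )


@dataclass
class ImageDataset:
    """Ordered collection of paired samples with an optional fold mapping."""

    samples: List[PairedSample] = field(default_factory=list)
    fold_of: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample_ids must be unique")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, i):
        return self.samples[i]

    def subset(self, ids) -> "ImageDataset":
        ids = set(ids)
        return ImageDataset([s for s in self.samples if s.sample_id in ids])


def read_image(
    path: str,
    modality: str = "unknown",
    quality: str = "unknown",
    pixel_size_nm: Optional[float] = None,
) -> MicroImage:
    """Read a single-channel grayscale TIFF into a :class:`MicroImage`.

    Integer data (8/16-bit) is converted to float without rescaling, so a
    16-bit image with maximum 65535 reads back with maximum 65535.0.
    Multi-channel/RGB files are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and 1 in arr.shape:
        arr = arr.reshape([d for d in arr.shape if d != 1])
    if arr.ndim != 2:
        raise ValueError(f"single-channel required: {path} has shape {arr.shape}")
    arr = arr.astype(np.float64)
    if np.all(np.isnan(arr)):
        raise ValueError(f"all-NaN image: {path}")
    name = os.path.splitext(os.path.basename(path))[0]
    return MicroImage(
        pixels=arr,
        modality=modality,
        quality=quality,
        pixel_size_nm=pixel_size_nm,
        id=name,
    )


def write_image(img: MicroImage, path: str, dtype: str = "float32") -> None:
    """Write a :class:`MicroImage` to TIFF (float32 by default, lossless
    for unit-range data)."""
    arr = img.pixels
    if dtype == "float32":
        arr = arr.astype(np.float32)
    elif dtype == "uint16":
        arr = np.clip(arr, 0, 65535).astype(np.uint16)
    elif dtype == "uint8":
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, arr)


def normalize_unit(
    img: MicroImage, p_lo: float = 0.0, p_hi: float = 100.0
) -> MicroImage:
    """Linearly rescale so that the ``p_lo`` percentile maps to 0 and the
    ``p_hi`` percentile maps to 1, clipping outside values.

    Defaults (0, 100) give a plain min-max normalization.  Constant images
    map to all zeros rather than raising, so degenerate tiles do not break
    batch pipelines.
    """
    if not (0 <= p_lo < p_hi <= 100):
        raise ValueError("require 0 <= p_lo < p_hi <= 100")
    px = img.pixels
    if px.size == 0:
        raise ValueError("empty image")
    lo = np.percentile(px, p_lo)
    hi = np.percentile(px, p_hi)
    if hi <= lo:
        return img.with_pixels(np.zeros_like(px))
    out = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
    return img.with_pixels(out)


_RANGE_TOL = 1e-6


def to_net_range(values: np.ndarray) -> np.ndarray:
    """Affine map [0, 1] -> [-1, 1] (``v -> 2v - 1``)."""
    v = np.asarray(values, dtype=np.float64)
    if v.min() < -_RANGE_TOL or v.max() > 1 + _RANGE_TOL:
        raise ValueError(
            f"input outside [0, 1] (min {v.min():.3g}, max {v.max():.3g})"
        )
    return 2.0 * v - 1.0


def from_net_range(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_net_range`: [-1, 1] -> [0, 1]."""
    v = np.asarray(values, dtype=np.float64)
    if v.min() < -1 - _RANGE_TOL or v.max() > 1 + _RANGE_TOL:
        raise ValueError(
            f"input outside [-1, 1] (min {v.min():.3g}, max {v.max():.3g})"
        )
    return (v + 1.0) / 2.0
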