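"""Reference and non-reference image-quality metrics.

Full-reference metrics (SSIM, PSNR, normalized PSNR, Fourier ring
correlation) score a reconstruction against its co-registered ground
truth; non-reference metrics (Otsu-split SNR, Laplacian edge energy)
characterize a single image and drive the quality-control use case, where
a generator trained on high-quality data acts as an implicit standard and
deviation maps flag degraded acquisitions.

FRC conventions
---------------
``frc`` correlates the two images' Fourier transforms over one-pixel-wide
frequency rings, optionally after Hann apodization (on by default, to
suppress edge leakage on small tiles).  Derived scalars:

* ``frc_resolution`` — the fixed-threshold (1/7) criterion: resolution is
  the inverse of the first frequency where the curve falls below the
  threshold; curves that never cross are Nyquist-limited and report 2 px
  with a flag.
* ``hf_disagreement`` — ``1 - mean(FRC)`` over the upper half of the
  Nyquist band, clipped to [0, 1]: 0 means spectrally indistinguishable
  from the ground truth, larger values mean missing or fabricated
  high-frequency content.

SSIM uses the standard Gaussian-window form (11x11, sigma 1.5,
K1=0.01, K2=0.03) via scikit-image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.metrics import structural_similarity

__all__ = [
    "FRCCurve",
    "FRCResolution",
    "MetricReport",
    "LineProfile",
    "ssim",
    "psnr_db",
    "npsnr",
    "frc",
    "hf_disagreement",
    "frc_resolution",
    "line_profile",
    "pearson",
    "snr_nonref",
    "edge_preservation",
    "deviation_map",
    "metric_report",
]

DEFAULT_PSNR_CAP_DB = 40.0
FRC_THRESHOLD = 1.0 / 7.0


class FRCCurve(NamedTuple):
    ring_freqs: np.ndarray  # cycles/pixel, strictly increasing, <= 0.5
    correlations: np.ndarray
    ring_counts: np.ndarray


class FRCResolution(NamedTuple):
    resolution_px: float
    nyquist_limited: bool


@dataclass
class LineProfile:
    endpoints: Tuple[Tuple[float, float], Tuple[float, float]]
    n_samples: int
    intensities: np.ndarray


@dataclass
class MetricReport:
    """Per-image quality summary of a reconstruction vs its reference."""

    ssim: float
    psnr_db: float
    npsnr: float
    frc_resolution_px: float
    hf_disagreement: float
    pearson_profile: Optional[float] = None


def _as2d(a) -> np.ndarray:
    a = np.asarray(getattr(a, "pixels", a), dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("expected a 2-D image")
    return a


def ssim(a, b, data_range: float = 1.0) -> float:
    """Mean structural similarity (Gaussian window 11x11, sigma 1.5)."""
    a, b = _as2d(a), _as2d(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(
        structural_similarity(
            a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03,
        )
    )


def psnr_db(a, b, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    a, b = _as2d(a), _as2d(b)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def npsnr(psnr_value_db: float, cap_db: float = DEFAULT_PSNR_CAP_DB) -> float:
    """Normalized PSNR in [0, 1]: ``min(PSNR/cap, 1)``; the identity
    comparison (infinite PSNR) maps to 1 by convention."""
    if cap_db <= 0:
        raise ValueError("cap_db must be positive")
    if np.isinf(psnr_value_db):
        return 1.0
    return float(np.clip(psnr_value_db / cap_db, 0.0, 1.0))


def _hann2d(n: int) -> np.ndarray:
    w = np.hanning(n)
    return np.outer(w, w)


def frc(a, b, apodize: bool = True) -> FRCCurve:
    """Fourier ring correlation between two equally sized square images.

    FRC(r) = Re(sum_r F_a conj(F_b)) / sqrt(sum_r |F_a|^2 sum_r |F_b|^2)
    over one-pixel-wide rings; correlations are clipped to [-1, 1] against
    floating-point overshoot.
    """
    a, b = _as2d(a), _as2d(b)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("frc requires two equal square images")
    n = a.shape[0]
    if apodize:
        w = _hann2d(n)
        a, b = a * w, b * w
    fa = np.fft.fftshift(np.fft.fft2(a))
    fb = np.fft.fftshift(np.fft.fft2(b))
    c = n // 2
    yy, xx = np.indices((n, n))
    rad = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    ring = np.round(rad).astype(int)
    n_rings = n // 2  # up to Nyquist
    idx = ring.ravel()
    valid = idx < n_rings
    idx = idx[valid]
    cross = np.bincount(idx, weights=(fa * np.conj(fb)).real.ravel()[valid],
                        minlength=n_rings)
    pa = np.bincount(idx, weights=(np.abs(fa) ** 2).ravel()[valid], minlength=n_rings)
    pb = np.bincount(idx, weights=(np.abs(fb) ** 2).ravel()[valid], minlength=n_rings)
    counts = np.bincount(idx, minlength=n_rings)
    # ring 0 is the DC term; report rings 1..n_rings-1
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cross / np.sqrt(pa * pb)
    corr = np.nan_to_num(corr, nan=0.0)
    freqs = np.arange(n_rings) / n
    keep = slice(1, n_rings)
    return FRCCurve(
        ring_freqs=freqs[keep],
        correlations=np.clip(corr[keep], -1.0, 1.0),
        ring_counts=counts[keep],
    )


def hf_disagreement(curve: FRCCurve, band_lo_frac: float = 0.5) -> float:
    """``1 - mean FRC`` over rings with frequency >= ``band_lo_frac`` x
    Nyquist, clipped to [0, 1].  Zero for identical images."""
    if not 0 < band_lo_frac < 1:
        raise ValueError("band_lo_frac must be in (0, 1)")
    band = curve.ring_freqs >= band_lo_frac * 0.5
    if not band.any():
        raise ValueError("empty high-frequency band")
    return float(np.clip(1.0 - np.mean(curve.correlations[band]), 0.0, 1.0))


def frc_resolution(
    curve: FRCCurve, threshold: float = FRC_THRESHOLD, smooth_window: int = 1
) -> FRCResolution:
    """Fixed-threshold FRC resolution in pixels.

    Finds the first crossing of the (optionally moving-average smoothed)
    curve below ``threshold`` and linearly interpolates the crossing
    frequency; resolution is its inverse.  A curve that never crosses is
    Nyquist-limited: 2 px, flagged.
    """
    corr = np.asarray(curve.correlations, dtype=float)
    freqs = np.asarray(curve.ring_freqs, dtype=float)
    if corr.size < 2:
        raise ValueError("degenerate FRC curve")
    if smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        corr = np.convolve(corr, k, mode="same")
    below = corr < threshold
    if not below.any():
        return FRCResolution(resolution_px=2.0, nyquist_limited=True)
    i = int(np.argmax(below))
    if i == 0:
        return FRCResolution(resolution_px=float(1.0 / freqs[0]), nyquist_limited=False)
    f0, f1 = freqs[i - 1], freqs[i]
    c0, c1 = corr[i - 1], corr[i]
    fstar = f0 + (f1 - f0) * (c0 - threshold) / (c0 - c1)
    return FRCResolution(resolution_px=float(1.0 / fstar), nyquist_limited=False)


def line_profile(img, p0, p1, n_samples: int = 100) -> LineProfile:
    """Bilinear intensity profile along the segment p0 -> p1 (row, col)."""
    px = _as2d(img)
    for p in (p0, p1):
        if not (0 <= p[0] <= px.shape[0] - 1 and 0 <= p[1] <= px.shape[1] - 1):
            raise ValueError(f"endpoint {p} outside image {px.shape}")
    rows = np.linspace(p0[0], p1[0], n_samples)
    cols = np.linspace(p0[1], p1[1], n_samples)
    vals = ndimage.map_coordinates(px, [rows, cols], order=1, mode="nearest")
    return LineProfile(endpoints=(tuple(p0), tuple(p1)), n_samples=n_samples,
                       intensities=vals)


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson correlation of two equal-length sequences (n >= 3)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length sequences of length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(a, b).statistic)


def snr_nonref(img) -> float:
    """Non-reference SNR: Otsu split into foreground/background, then
    ``(mean_fg - mean_bg) / sd_bg``."""
    px = _as2d(img)
    if np.ptp(px) == 0:
        raise ValueError("empty foreground: constant image")
    thr = threshold_otsu(px)
    fg, bg = px[px > thr], px[px <= thr]
    if fg.size == 0:
        raise ValueError("empty foreground")
    sd = bg.std()
    if sd == 0:
        raise ValueError("zero background variance")
    return float((fg.mean() - bg.mean()) / sd)


def edge_preservation(img, method: str = "laplacian") -> float:
    """Sharpness proxy on the image rescaled to [0, 255].

    ``laplacian``: variance of the Laplacian response; ``tenengrad``:
    mean squared Sobel gradient magnitude.  Blurring strictly lowers both.
    """
    px = _as2d(img) * 255.0
    if method == "laplacian":
        return float(ndimage.laplace(px).var())
    if method == "tenengrad":
        gx = ndimage.sobel(px, axis=1)
        gy = ndimage.sobel(px, axis=0)
        return float(np.mean(gx**2 + gy**2))
    raise ValueError(f"unknown method {method!r}")


def deviation_map(generated, observed) -> Tuple[np.ndarray, float]:
    """Pixel-wise |generated - observed| and its mean.

    Against a generator trained on high-quality data, a large score flags
    an acquisition that deviates from the learned imaging standard."""
    g, o = _as2d(generated), _as2d(observed)
    if g.shape != o.shape:
        raise ValueError("shape mismatch")
    m = np.abs(g - o)
    return m, float(m.mean())


def metric_report(candidate, reference,
                  psnr_cap_db: float = DEFAULT_PSNR_CAP_DB) -> MetricReport:
    """Bundle the full-reference metrics of ``candidate`` vs ``reference``."""
    p = psnr_db(candidate, reference)
    curve = frc(candidate, reference)
    return MetricReport(
        ssim=ssim(candidate, reference),
        psnr_db=p,
        npsnr=npsnr(p, psnr_cap_db),
        frc_resolution_px=frc_resolution(curve).resolution_px,
        hf_disagreement=hf_disagreement(curve),
    )
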