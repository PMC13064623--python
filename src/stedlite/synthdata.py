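"""Synthetic confocal/STED/dSTED phantom generator.

Primary cilia imaged with a ciliary-membrane marker appear as thin,
smoothly curved, elongated structures a few pixels wide.  The generator
emulates that morphology with random smooth curvilinear emitter tracks
(spline-interpolated control points rasterized with a Gaussian
cross-section) and renders each emitter map through a simple but physical
forward model:

    image = Poisson(photon_scale * (emitters (*) Gaussian PSF)) / photon_scale
            + Gaussian read noise

The three modalities differ only in PSF width and noise level — dSTED is
the sharpest and cleanest, STED sharp with moderate shot noise, confocal
diffraction-blurred and noisier — so every rendering of one phantom is
perfectly co-registered by construction.  Low-quality variants add
scan-order photobleaching (row-wise exponential attenuation), labeling
gaps and extra read noise.

Because the cross-section of a cilium is narrower than the confocal PSF
but wider than the STED PSF, line profiles across a rendered membrane pair
show two resolved peaks in STED renders and a single broad peak in
confocal renders — the qualitative signature the downstream translation
task must reproduce.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_interp_spline

from ._rng import spawn
from .imagecore import ImageDataset, MicroImage, PairedSample, normalize_unit, read_image, write_image

__all__ = [
    "PhantomConfig",
    "Phantom",
    "generate_emitters",
    "render_modality",
    "degrade_low_quality",
    "generate_phantom",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Knobs of the phantom forward model.

    PSF sigmas are ordered ``sigma_dsted_px < sigma_sted_px <
    sigma_conf_px`` to mimic the resolution ladder dSTED < STED <
    confocal.  ``photon_scale_*`` sets the expected photon count per unit
    emitter intensity (larger = less shot noise); confocal detectors
    integrate more signal, so its scale is highest.
    """

    size_px: int = 128
    n_structures_min: int = 1
    n_structures_max: int = 3
    curve_thickness_px: float = 2.5
    sigma_sted_px: float = 1.0
    sigma_conf_px: float = 4.0
    sigma_dsted_px: float = 0.7
    photon_scale_sted: float = 200.0
    photon_scale_conf: float = 500.0
    photon_scale_dsted: float = 800.0
    read_noise_sd: float = 0.01
    bleach_rate: float = 0.01
    gap_fraction: float = 0.3
    extra_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (self.sigma_dsted_px < self.sigma_sted_px < self.sigma_conf_px):
            raise ValueError(
                "require sigma_dsted_px < sigma_sted_px < sigma_conf_px"
            )
        if self.size_px < 16:
            raise ValueError("size_px too small")
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap_fraction must be in [0, 1)")
        if not 0 <= self.n_structures_min <= self.n_structures_max:
            raise ValueError("invalid n_structures range")


@dataclass
class Phantom:
    """One emitter map plus its co-registered renderings."""

    emitters: np.ndarray
    renderings: Dict[str, MicroImage] = field(default_factory=dict)
    config_echo: Optional[PhantomConfig] = None


def _smooth_track(rng: np.random.Generator, size: int, n_ctrl: int = 5,
                  n_samples: int = 400) -> np.ndarray:
    """One smooth random curve: cubic spline through random control points,
    sampled densely; returns (n_samples, 2) row/col coordinates."""
    margin = 0.12 * size
    ctrl = rng.uniform(margin, size - margin, size=(n_ctrl, 2))
    # order control points along their principal axis so the curve does
    # not fold back on itself pathologically
    c = ctrl - ctrl.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    order = np.argsort(c @ vt[0])
    ctrl = ctrl[order]
    t = np.linspace(0, 1, n_ctrl)
    spline = make_interp_spline(t, ctrl, k=min(3, n_ctrl - 1))
    return spline(np.linspace(0, 1, n_samples))


def generate_emitters(config: PhantomConfig, seed: Optional[int] = None) -> np.ndarray:
    """Rasterize ``n_structures`` smooth curvilinear tracks into a
    nonnegative emitter-density grid.

    Each track is stamped as unit impulses along the curve and blurred
    with a Gaussian of ``curve_thickness_px / 2.355`` sigma (FWHM =
    thickness), giving membranes of the configured apparent width.
    Deterministic given the seed.
    """
    rng = spawn(config.seed if seed is None else seed, 0xE)
    size = config.size_px
    grid = np.zeros((size, size), dtype=np.float64)
    n = int(rng.integers(config.n_structures_min, config.n_structures_max + 1))
    for _ in range(n):
        pts = _smooth_track(rng, size)
        rows = np.clip(np.round(pts[:, 0]).astype(int), 0, size - 1)
        cols = np.clip(np.round(pts[:, 1]).astype(int), 0, size - 1)
        np.add.at(grid, (rows, cols), 1.0)
    if n > 0:
        sigma = config.curve_thickness_px / 2.355  # FWHM -> sigma
        grid = ndimage.gaussian_filter(grid, sigma, mode="constant")
    return grid


def render_modality(
    emitters: np.ndarray,
    psf_sigma_px: float,
    photon_scale: Optional[float],
    read_noise_sd: float = 0.0,
    seed: int = 0,
    modality: str = "unknown",
) -> MicroImage:
    """Blur an emitter map with a normalized Gaussian PSF and apply scaled
    Poisson shot noise plus Gaussian read noise.

    ``photon_scale=None`` (or ``inf``) disables shot noise, giving the
    noiseless expectation; reflective boundary handling avoids dark frame
    artifacts on small tiles.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    if photon_scale is not None and not np.isinf(photon_scale) and photon_scale <= 0:
        raise ValueError("photon_scale must be positive")
    blurred = ndimage.gaussian_filter(np.asarray(emitters, float), psf_sigma_px,
                                      mode="reflect")
    rng = spawn(seed, 0x5)
    if photon_scale is None or np.isinf(photon_scale):
        img = blurred
    else:
        img = rng.poisson(np.clip(blurred, 0, None) * photon_scale) / photon_scale
    if read_noise_sd > 0:
        img = img + rng.normal(0.0, read_noise_sd, size=img.shape)
    return MicroImage(pixels=img, modality=modality, quality="high")


def degrade_low_quality(
    img: MicroImage,
    bleach_rate: float = 0.01,
    gap_fraction: float = 0.3,
    extra_noise_sd: float = 0.05,
    seed: int = 0,
) -> MicroImage:
    """Emulate sub-optimal acquisition: scan-order photobleaching, masked
    labeling gaps, extra Gaussian noise.  Expects a unit-range image.

    Bleaching multiplies row ``r`` by ``exp(-bleach_rate * r)`` (the slow
    scan axis loses signal as the acquisition proceeds).  Gaps zero a
    random fraction of the bright (above-median) support, mimicking
    patches of failed labeling.
    """
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must be in [0, 1)")
    rng = spawn(seed, 0xD)
    px = img.pixels.copy()
    rows = np.arange(px.shape[0], dtype=float)
    px *= np.exp(-bleach_rate * rows)[:, None]
    if gap_fraction > 0:
        support = px > np.median(px)
        n_blobs = max(1, int(round(6 * gap_fraction)))
        mask = np.ones_like(px)
        coords = np.argwhere(support)
        if len(coords):
            centers = coords[rng.integers(0, len(coords), size=n_blobs)]
            rr, cc = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
            radius = 0.08 * px.shape[0] * (0.5 + gap_fraction)
            for r0, c0 in centers:
                mask[(rr - r0) ** 2 + (cc - c0) ** 2 < radius**2] = 0.0
        px *= mask
    if extra_noise_sd > 0:
        px = px + rng.normal(0.0, extra_noise_sd, size=px.shape)
    return img.with_pixels(px, quality="low")


_MODALITY_STREAM = {"confocal": 11, "sted": 22, "dsted": 33}

_MODALITY_PARAMS = {
    "confocal": ("sigma_conf_px", "photon_scale_conf"),
    "sted": ("sigma_sted_px", "photon_scale_sted"),
    "dsted": ("sigma_dsted_px", "photon_scale_dsted"),
}


def generate_phantom(
    config: PhantomConfig,
    seed: Optional[int] = None,
    modalities: Tuple[str, ...] = ("confocal", "sted", "dsted"),
    include_low_quality: bool = False,
    noiseless: bool = False,
) -> Phantom:
    """Generate one emitter map and its renderings, all unit-normalized.

    Every rendering shares one emitter map and one tile size, so the pair
    set is born co-registered.
    """
    seed = config.seed if seed is None else seed
    emitters = generate_emitters(config, seed=seed)
    phantom = Phantom(emitters=emitters, config_echo=config)
    for m in modalities:
        sig_name, scale_name = _MODALITY_PARAMS[m]
        img = render_modality(
            emitters,
            getattr(config, sig_name),
            None if noiseless else getattr(config, scale_name),
            0.0 if noiseless else config.read_noise_sd,
            seed=seed + _MODALITY_STREAM[m],
            modality=m,
        )
        phantom.renderings[m] = normalize_unit(img)
    if include_low_quality:
        for m in modalities:
            if m == "confocal":
                continue
            lq = degrade_low_quality(
                phantom.renderings[m],
                bleach_rate=config.bleach_rate,
                gap_fraction=config.gap_fraction,
                extra_noise_sd=config.extra_noise_sd,
                seed=seed,
            )
            phantom.renderings[f"{m}_low"] = lq
    return phantom


def generate_dataset(
    n_samples: int,
    config: Optional[PhantomConfig] = None,
    target_modality: str = "sted",
) -> ImageDataset:
    """Generate ``n_samples`` co-registered (confocal, target) pairs.

    Per-sample seeds derive reproducibly from ``config.seed``; a fixed
    master seed reproduces the dataset bit-for-bit.
    """
    if n_samples < 1:
        raise ValueError("n_samples >= 1 required")
    config = config or PhantomConfig()
    if target_modality not in ("sted", "dsted"):
        raise ValueError("target_modality must be 'sted' or 'dsted'")
    samples = []
    for i in range(n_samples):
        sub = int(spawn(config.seed, 0xDA, i).integers(0, 2**31 - 1))
        ph = generate_phantom(config, seed=sub, modalities=("confocal", target_modality))
        sid = f"sample_{i:04d}"
        src = ph.renderings["confocal"]
        tgt = ph.renderings[target_modality]
        src.id, tgt.id = f"{sid}_confocal", f"{sid}_{target_modality}"
        samples.append(PairedSample(source=src, target=tgt, registered=True,
                                    sample_id=sid))
    return ImageDataset(samples=samples)


def write_dataset(dataset: ImageDataset, outdir: str,
                  config: Optional[PhantomConfig] = None) -> str:
    """Write pairs as float32 TIFFs plus a JSON manifest; returns the
    manifest path."""
    os.makedirs(outdir, exist_ok=True)
    entries = []
    for s in dataset:
        for role, img in (("source", s.source), ("target", s.target)):
            fn = f"{s.sample_id}_{role}_{img.modality}.tif"
            write_image(img, os.path.join(outdir, fn))
            entries.append({"sample_id": s.sample_id, "role": role,
                            "modality": img.modality, "file": fn})
    manifest = {
        "n_samples": len(dataset),
        "entries": entries,
        "config": asdict(config) if config else None,
    }
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def load_dataset(indir: str) -> ImageDataset:
    """Inverse of :func:`write_dataset`."""
    with open(os.path.join(indir, "manifest.json")) as fh:
        manifest = json.load(fh)
    by_id: Dict[str, Dict[str, MicroImage]] = {}
    for e in manifest["entries"]:
        img = read_image(os.path.join(indir, e["file"]), modality=e["modality"])
        by_id.setdefault(e["sample_id"], {})[e["role"]] = img
    samples = [
        PairedSample(source=v["source"], target=v["target"], sample_id=k)
        for k, v in sorted(by_id.items())
    ]
    return ImageDataset(samples=samples)
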