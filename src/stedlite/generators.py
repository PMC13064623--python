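"""The nine-generator ladder: declarative specs, builders, parameter counts.

Two channel policies span the ladder.  The *doubling* policy is the
conventional U-Net design — widths double at every downsampling, capped at
``cap_multiplier x base_width`` — instantiated at base widths 64, 32, 16,
8 and 4 (Models 1-4 and 6; Model 1 bottlenecks at 512 channels with 41.8 M
trainable weights).  The *fixed* policy keeps one constant width at every
level (Models 5, 7, 8, 9 at widths 64, 32, 16, 8), which collapses the
parameter count into the tens of thousands while preserving the
encoder-decoder-skip topology.

The exact depth/kernel/skip configuration of the fixed family is frozen by
:func:`calibrate_fixed_family`, an exhaustive search over depth in {3..7},
kernel in {3, 4} and skip mode in {concat, add} scored against the
published per-width parameter counts; the winning triple (depth 4, kernel
4, concatenated skips) is what :data:`MODEL_REGISTRY` ships.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import _rng
from .imagecore import MicroImage, from_net_range, to_net_range
from .nn import UNet

__all__ = [
    "GeneratorSpec",
    "MODEL_REGISTRY",
    "registry_spec",
    "build_generator",
    "count_trainable",
    "translate",
    "calibrate_fixed_family",
    "TABLE_PARAMS_M",
]

# Published per-model generator parameter counts, in millions.
TABLE_PARAMS_M: Dict[int, float] = {
    1: 41.8, 2: 10.45, 3: 2.61, 4: 0.65, 5: 0.53,
    6: 0.16, 7: 0.13, 8: 0.035, 9: 0.009,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Full architectural description of one U-Net generator variant."""

    policy: str  # "doubling" | "fixed"
    base_width: int
    depth: int
    kernel_size: int = 4
    cap_multiplier: int = 8
    norm: str = "instance"
    dropout_p: float = 0.0
    skip_mode: str = "concat"
    final_activation: str = "tanh"

    def __post_init__(self):
        if self.policy not in ("doubling", "fixed"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.base_width < 1 or self.depth < 2:
            raise ValueError("base_width >= 1 and depth >= 2 required")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")

    @property
    def widths(self) -> List[int]:
        if self.policy == "doubling":
            cap = self.cap_multiplier * self.base_width
            return [min(self.base_width * 2**i, cap) for i in range(self.depth)]
        return [self.base_width] * self.depth

    @property
    def bottleneck_width(self) -> int:
        return self.widths[-1]

    def param_count(self, in_ch: int = 1, out_ch: int = 1) -> int:
        """Closed-form trainable-weight count (bias-free convolutions,
        non-affine norms: weights live only in conv kernels)."""
        k2 = self.kernel_size**2
        c = [in_ch] + self.widths
        d = self.depth
        total = sum(k2 * c[i] * c[i + 1] for i in range(d))  # encoder
        mult = 2 if self.skip_mode == "concat" else 1
        total += k2 * c[d] * c[d - 1]  # innermost up
        for i in range(1, d - 1):
            total += k2 * (mult * c[i + 1]) * c[i]
        total += k2 * (mult * c[1]) * out_ch  # outermost up
        return int(total)


def _doubling(base: int, dropout_p: float = 0.5) -> GeneratorSpec:
    # 7 resolution levels: 128-px inputs reach a 1x1 bottleneck.
    return GeneratorSpec(
        policy="doubling", base_width=base, depth=7, kernel_size=4,
        cap_multiplier=8, dropout_p=dropout_p,
    )


def _fixed(width: int) -> GeneratorSpec:
    # depth/kernel/skip frozen by calibrate_fixed_family()
    return GeneratorSpec(
        policy="fixed", base_width=width, depth=4, kernel_size=4,
        dropout_p=0.0, skip_mode="concat",
    )


#: Model index -> spec.  Indices follow the ladder: complexity decreases as
#: the index grows; doubling models are 1-4 and 6, fixed models 5 and 7-9.
MODEL_REGISTRY: Dict[int, GeneratorSpec] = {
    1: _doubling(64),
    2: _doubling(32),
    3: _doubling(16),
    4: _doubling(8),
    5: _fixed(64),
    6: _doubling(4),
    7: _fixed(32),
    8: _fixed(16),
    9: _fixed(8),
}


def registry_spec(model_index: int) -> GeneratorSpec:
    """Return the frozen spec for model 1..9."""
    if model_index not in MODEL_REGISTRY:
        raise KeyError(f"model_index must be in 1..9, got {model_index}")
    return MODEL_REGISTRY[model_index]


def build_generator(
    spec: GeneratorSpec,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> UNet:
    """Instantiate the network described by ``spec``.

    Initialization is N(0, 0.02) drawn from ``rng`` (or a generator derived
    from ``seed``, or the package RNG) — two builds from the same seed are
    bit-identical.
    """
    if rng is None and seed is not None:
        rng = np.random.default_rng(seed)
    return UNet(
        widths=spec.widths,
        kernel=spec.kernel_size,
        skip_mode=spec.skip_mode,
        dropout_p=spec.dropout_p,
        rng=rng,
    )


def count_trainable(net) -> int:
    """Exact number of trainable scalars in a built network."""
    return int(net.count_trainable())


def translate(net: UNet, img: MicroImage) -> MicroImage:
    """Apply a generator to one unit-range image; returns the translated
    image back in [0, 1] with modality tagged ``generated``."""
    x = to_net_range(img.pixels).astype(np.float32)
    if x.shape[0] % (2**net.depth) or x.shape[1] % (2**net.depth):
        raise ValueError(f"input size {x.shape} incompatible with depth {net.depth}")
    y, _ = net.forward(x[None, None], train=False)
    out = from_net_range(np.clip(y[0, 0], -1.0, 1.0))
    return img.with_pixels(out, modality="generated")


def calibrate_fixed_family(
    targets_m: Optional[Dict[int, float]] = None,
    depths: Tuple[int, ...] = (3, 4, 5, 6, 7),
    kernels: Tuple[int, ...] = (3, 4),
    skips: Tuple[str, ...] = ("concat", "add"),
) -> Tuple[Tuple[int, int, str], "pd.DataFrame"]:
    """Exhaustive search for the fixed-family (depth, kernel, skip) triple.

    Scores each candidate by how many of the published fixed-family counts
    (widths 64/32/16/8 -> 0.53/0.13/0.035/0.009 M) it reproduces at printed
    precision, breaking ties by total absolute error in millions.  Returns
    the winning triple and the full scoring table.
    """
    import pandas as pd

    if targets_m is None:
        targets_m = {64: 0.53, 32: 0.13, 16: 0.035, 8: 0.009}
    rows = []
    for d, k, sk in itertools.product(depths, kernels, skips):
        row = {"depth": d, "kernel": k, "skip": sk, "matches": 0, "abs_err_m": 0.0}
        for w, tgt in targets_m.items():
            spec = GeneratorSpec("fixed", w, depth=d, kernel_size=k, skip_mode=sk)
            m = spec.param_count() / 1e6
            ndec = max(2, len(str(tgt).split(".")[1]))
            row[f"w{w}_m"] = m
            row["matches"] += int(round(m, ndec) == tgt)
            row["abs_err_m"] += abs(m - tgt)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["matches", "abs_err_m"], ascending=[False, True]
    ).reset_index(drop=True)
    best = table.iloc[0]
    return (int(best["depth"]), int(best["kernel"]), str(best["skip"])), table
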