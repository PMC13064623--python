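"""U-Net generator with encoder/decoder mirror and skip connections.

The network is parameterized by the per-level channel widths, so one class
covers both channel policies used in the model ladder: the conventional
doubling design (widths ``min(base * 2**i, cap * base)``) and the
lightweight fixed-channel design (every level at the same width).

Block layout follows the standard image-translation U-Net:

* encoder level 0: plain stride-2 convolution (no activation in front);
* encoder levels 1..d-2: LeakyReLU(0.2) -> stride-2 conv -> instance norm;
* encoder level d-1 (bottleneck): LeakyReLU -> stride-2 conv;
* decoder innermost: ReLU -> transposed conv -> instance norm;
* decoder middle levels: ReLU -> transposed conv (input = concat of skip
  and the deeper decoder output) -> instance norm [-> dropout];
* decoder outermost: ReLU -> transposed conv -> tanh.

All convolutions are bias-free and the instance norms carry no affine
parameters; trainable weights therefore live exclusively in the
convolution kernels.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from . import layers as layers_mod
from .layers import (
    Conv2d,
    ConvTranspose2d,
    Dropout,
    InstanceNorm2d,
    LeakyReLU,
    Param,
    ReLU,
    Tanh,
)


class UNet:
    """Encoder-decoder generator producing tanh-range images.

    Parameters
    ----------
    widths:
        Channel width of each resolution level, shallow to deep; its length
        is the number of stride-2 downsamplings.
    kernel:
        Convolution kernel size (stride fixed at 2, padding ``k//2 - 1`` so
        the spatial size halves/doubles exactly).
    skip_mode:
        ``"concat"`` (channel concatenation, the U-Net default) or
        ``"add"`` (element-wise sum, halving decoder input widths).
    dropout_p:
        Dropout probability on the deep middle decoder levels (those at the
        width cap); applied in training mode only.
    """

    def __init__(
        self,
        widths: Sequence[int],
        in_ch: int = 1,
        out_ch: int = 1,
        kernel: int = 4,
        skip_mode: str = "concat",
        dropout_p: float = 0.0,
        dropout_levels: Optional[Sequence[int]] = None,
        rng: Optional[np.random.Generator] = None,
    ):
        if skip_mode not in ("concat", "add"):
            raise ValueError("skip_mode must be 'concat' or 'add'")
        if kernel % 2 != 0 and kernel != 3:
            raise ValueError("kernel must be 3 or even")
        self.widths = list(widths)
        self.depth = len(self.widths)
        if self.depth < 2:
            raise ValueError("need at least 2 resolution levels")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel = kernel
        # stride-2 'same' geometry: even kernels use pad k//2-1, k=3 uses pad 1
        self.pad = kernel // 2 - 1 if kernel % 2 == 0 else 1
        self.skip_mode = skip_mode
        d = self.depth
        c = [in_ch] + self.widths  # c[i] = channels entering level i

        def conv(i, o):
            return Conv2d(i, o, kernel, stride=2, pad=self.pad, bias=False, rng=rng)

        def convT(i, o):
            return ConvTranspose2d(i, o, kernel, stride=2, pad=self.pad, bias=False, rng=rng)

        self.down_convs = [conv(c[i], c[i + 1]) for i in range(d)]
        self.down_norms = [
            InstanceNorm2d() if 0 < i < d - 1 else None for i in range(d)
        ]
        mult = 2 if skip_mode == "concat" else 1
        self.up_convs: List[ConvTranspose2d] = []
        for i in reversed(range(d)):  # deepest first
            cin = c[i + 1] if i == d - 1 else mult * c[i + 1]
            cout = out_ch if i == 0 else c[i]
            self.up_convs.append(convT(cin, cout))
        self.up_norms = [InstanceNorm2d() if i > 0 else None for i in reversed(range(d))]
        if dropout_levels is None:
            # deep middle levels at the width cap (conventional placement)
            cap = max(self.widths)
            dropout_levels = [
                i for i in range(1, d - 1) if self.widths[i] == cap
            ] if dropout_p > 0 else []
        self.dropouts = {
            i: Dropout(dropout_p, rng=rng) for i in dropout_levels if dropout_p > 0
        }
        self.lrelu = LeakyReLU(0.2)
        self.relu = ReLU()
        self.tanh = Tanh()

    # -- parameters -----------------------------------------------------
    def params(self) -> List[Param]:
        out: List[Param] = []
        for l in self.down_convs + self.up_convs:
            out.extend(l.params())
        return out

    def count_trainable(self) -> int:
        return int(sum(p.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    def state_dict(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.data[...] = state[f"p{i}"]

    # -- forward/backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False):
        """Run the network; returns ``(output, tape)``.

        ``tape`` is self-contained, so the network may be applied several
        times before any backward call.
        """
        x = np.asarray(x, dtype=layers_mod.DTYPE)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[2] % (2**self.depth) or x.shape[3] % (2**self.depth):
            raise ValueError(
                f"input size {x.shape[2:]} not divisible by 2^{self.depth}"
            )
        tape = {"enc": [], "dec": [], "shape": x.shape}
        skips = []
        h = x
        d = self.depth
        for i in range(d):
            entry = {}
            if i > 0:
                h, entry["act"] = self.lrelu.forward(h)
            h, entry["conv"] = self.down_convs[i].forward(h)
            if self.down_norms[i] is not None:
                h, entry["norm"] = self.down_norms[i].forward(h)
            tape["enc"].append(entry)
            skips.append(h)
        for j, level in enumerate(reversed(range(d))):  # j=0 is deepest
            entry = {"level": level}
            if level < d - 1:
                skip = skips[level]
                if self.skip_mode == "concat":
                    entry["split"] = skip.shape[1]
                    h = np.concatenate([skip, h], axis=1)
                else:
                    h = skip + h
            h, entry["act"] = self.relu.forward(h)
            h, entry["conv"] = self.up_convs[j].forward(h)
            if self.up_norms[j] is not None:
                h, entry["norm"] = self.up_norms[j].forward(h)
            if level in self.dropouts:
                h, entry["drop"] = self.dropouts[level].forward(h, train=train)
            tape["dec"].append(entry)
        out, tape["tanh"] = self.tanh.forward(h)
        return out, tape

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)

    def backward(self, tape, grad_out: np.ndarray) -> np.ndarray:
        """Backpropagate ``grad_out`` through the tape; accumulates parameter
        gradients and returns the gradient w.r.t. the input."""
        g = self.tanh.backward(tape["tanh"], np.asarray(grad_out, dtype=layers_mod.DTYPE))
        d = self.depth
        skip_grads = [None] * d
        for j, entry in zip(reversed(range(d)), reversed(tape["dec"])):
            level = entry["level"]
            if "drop" in entry:
                g = self.dropouts[level].backward(entry["drop"], g)
            if "norm" in entry:
                g = self.up_norms[j].backward(entry["norm"], g)
            g = self.up_convs[j].backward(entry["conv"], g)
            g = self.relu.backward(entry["act"], g)
            if level < d - 1:
                if self.skip_mode == "concat":
                    s = entry["split"]
                    skip_grads[level] = g[:, :s]
                    g = g[:, s:]
                else:
                    skip_grads[level] = g
        for i, entry in zip(reversed(range(d)), reversed(tape["enc"])):
            if skip_grads[i] is not None and i < d - 1:
                g = g + skip_grads[i]
            if "norm" in entry:
                g = self.down_norms[i].backward(entry["norm"], g)
            g = self.down_convs[i].backward(entry["conv"], g)
            if "act" in entry:
                g = self.lrelu.backward(entry["act"], g)
        return g
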