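"""PatchGAN discriminator.

A fully convolutional classifier that outputs a 2-D grid of real/fake
scores, each judging one overlapping receptive-field patch of the input
(the classic 70x70-patch design at default widths 64-128-256-512).  The
conditional variant (Pix2Pix) receives the source and candidate target
concatenated on the channel axis; the unconditional variant (CycleGAN)
sees the candidate alone.  Outputs are raw logits: the adversarial losses
decide whether to squash them (BCE) or regress them (least squares).
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from . import layers as layers_mod
from .layers import Conv2d, InstanceNorm2d, LeakyReLU, Param


class PatchGAN:
    def __init__(
        self,
        widths: Sequence[int] = (64, 128, 256, 512),
        in_ch: int = 1,
        kernel: int = 4,
        rng: Optional[np.random.Generator] = None,
    ):
        self.widths = list(widths)
        self.in_ch = in_ch
        pad = 1
        layers = []
        prev = in_ch
        for i, w in enumerate(self.widths):
            stride = 2 if i < len(self.widths) - 1 else 1
            layers.append(
                Conv2d(prev, w, kernel, stride=stride, pad=pad, bias=(i == 0), rng=rng)
            )
            layers.append(None if i == 0 else InstanceNorm2d())
            prev = w
        self.convs = layers[::2]
        self.norms = layers[1::2]
        self.final = Conv2d(prev, 1, kernel, stride=1, pad=pad, bias=True, rng=rng)
        self.lrelu = LeakyReLU(0.2)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for c in self.convs:
            out.extend(c.params())
        out.extend(self.final.params())
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

    def forward(self, x: np.ndarray, train: bool = False):
        x = np.asarray(x, dtype=layers_mod.DTYPE)
        if x.ndim == 3:
            x = x[:, None]
        tape = []
        h = x
        for conv, norm in zip(self.convs, self.norms):
            entry = {}
            h, entry["conv"] = conv.forward(h)
            if norm is not None:
                h, entry["norm"] = norm.forward(h)
            h, entry["act"] = self.lrelu.forward(h)
            tape.append(entry)
        h, final_cache = self.final.forward(h)
        tape.append({"conv": final_cache})
        return h, tape

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)

    def backward(self, tape, grad_out: np.ndarray) -> np.ndarray:
        g = self.final.backward(tape[-1]["conv"], np.asarray(grad_out, layers_mod.DTYPE))
        for conv, norm, entry in zip(
            reversed(self.convs), reversed(self.norms), reversed(tape[:-1])
        ):
            g = self.lrelu.backward(entry["act"], g)
            if norm is not None:
                g = norm.backward(entry["norm"], g)
            g = conv.backward(entry["conv"], g)
        return g
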