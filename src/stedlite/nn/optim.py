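"""Adam optimizer with the linear learning-rate decay used for GAN training."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from .layers import Param


class Adam:
    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 2e-4,
        betas: Tuple[float, float] = (0.5, 0.999),
        eps: float = 1e-8,
    ):
        self.params: List[Param] = list(params)
        self.lr = self.base_lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def set_epoch(self, epoch: int, total_epochs: int, decay_start: int) -> None:
        """Linear decay of the learning rate to 0 between ``decay_start``
        and ``total_epochs`` (constant before)."""
        if epoch < decay_start or total_epochs <= decay_start:
            self.lr = self.base_lr
        else:
            frac = (total_epochs - epoch) / (total_epochs - decay_start)
            self.lr = self.base_lr * max(frac, 0.0)

    def state_dict(self) -> dict:
        out = {"t": self.t, "lr": self.lr}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m{i}"], out[f"v{i}"] = m.copy(), v.copy()
        return out
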