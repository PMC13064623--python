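"""Minimal reverse-mode neural-network layers on NumPy.

The package trains small U-Net generators and PatchGAN discriminators on
CPU; this module provides exactly the layers those architectures need:
strided convolution, strided transposed convolution, non-affine instance
normalization, LeakyReLU/ReLU/Tanh, and dropout.  Convolutions are lowered
to BLAS matrix products via an im2col gather (a loop over the k*k kernel
offsets, vectorized over batch and space), which keeps a full forward +
backward pass for the desk-scale networks in the tens of milliseconds.

Design: layers are stateless with respect to activations.  ``forward``
returns ``(output, cache)`` and ``backward(cache, grad_out)`` returns the
input gradient while accumulating parameter gradients into ``Param.grad``.
This lets one network be applied several times inside a single objective
(as CycleGAN requires: translation, cycle reconstruction and identity all
reuse the same generator) with independent tapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

DTYPE = np.float32


@dataclass
class Param:
    """One trainable tensor and its accumulated gradient."""

    data: np.ndarray
    name: str = ""
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base class: parameter-free identity."""

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False):
        return x, None

    def backward(self, cache, grad_out: np.ndarray) -> np.ndarray:
        return grad_out


def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _im2col(x: np.ndarray, k: int, s: int, p: int):
    """Gather k*k patches: (N,C,H,W) -> (C*k*k, N*Ho*Wo) plus geometry."""
    n, c, h, w = x.shape
    xp = _pad2d(x, p)
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    cols = np.empty((c, k, k, n, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s].transpose(
                1, 0, 2, 3
            )
    return cols.reshape(c * k * k, n * ho * wo), (n, c, h, w, ho, wo)


def _col2im(cols: np.ndarray, geom, k: int, s: int, p: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    n, c, h, w, ho, wo = geom
    cols = cols.reshape(c, k, k, n, ho, wo)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + s * ho : s, j : j + s * wo : s] += cols[
                :, i, j
            ].transpose(1, 0, 2, 3)
    if p == 0:
        return xp
    return xp[:, :, p:-p, p:-p]


class Conv2d(Layer):
    """2-D convolution, zero padding, optional bias.

    Weights are initialized N(0, 0.02) as is conventional for GAN training;
    the generators in this package use ``bias=False`` throughout.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 1,
        bias: bool = False,
        rng: Optional[np.random.Generator] = None,
        init_std: float = 0.02,
    ):
        rng = _default_rng(rng)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, pad
        w = rng.normal(0.0, init_std, size=(out_ch, in_ch * kernel * kernel))
        self.weight = Param(w, name=f"conv{in_ch}x{out_ch}k{kernel}.w")
        self.bias = Param(np.zeros(out_ch), name="b") if bias else None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train: bool = False):
        cols, geom = _im2col(x, self.k, self.s, self.p)
        out = self.weight.data @ cols  # (out_ch, N*Ho*Wo)
        n, _, _, _, ho, wo = geom
        if self.bias is not None:
            out += self.bias.data[:, None]
        out = out.reshape(self.out_ch, n, ho, wo).transpose(1, 0, 2, 3)
        return np.ascontiguousarray(out), (cols, geom)

    def backward(self, cache, grad_out):
        cols, geom = cache
        n, c, h, w, ho, wo = geom
        g = grad_out.transpose(1, 0, 2, 3).reshape(self.out_ch, n * ho * wo)
        self.weight.grad += g @ cols.T
        if self.bias is not None:
            self.bias.grad += g.sum(axis=1)
        dcols = self.weight.data.T @ g
        return _col2im(dcols, geom, self.k, self.s, self.p)


class ConvTranspose2d(Layer):
    """2-D transposed (fractionally strided) convolution.

    Forward is the data-gradient of :class:`Conv2d`; with ``kernel=4,
    stride=2, pad=1`` it exactly doubles the spatial size, mirroring the
    encoder's stride-2 downsampling.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 2,
        pad: int = 1,
        bias: bool = False,
        rng: Optional[np.random.Generator] = None,
        init_std: float = 0.02,
    ):
        rng = _default_rng(rng)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, pad
        w = rng.normal(0.0, init_std, size=(in_ch, out_ch * kernel * kernel))
        self.weight = Param(w, name=f"convT{in_ch}x{out_ch}k{kernel}.w")
        self.bias = Param(np.zeros(out_ch), name="b") if bias else None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def out_size(self, h: int) -> int:
        return self.s * (h - 1) + self.k - 2 * self.p

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        ho, wo = self.out_size(h), self.out_size(w)
        xm = x.transpose(1, 0, 2, 3).reshape(self.in_ch, n * h * w)
        cols = self.weight.data.T @ xm  # (out_ch*k*k, N*H*W)
        geom = (n, self.out_ch, ho, wo, h, w)
        out = _col2im(cols, geom, self.k, self.s, self.p)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        return out, (xm, (n, h, w, ho, wo))

    def backward(self, cache, grad_out):
        xm, (n, h, w, ho, wo) = cache
        gcols, _ = _im2col(grad_out, self.k, self.s, self.p)
        # gcols: (out_ch*k*k, N*H*W) — same patch grid as the forward scatter
        self.weight.grad += xm @ gcols.T
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=(0, 2, 3))
        dxm = self.weight.data @ gcols
        return np.ascontiguousarray(
            dxm.reshape(self.in_ch, n, h, w).transpose(1, 0, 2, 3)
        )


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over space (no affine terms).

    Matching the parameter-count convention of the generator registry the
    normalization carries no learnable scale/shift.
    """

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x, train: bool = False):
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        y = xc * inv
        return y, (y, inv, x.shape[2] * x.shape[3])

    def backward(self, cache, grad_out):
        y, inv, m = cache
        gmean = grad_out.mean(axis=(2, 3), keepdims=True)
        gymean = (grad_out * y).mean(axis=(2, 3), keepdims=True)
        return inv * (grad_out - gmean - y * gymean)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train: bool = False):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, cache, grad_out):
        return np.where(cache, grad_out, self.slope * grad_out)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x, train: bool = False):
        y = np.tanh(x)
        return y, y

    def backward(self, cache, grad_out):
        return grad_out * (1.0 - cache * cache)


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False or p == 0."""

    def __init__(self, p: float = 0.5, rng: Optional[np.random.Generator] = None):
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.p == 0:
            return x, None
        rng = _default_rng(self.rng)
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        mask = mask.astype(x.dtype)
        return x * mask, mask

    def backward(self, cache, grad_out):
        if cache is None:
            return grad_out
        return grad_out * cache


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out: List[Param] = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, train: bool = False):
        caches = []
        for l in self.layers:
            x, c = l.forward(x, train=train)
            caches.append(c)
        return x, caches

    def backward(self, caches, grad_out):
        for l, c in zip(reversed(self.layers), reversed(caches)):
            grad_out = l.backward(c, grad_out)
        return grad_out


def _default_rng(rng: Optional[np.random.Generator]) -> np.random.Generator:
    if rng is not None:
        return rng
    from .. import _rng

    return _rng.get_rng()
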