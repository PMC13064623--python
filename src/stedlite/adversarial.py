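"""Adversarial objectives and training loops for Pix2Pix and CycleGAN.

Pix2Pix (paired) minimizes an adversarial term plus a weighted L1
reconstruction term:

    L_pix2pix(G, D) = L_GAN(G, D) + lambda * L_L1(G)

CycleGAN (unpaired) couples two generator/discriminator pairs with
cycle-consistency and identity penalties:

    L_cyclegan = L_GAN(G, D_Y) + L_GAN(F, D_X)
                 + lambda_cyc * [ |F(G(x)) - x|_1 + |G(F(y)) - y|_1 ]
                 + lambda_id  * [ |G(y) - y|_1 + |F(x) - x|_1 ]

Nothing in the CycleGAN path consults the pairing: the y-collection may
be shuffled or come from entirely different fields of view.

Both loops follow the standard GAN recipe — alternating discriminator and
generator Adam updates (lr 2e-4, betas 0.5/0.999), linear learning-rate
decay to zero after a configurable epoch, per-iteration dihedral
augmentation, checkpoints every ``checkpoint_every`` epochs — and are
fully deterministic given the config seed on a fixed machine.  The
default adversarial mode is the non-saturating binary cross-entropy for
Pix2Pix and least-squares (LSGAN) for CycleGAN.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _rng
from .imagecore import ImageDataset, to_net_range
from .generators import GeneratorSpec, build_generator
from .metrics import ssim
from .nn import Adam, PatchGAN, UNet
from .preprocess import dihedral

__all__ = [
    "DiscriminatorSpec",
    "LossWeights",
    "TrainConfig",
    "TrainHistory",
    "ImagePool",
    "seed_all",
    "l1_loss",
    "adversarial_loss",
    "pix2pix_objective",
    "cycle_loss",
    "identity_loss",
    "cyclegan_objective",
    "train_pix2pix",
    "train_cyclegan",
]


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class DiscriminatorSpec:
    """PatchGAN configuration; ``conditional`` concatenates source and
    candidate target on the channel axis (Pix2Pix)."""

    widths: Tuple[int, ...] = (64, 128, 256, 512)
    kernel_size: int = 4
    norm: str = "instance"
    conditional: bool = False


@dataclass(frozen=True)
class LossWeights:
    lambda_l1: float = 100.0   # Pix2Pix reconstruction weight
    lambda_cyc: float = 10.0   # cycle-consistency weight
    lambda_id: float = 5.0     # identity weight

    def __post_init__(self):
        for v in (self.lambda_l1, self.lambda_cyc, self.lambda_id):
            if not np.isfinite(v) or v < 0:
                raise ValueError("loss weights must be finite and >= 0")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    checkpoint_every: int = 5
    learning_rate: float = 2e-4
    adam_betas: Tuple[float, float] = (0.5, 0.999)
    batch_size: int = 4
    seed: int = 0
    gan_mode: Optional[str] = None  # None -> bce for pix2pix, lsgan for cyclegan
    lr_decay_start: int = 100
    augment: bool = True
    pool_size: int = 50

    def __post_init__(self):
        if self.epochs < 1 or self.checkpoint_every < 1 or self.batch_size < 1:
            raise ValueError("epochs, checkpoint_every, batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainHistory:
    """Per-epoch loss records (one row per epoch, all entries finite)."""

    records: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str) -> None:
        self.records.to_csv(path, index=False)


def seed_all(seed: int) -> None:
    """Reset every random source the package uses (weight init, dropout,
    augmentation, image pool, phantom fallbacks) to a fresh state derived
    from ``seed``."""
    _rng.set_seed(seed)


class ImagePool:
    """Buffer of historical generator outputs for discriminator updates.

    With probability 1/2 a query image is swapped against a stored one,
    decorrelating discriminator updates from the current generator state.
    """

    def __init__(self, size: int = 50, rng: Optional[np.random.Generator] = None):
        self.size = size
        self.rng = rng if rng is not None else _rng.get_rng()
        self.images: List[np.ndarray] = []

    def query(self, batch: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return batch
        out = []
        for img in batch:
            if len(self.images) < self.size:
                self.images.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                i = int(self.rng.integers(0, self.size))
                out.append(self.images[i].copy())
                self.images[i] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


# --------------------------------------------------------------------------
# loss operations (forward values; training uses the *_grad helpers)
# --------------------------------------------------------------------------
def l1_loss(generated: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute difference."""
    g, t = np.asarray(generated, float), np.asarray(target, float)
    if g.shape != t.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.abs(g - t)))


def adversarial_loss(
    disc_scores_real: np.ndarray, disc_scores_fake: np.ndarray, mode: str = "bce"
) -> Tuple[float, float]:
    """Patch-averaged adversarial losses ``(loss_D, loss_G)``.

    ``bce`` expects probabilities in (0, 1): the discriminator minimizes
    the negated log-likelihood of the real/fake labels and the generator
    the non-saturating ``-log D(fake)``.  ``lsgan`` expects raw scores and
    regresses them to the 1/0 labels.
    """
    r = np.asarray(disc_scores_real, float)
    f = np.asarray(disc_scores_fake, float)
    if r.shape != f.shape:
        raise ValueError("score map shape mismatch")
    if mode == "bce":
        eps = 1e-12
        loss_d = float(-(np.mean(np.log(r + eps)) + np.mean(np.log(1 - f + eps))))
        loss_g = float(-np.mean(np.log(f + eps)))
        return loss_d, loss_g
    if mode == "lsgan":
        loss_d = float(0.5 * (np.mean((r - 1) ** 2) + np.mean(f**2)))
        loss_g = float(np.mean((f - 1) ** 2))
        return loss_d, loss_g
    raise ValueError(f"invalid mode {mode!r}")


def _batch(arr_like) -> np.ndarray:
    a = np.asarray(arr_like, dtype=np.float32)
    if a.ndim == 2:
        a = a[None]
    if a.ndim == 3:
        a = a[:, None]
    return a


def pix2pix_objective(G: UNet, D: PatchGAN, batch, weights: LossWeights) -> Dict[str, float]:
    """Evaluate the paired objective on one (x, y) batch; returns the
    component breakdown and the weighted total."""
    x, y = (_batch(b) for b in batch)
    if x.shape != y.shape:
        raise ValueError("unpaired batch: source/target shapes differ")
    fake, _ = G.forward(x)
    logits_fake, _ = D.forward(np.concatenate([x, fake], axis=1))
    logits_real, _ = D.forward(np.concatenate([x, y], axis=1))
    probs = 1.0 / (1.0 + np.exp(-logits_real)), 1.0 / (1.0 + np.exp(-logits_fake))
    _, adv_g = adversarial_loss(*probs, mode="bce")
    l1 = l1_loss(fake, y)
    return {
        "adversarial_g": adv_g,
        "l1": l1,
        "total": adv_g + weights.lambda_l1 * l1,
    }


def cycle_loss(G: UNet, F: UNet, batch_x, batch_y) -> float:
    """Two-sided reconstruction error |F(G(x))-x| + |G(F(y))-y|."""
    x, y = _batch(batch_x), _batch(batch_y)
    gx, _ = G.forward(x)
    rec_x, _ = F.forward(gx)
    fy, _ = F.forward(y)
    rec_y, _ = G.forward(fy)
    return l1_loss(rec_x, x) + l1_loss(rec_y, y)


def identity_loss(G: UNet, F: UNet, batch_x, batch_y) -> float:
    """|G(y)-y| + |F(x)-x|: generators applied to their own target domain."""
    x, y = _batch(batch_x), _batch(batch_y)
    gy, _ = G.forward(y)
    fx, _ = F.forward(x)
    return l1_loss(gy, y) + l1_loss(fx, x)


def cyclegan_objective(
    G: UNet, F: UNet, D_X: PatchGAN, D_Y: PatchGAN, batches,
    weights: LossWeights,
) -> Dict[str, float]:
    """Evaluate the unpaired objective on (batch_x, batch_y); no pairing
    assumption anywhere in this path."""
    batch_x, batch_y = batches
    x, y = _batch(batch_x), _batch(batch_y)
    fake_y, _ = G.forward(x)
    fake_x, _ = F.forward(y)
    sy, _ = D_Y.forward(fake_y)
    sx, _ = D_X.forward(fake_x)
    adv_g = float(np.mean((sy - 1) ** 2))
    adv_f = float(np.mean((sx - 1) ** 2))
    cyc = cycle_loss(G, F, x, y)
    idt = identity_loss(G, F, x, y)
    return {
        "adversarial_g": adv_g,
        "adversarial_f": adv_f,
        "cycle": cyc,
        "identity": idt,
        "total": adv_g + adv_f + weights.lambda_cyc * cyc + weights.lambda_id * idt,
    }


# --------------------------------------------------------------------------
# gradient helpers
# --------------------------------------------------------------------------
def _l1_grad(pred: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff).astype(np.float32) / diff.size


def _gan_grad(logits: np.ndarray, label: float, mode: str) -> Tuple[float, np.ndarray]:
    """Loss and d(loss)/d(logits) for one score map vs a constant label."""
    if mode == "bce":
        p = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        loss = float(-np.mean(label * np.log(p + eps) + (1 - label) * np.log(1 - p + eps)))
        grad = (p - label).astype(np.float32) / logits.size
        return loss, grad
    if mode == "lsgan":
        diff = logits - label
        return float(np.mean(diff**2)), (2.0 * diff).astype(np.float32) / logits.size
    raise ValueError(f"invalid mode {mode!r}")


def _check_finite(value: float, what: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite {what} at epoch {epoch}: {value}")


def _dataset_arrays(dataset) -> Tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for s in dataset:
        xs.append(to_net_range(s.source.pixels))
        ys.append(to_net_range(s.target.pixels))
    return (np.asarray(xs, np.float32)[:, None],
            np.asarray(ys, np.float32)[:, None])


def _checkpoint_epochs(epochs: int, every: int) -> List[int]:
    eps = [e for e in range(every, epochs + 1, every)]
    if not eps or eps[-1] != epochs:
        eps.append(epochs)
    return eps


def _save_checkpoint(directory, epoch, nets: Dict[str, object], config) -> object:
    state = {name: net.state_dict() for name, net in nets.items()}
    if directory is None:
        return {"epoch": epoch, "state": state}
    os.makedirs(directory, exist_ok=True)
    path = os.path.join(directory, f"checkpoint_epoch{epoch:04d}.npz")
    flat = {f"{n}/{k}": v for n, st in state.items() for k, v in st.items()}
    np.savez(path, **flat)
    with open(os.path.join(directory, "config.json"), "w") as fh:
        json.dump(asdict(config), fh, indent=1, default=str)
    return path


def _val_ssim(G: UNet, val_pairs) -> float:
    scores = []
    for s in val_pairs:
        x = to_net_range(s.source.pixels).astype(np.float32)
        out, _ = G.forward(x[None, None])
        scores.append(ssim((out[0, 0] + 1) / 2, s.target.pixels))
    return float(np.mean(scores))


# --------------------------------------------------------------------------
# training loops
# --------------------------------------------------------------------------
def train_pix2pix(
    dataset: ImageDataset,
    gen_spec: GeneratorSpec,
    disc_spec: Optional[DiscriminatorSpec] = None,
    config: Optional[TrainConfig] = None,
    weights: Optional[LossWeights] = None,
    val_pairs: Optional[Sequence] = None,
    checkpoint_dir: Optional[str] = None,
):
    """Train a paired translator; returns ``(G, history, checkpoints)``.

    The discriminator is conditional: it scores the (source, candidate)
    concatenation.  Alternates one discriminator and one generator Adam
    update per batch.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    config = config or TrainConfig()
    weights = weights or LossWeights()
    disc_spec = disc_spec or DiscriminatorSpec(conditional=True)
    mode = config.gan_mode or "bce"
    X, Y = _dataset_arrays(dataset)
    rng = _rng.spawn(config.seed, 0x91)
    G = build_generator(gen_spec, rng=_rng.spawn(config.seed, 0x92))
    D = PatchGAN(widths=disc_spec.widths, in_ch=2, kernel=disc_spec.kernel_size,
                 rng=_rng.spawn(config.seed, 0x93))
    opt_g = Adam(G.params(), lr=config.learning_rate, betas=config.adam_betas)
    opt_d = Adam(D.params(), lr=config.learning_rate, betas=config.adam_betas)
    n = len(dataset)
    records, checkpoints = [], []
    ckpt_epochs = set(_checkpoint_epochs(config.epochs, config.checkpoint_every))
    for epoch in range(1, config.epochs + 1):
        opt_g.set_epoch(epoch - 1, config.epochs, config.lr_decay_start)
        opt_d.set_epoch(epoch - 1, config.epochs, config.lr_decay_start)
        order = rng.permutation(n)
        ep = {"loss_d": 0.0, "loss_g_adv": 0.0, "loss_l1": 0.0}
        n_batches = 0
        for i0 in range(0, n, config.batch_size):
            idx = order[i0 : i0 + config.batch_size]
            xb, yb = X[idx].copy(), Y[idx].copy()
            if config.augment:
                for j in range(len(idx)):
                    el = int(rng.integers(0, 8))
                    xb[j, 0] = dihedral(xb[j, 0], el)
                    yb[j, 0] = dihedral(yb[j, 0], el)
            fake, tape_g = G.forward(xb, train=True)
            # --- discriminator update
            D.zero_grad()
            lr_logits, t_real = D.forward(np.concatenate([xb, yb], axis=1))
            ld_r, gr = _gan_grad(lr_logits, 1.0, mode)
            D.backward(t_real, 0.5 * gr)
            lf_logits, t_fake = D.forward(np.concatenate([xb, fake], axis=1))
            ld_f, gf = _gan_grad(lf_logits, 0.0, mode)
            D.backward(t_fake, 0.5 * gf)
            opt_d.step()
            # --- generator update
            G.zero_grad()
            D.zero_grad()
            logits, t_d = D.forward(np.concatenate([xb, fake], axis=1))
            lg_adv, gl = _gan_grad(logits, 1.0, mode)
            dinput = D.backward(t_d, gl)
            dfake = dinput[:, 1:2]
            l1_val, dl1 = _l1_grad(fake, yb)
            G.backward(tape_g, dfake + weights.lambda_l1 * dl1)
            opt_g.step()
            D.zero_grad()
            loss_d = 0.5 * (ld_r + ld_f)
            _check_finite(loss_d + lg_adv + l1_val, "loss", epoch)
            ep["loss_d"] += loss_d
            ep["loss_g_adv"] += lg_adv
            ep["loss_l1"] += l1_val
            n_batches += 1
        rec = {"epoch": epoch, **{k: v / n_batches for k, v in ep.items()}}
        if val_pairs is not None:
            rec["val_ssim"] = _val_ssim(G, val_pairs)
        records.append(rec)
        if epoch in ckpt_epochs:
            checkpoints.append(_save_checkpoint(checkpoint_dir, epoch, {"G": G}, config))
    return G, TrainHistory(pd.DataFrame(records)), checkpoints


def train_cyclegan(
    dataset_x,
    dataset_y,
    gen_spec: GeneratorSpec,
    disc_spec: Optional[DiscriminatorSpec] = None,
    config: Optional[TrainConfig] = None,
    weights: Optional[LossWeights] = None,
    val_pairs: Optional[Sequence] = None,
    checkpoint_dir: Optional[str] = None,
):
    """Train the unpaired two-generator system; returns
    ``(G, F, D_X, D_Y, history, checkpoints)``.

    ``dataset_x`` and ``dataset_y`` are independent image collections
    (2-D arrays or MicroImages in unit range); no pairing is assumed or
    consulted.  G maps X->Y, F maps Y->X.
    """
    xs = [to_net_range(getattr(s, "pixels", s)) for s in dataset_x]
    ys = [to_net_range(getattr(s, "pixels", s)) for s in dataset_y]
    if not xs or not ys:
        raise ValueError("empty dataset")
    X = np.asarray(xs, np.float32)[:, None]
    Y = np.asarray(ys, np.float32)[:, None]
    config = config or TrainConfig()
    weights = weights or LossWeights()
    disc_spec = disc_spec or DiscriminatorSpec(conditional=False)
    mode = config.gan_mode or "lsgan"
    rng = _rng.spawn(config.seed, 0xC1)
    G = build_generator(gen_spec, rng=_rng.spawn(config.seed, 0xC2))
    F = build_generator(gen_spec, rng=_rng.spawn(config.seed, 0xC3))
    D_X = PatchGAN(widths=disc_spec.widths, in_ch=1, kernel=disc_spec.kernel_size,
                   rng=_rng.spawn(config.seed, 0xC4))
    D_Y = PatchGAN(widths=disc_spec.widths, in_ch=1, kernel=disc_spec.kernel_size,
                   rng=_rng.spawn(config.seed, 0xC5))
    opts = {
        "G": Adam(G.params(), config.learning_rate, config.adam_betas),
        "F": Adam(F.params(), config.learning_rate, config.adam_betas),
        "D_X": Adam(D_X.params(), config.learning_rate, config.adam_betas),
        "D_Y": Adam(D_Y.params(), config.learning_rate, config.adam_betas),
    }
    pool_x = ImagePool(config.pool_size, rng=_rng.spawn(config.seed, 0xC6))
    pool_y = ImagePool(config.pool_size, rng=_rng.spawn(config.seed, 0xC7))
    nx, ny = len(X), len(Y)
    n_iter = max(nx, ny) // config.batch_size or 1
    records, checkpoints = [], []
    ckpt_epochs = set(_checkpoint_epochs(config.epochs, config.checkpoint_every))
    for epoch in range(1, config.epochs + 1):
        for o in opts.values():
            o.set_epoch(epoch - 1, config.epochs, config.lr_decay_start)
        perm_x, perm_y = rng.permutation(nx), rng.permutation(ny)
        ep = {"loss_g_adv": 0.0, "loss_f_adv": 0.0, "loss_cycle": 0.0,
              "loss_identity": 0.0, "loss_d": 0.0}
        for it in range(n_iter):
            bx = perm_x[(it * config.batch_size) % nx :][: config.batch_size]
            by = perm_y[(it * config.batch_size) % ny :][: config.batch_size]
            if len(bx) < config.batch_size:
                bx = perm_x[: config.batch_size]
            if len(by) < config.batch_size:
                by = perm_y[: config.batch_size]
            xb, yb = X[bx].copy(), Y[by].copy()
            if config.augment:
                for j in range(len(xb)):
                    xb[j, 0] = dihedral(xb[j, 0], int(rng.integers(0, 8)))
                for j in range(len(yb)):
                    yb[j, 0] = dihedral(yb[j, 0], int(rng.integers(0, 8)))
            # ---- generator update (G and F jointly)
            G.zero_grad(); F.zero_grad(); D_X.zero_grad(); D_Y.zero_grad()
            fake_y, tG1 = G.forward(xb, train=True)
            fake_x, tF1 = F.forward(yb, train=True)
            rec_x, tF2 = F.forward(fake_y, train=True)
            rec_y, tG2 = G.forward(fake_x, train=True)
            # adversarial terms
            sy, tDY = D_Y.forward(fake_y)
            ladv_g, gy = _gan_grad(sy, 1.0, mode)
            d_fake_y = D_Y.backward(tDY, gy)
            sx, tDX = D_X.forward(fake_x)
            ladv_f, gx = _gan_grad(sx, 1.0, mode)
            d_fake_x = D_X.backward(tDX, gx)
            # cycle terms
            lcyc_x, d_rec_x = _l1_grad(rec_x, xb)
            d_fake_y = d_fake_y + weights.lambda_cyc * F.backward(tF2, d_rec_x)
            lcyc_y, d_rec_y = _l1_grad(rec_y, yb)
            d_fake_x = d_fake_x + weights.lambda_cyc * G.backward(tG2, d_rec_y)
            # identity terms
            lid = 0.0
            if weights.lambda_id > 0:
                idt_y, tG3 = G.forward(yb, train=True)
                lid_y, d_idt_y = _l1_grad(idt_y, yb)
                G.backward(tG3, weights.lambda_id * d_idt_y)
                idt_x, tF3 = F.forward(xb, train=True)
                lid_x, d_idt_x = _l1_grad(idt_x, xb)
                F.backward(tF3, weights.lambda_id * d_idt_x)
                lid = lid_y + lid_x
            G.backward(tG1, d_fake_y)
            F.backward(tF1, d_fake_x)
            opts["G"].step(); opts["F"].step()
            D_X.zero_grad(); D_Y.zero_grad()
            # ---- discriminator updates (pooled fakes)
            ld = 0.0
            for D, opt, real, fake, pool in (
                (D_Y, opts["D_Y"], yb, fake_y, pool_y),
                (D_X, opts["D_X"], xb, fake_x, pool_x),
            ):
                D.zero_grad()
                s_real, t_r = D.forward(real)
                l_r, g_r = _gan_grad(s_real, 1.0, mode)
                D.backward(t_r, 0.5 * g_r)
                pooled = pool.query(fake)
                s_fake, t_f = D.forward(pooled)
                l_f, g_f = _gan_grad(s_fake, 0.0, mode)
                D.backward(t_f, 0.5 * g_f)
                opt.step()
                ld += 0.5 * (l_r + l_f)
            lcyc = lcyc_x + lcyc_y
            _check_finite(ladv_g + ladv_f + lcyc + lid + ld, "loss", epoch)
            ep["loss_g_adv"] += ladv_g
            ep["loss_f_adv"] += ladv_f
            ep["loss_cycle"] += lcyc
            ep["loss_identity"] += lid
            ep["loss_d"] += ld
        rec = {"epoch": epoch, **{k: v / n_iter for k, v in ep.items()}}
        if val_pairs is not None:
            rec["val_ssim"] = _val_ssim(G, val_pairs)
        records.append(rec)
        if epoch in ckpt_epochs:
            checkpoints.append(
                _save_checkpoint(checkpoint_dir, epoch,
                                 {"G": G, "F": F, "D_X": D_X, "D_Y": D_Y}, config)
            )
    return G, F, D_X, D_Y, TrainHistory(pd.DataFrame(records)), checkpoints
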