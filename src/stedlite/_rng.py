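"""Package-global random state.

All stochastic components (weight initialization, dropout, augmentation
sampling, the CycleGAN image pool) draw from explicit generators; when no
generator is passed they fall back to the package RNG managed here, which
:func:`stedlite.adversarial.seed_all` resets between experiments.
"""

from __future__ import annotations

import numpy as np

_GLOBAL_RNG: np.random.Generator = np.random.default_rng(0)


def get_rng() -> np.random.Generator:
    return _GLOBAL_RNG


def set_seed(seed: int) -> None:
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)
    np.random.seed(seed % (2**32))  # legacy consumers (e.g. sklearn shuffles)


def spawn(seed: int, *stream: int) -> np.random.Generator:
    """Derive an independent generator from ``seed`` and a stream key."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))
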