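"""Shared fixtures.

The CycleGAN desk-scale run (Model 9, 64 synthetic pairs, 30 epochs) is
expensive, so it is trained once per session and shared between the
training-behavior tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from stedlite.adversarial import TrainConfig, seed_all, train_cyclegan
from stedlite.generators import registry_spec
from stedlite.synthdata import PhantomConfig, generate_dataset

SMOKE_TILE_PX = 64  # desk-scale tile size for training smoke runs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def phantom_dataset():
    """Small co-registered confocal/STED dataset (shared, read-only)."""
    return generate_dataset(8, PhantomConfig(size_px=64, seed=7))


@pytest.fixture(scope="session")
def cyclegan_smoke():
    """Model-9 CycleGAN trained unpaired on 64 synthetic pairs, 30 epochs.

    The target collection is shuffled before training, so the run also
    demonstrates that the unpaired path never consults the pairing.
    Returns (G, F, history, held_out_pairs).
    """
    train = generate_dataset(64, PhantomConfig(size_px=SMOKE_TILE_PX, seed=11))
    held = generate_dataset(16, PhantomConfig(size_px=SMOKE_TILE_PX, seed=977))
    seed_all(123)
    xs = [s.source for s in train]
    ys = [s.target for s in train]
    np.random.default_rng(5).shuffle(ys)  # unpaired by construction
    G, F, _, _, history, _ = train_cyclegan(
        xs, ys, registry_spec(9),
        config=TrainConfig(epochs=30, batch_size=4, seed=123),
    )
    return G, F, history, list(held)
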