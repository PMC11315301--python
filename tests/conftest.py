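"""Shared fixtures.

The expensive fixtures (trained GAN, ensemble, encoder) are session-scoped:
they are trained once at 32×32 desk scale and shared by the reconstruction,
inversion and end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctanomaly import (
    EncoderLossConfig,
    GanTrainConfig,
    PhantomSpec,
    generate_phantom,
    train_encoder,
    train_gan,
)

RESOLUTION = 32
LATENT_DIM = 512


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    return PhantomSpec(resolution=RESOLUTION, seed=7)


@pytest.fixture(scope="session")
def train_ds(phantom_spec):
    """64 normal phantom slices at 32×32 — the desk-scale training set."""
    return generate_phantom(phantom_spec, 64)


def _gan_config(seed: int) -> GanTrainConfig:
    return GanTrainConfig(resolution=RESOLUTION, latent_dim=LATENT_DIM,
                          base_channels_g=32, base_channels_d=16,
                          total_steps=2000, seed=seed)


@pytest.fixture(scope="session")
def tiny_gan(train_ds):
    """One generator trained 2000 steps on the phantom training set."""
    gen, _, log = train_gan(train_ds, _gan_config(0))
    assert all(np.isfinite(row["loss_d"]) and np.isfinite(row["loss_g"])
               for row in log)
    return gen


@pytest.fixture(scope="session")
def gan_ensemble(train_ds, tiny_gan):
    """Three generators trained with the same settings, different seeds."""
    gens = [tiny_gan]
    for seed in (1, 2):
        gen, _, _ = train_gan(train_ds, _gan_config(seed))
        gens.append(gen)
    return gens


@pytest.fixture(scope="session")
def tiny_encoder(train_ds, tiny_gan):
    """Encoder trained against the frozen tiny generator."""
    cfg = EncoderLossConfig(steps=500, seed=0)
    enc, log = train_encoder(train_ds, tiny_gan, cfg)
    return enc
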