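"""Encoder training: map images into the generator's latent box.

The encoder E is a stack of down-sampling blocks — 2-D convolution, batch
normalization and a gated linear unit per block, ``log2(N) − 1`` blocks so a
512×512 input passes through eight of them — followed by a dense head with a
terminal tanh, which keeps every output component inside the latent box
[−1, 1] (the support of the generator's uniform prior).

E is trained against a frozen generator by minimizing

    L_E = E_x [ w1·ℓ_percept(x, G(E(x))) + w2·ℓ_MSE(x, G(E(x))) ],
    w1 = 1, w2 = 10,

with random-erase augmentation of the encoder *input* (probability 0.25; the
un-erased image stays the reconstruction target) so E cannot collapse to the
identity shortcut.

The perceptual term is pluggable.  The default backend, ``randconv``, is a
fixed-seed stack of random convolution filters whose LPIPS-style distance
(unit-normalize features across channels, average squared differences, sum
over layers) is fully self-contained; additional feature extractors can be
registered via :func:`register_perceptual_backend`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .gan import Generator
from .imaging_io import ImageGrid, SliceDataset

_DTYPE = np.float32


# ---------------------------------------------------------------------------
# perceptual distance


class RandConvFeatures(nn.Module):
    """Frozen random-filter feature pyramid (three strided conv layers)."""

    LAYER_CHANNELS = (8, 16, 32)

    def __init__(self, seed: int = 12345):
        rng = np.random.default_rng(seed)
        chans = (1,) + self.LAYER_CHANNELS
        self.convs = [
            nn.Conv2d(chans[i], chans[i + 1], 3, stride=2, padding=1, rng=rng)
            for i in range(len(self.LAYER_CHANNELS))
        ]
        self.set_trainable(False)
        self.eval()

    def features(self, x: nn.Tensor) -> list[nn.Tensor]:
        feats = []
        for conv in self.convs:
            x = conv(x).leaky_relu(0.2)
            feats.append(x)
        return feats


_BACKENDS: dict[str, type] = {"randconv": RandConvFeatures}
_BACKEND_CACHE: dict[str, object] = {}


def register_perceptual_backend(name: str, factory) -> None:
    """Register a feature-extractor class under ``name``.

    The factory must be callable with no arguments and expose
    ``features(Tensor) -> list[Tensor]``.
    """
    _BACKENDS[name] = factory


def get_perceptual_backend(name: str):
    if name not in _BACKENDS:
        raise KeyError(f"unknown perceptual backend {name!r}; "
                       f"registered: {sorted(_BACKENDS)}")
    if name not in _BACKEND_CACHE:
        _BACKEND_CACHE[name] = _BACKENDS[name]()
    return _BACKEND_CACHE[name]


def _channel_normalize(f: nn.Tensor) -> nn.Tensor:
    norm = (f.pow(2.0).sum(axis=1, keepdims=True)
            + nn.Tensor(np.float32(1e-8))).pow(-0.5)
    return f * norm


def perceptual_tensor(a: nn.Tensor, b: nn.Tensor, backend) -> nn.Tensor:
    """Differentiable perceptual distance between (B,1,H,W) tensors."""
    fa = backend.features(a)
    fb = backend.features(b)
    total = None
    for xa, xb in zip(fa, fb):
        d = (_channel_normalize(xa) - _channel_normalize(xb)).pow(2.0).mean()
        total = d if total is None else total + d
    return total


def _as_batch(x) -> np.ndarray:
    arr = x.pixels if isinstance(x, ImageGrid) else np.asarray(x, dtype=_DTYPE)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    return arr.astype(_DTYPE)


def perceptual_distance(a, b, backend: str = "randconv") -> float:
    """Symmetric, non-negative perceptual distance; 0 for identical images."""
    xa, xb = _as_batch(a), _as_batch(b)
    if xa.shape != xb.shape:
        raise ValueError(f"shape mismatch {xa.shape} vs {xb.shape}")
    be = get_perceptual_backend(backend)
    return float(perceptual_tensor(nn.Tensor(xa), nn.Tensor(xb), be).data)


# ---------------------------------------------------------------------------
# encoder network


class EncoderNet(nn.Module):
    """Down-sampling conv/batch-norm/GLU stack ending in a tanh latent head."""

    def __init__(self, resolution: int = 32, latent_dim: int = 512,
                 base_channels: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.resolution = resolution
        self.latent_dim = latent_dim
        self.base_channels = base_channels
        n_blocks = int(np.log2(resolution)) - 1     # N → 2
        chans = [1]
        for j in range(n_blocks):
            chans.append(min(base_channels * 2 ** j, 128))
        self.convs = [
            nn.Conv2d(chans[j], 2 * chans[j + 1], 4, stride=2, padding=1,
                      rng=rng)
            for j in range(n_blocks)
        ]
        self.bns = [nn.BatchNorm2d(2 * chans[j + 1]) for j in range(n_blocks)]
        self.glu = nn.GLU()
        self.head = nn.Dense(chans[-1] * 4, latent_dim, rng=rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for conv, bn in zip(self.convs, self.bns):
            x = self.glu(bn(conv(x)))
        b = x.data.shape[0]
        return self.head(x.reshape(b, -1)).tanh()

    def encode(self, x) -> np.ndarray:
        """Inference: image(s) → latent vector(s) in [−1, 1]^L."""
        z = self(nn.Tensor(_as_batch(x))).data
        return z


# ---------------------------------------------------------------------------
# loss, augmentation, training


@dataclass
class EncoderLossConfig:
    w1: float = 1.0
    w2: float = 10.0
    backend: str = "randconv"
    erase_probability: float = 0.25
    erase_frac_range: tuple[float, float] = (0.10, 0.35)
    erase_value: float = 0.0
    steps: int = 20_000
    batch_size: int = 8
    learning_rate: float = 2e-4
    base_channels: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("loss weights must be >= 0")
        if not 0.0 <= self.erase_probability <= 1.0:
            raise ValueError("erase_probability must be in [0, 1]")


def objective_tensor(x: nn.Tensor, xhat: nn.Tensor, w1: float, w2: float,
                     backend) -> nn.Tensor:
    """Differentiable w1·ℓ_percept + w2·ℓ_MSE (shared by encoder training and
    latent restoration)."""
    percept = perceptual_tensor(x, xhat, backend)
    mse = (x - xhat).pow(2.0).mean()
    return (nn.Tensor(np.float32(w1)) * percept
            + nn.Tensor(np.float32(w2)) * mse)


def encoder_loss(x, xhat, cfg: EncoderLossConfig | None = None) -> float:
    """w1·ℓ_percept(x, x̂) + w2·ℓ_MSE(x, x̂) on unit-scale images."""
    cfg = cfg or EncoderLossConfig()
    xa, xb = _as_batch(x), _as_batch(xhat)
    if xa.shape != xb.shape:
        raise ValueError(f"shape mismatch {xa.shape} vs {xb.shape}")
    be = get_perceptual_backend(cfg.backend)
    return float(objective_tensor(nn.Tensor(xa), nn.Tensor(xb),
                                  cfg.w1, cfg.w2, be).data)


def random_erase(img: ImageGrid | np.ndarray, cfg: EncoderLossConfig,
                 rng: np.random.Generator) -> ImageGrid | np.ndarray:
    """With probability ``erase_probability``, set one random axis-aligned
    rectangle to the background value; otherwise return the image unchanged."""
    is_grid = isinstance(img, ImageGrid)
    x = (img.pixels if is_grid else np.asarray(img, dtype=_DTYPE)).copy()
    if rng.random() < cfg.erase_probability:
        h, w = x.shape
        eh = max(1, int(round(rng.uniform(*cfg.erase_frac_range) * w)))
        ew = max(1, int(round(rng.uniform(*cfg.erase_frac_range) * w)))
        eh, ew = min(eh, h), min(ew, w)
        top = int(rng.integers(0, h - eh + 1))
        left = int(rng.integers(0, w - ew + 1))
        x[top:top + eh, left:left + ew] = cfg.erase_value
    return ImageGrid(x, scale="unit") if is_grid else x


def train_encoder(dataset: SliceDataset, gen: Generator,
                  cfg: EncoderLossConfig) -> tuple[EncoderNet, list[dict]]:
    """Train E against the frozen generator; G's parameters never change."""
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    stack = dataset.pixel_stack().astype(_DTYPE)
    if stack.shape[1] != gen.resolution:
        raise ValueError(
            f"dataset resolution {stack.shape[1]} != generator "
            f"{gen.resolution}")
    ss = np.random.SeedSequence(cfg.seed)
    init_rng, data_rng, erase_rng = [np.random.default_rng(s)
                                     for s in ss.spawn(3)]
    enc = EncoderNet(gen.resolution, gen.latent_dim, cfg.base_channels,
                     rng=init_rng)
    enc.train()
    gen.eval()
    gen.set_trainable(False)
    backend = get_perceptual_backend(cfg.backend)
    opt = nn.Adam(enc.parameters(), lr=cfg.learning_rate, betas=(0.5, 0.999))
    log: list[dict] = []
    try:
        for step in range(1, cfg.steps + 1):
            idx = data_rng.integers(0, len(stack), size=cfg.batch_size)
            target = stack[idx][:, None]
            erased = np.stack([random_erase(stack[i], cfg, erase_rng)
                               for i in idx])[:, None]
            z = enc(nn.Tensor(erased))
            xhat = gen(z)
            loss = objective_tensor(nn.Tensor(target), xhat, cfg.w1, cfg.w2,
                                    backend)
            enc.zero_grad()
            loss.backward()
            opt.step()
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise RuntimeError(f"non-finite encoder loss at step {step}")
            log.append({"step": step, "loss": lv})
    finally:
        gen.set_trainable(True)
    enc.eval()
    return enc, log
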