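"""GAN core: generator/discriminator, hinge losses, augmentation, training.

The generator follows the lightweight few-shot GAN recipe: a dense projection
of the latent code to a 4×4 feature map, then ``log2(N) − 2`` upsampling
blocks (nearest-neighbour upsample → 3×3 conv → optional noise injection →
batch norm → GLU), with skip-layer excitation gates between low- and
high-resolution blocks when the pyramid is deep enough, and a terminal tanh
squashed affinely into [0, 1].  The discriminator is a spectral-normalized
strided-conv stack producing one logit per image plus, for real inputs, a
small decoded reconstruction of an 8×-downsampled copy of the input — the
self-supervised feature-learning head whose mean-absolute-error enters the
discriminator loss.

Adversarial objectives are the hinge pair

    L_G = −E[D(G(z))]
    L_D = E[max(0, 1 − D(x))] + E[max(0, 1 + D(G(z)))] + L_rec

with the latent prior z ~ U[−1, 1]^L.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .imaging_io import ImageGrid, SliceDataset

_DTYPE = np.float32


# ---------------------------------------------------------------------------
# latent sampling and loss functions


def sample_latent(n: int, latent_dim: int,
                  rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw ``n`` latent vectors with i.i.d. components uniform on [−1, 1]."""
    if n < 1 or latent_dim < 1:
        raise ValueError("n and latent_dim must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.uniform(-1.0, 1.0, size=(n, latent_dim)).astype(_DTYPE)


def generator_loss(fake_logits: np.ndarray) -> float:
    """Hinge-GAN generator loss: −mean(D(G(z)))."""
    fake_logits = np.asarray(fake_logits, dtype=np.float64)
    if fake_logits.size == 0:
        raise ValueError("empty logit vector")
    return float(-fake_logits.mean())


def discriminator_loss(real_logits: np.ndarray, fake_logits: np.ndarray,
                       rec_loss: float = 0.0) -> float:
    """Hinge discriminator loss plus the auxiliary reconstruction term."""
    real_logits = np.asarray(real_logits, dtype=np.float64)
    fake_logits = np.asarray(fake_logits, dtype=np.float64)
    if real_logits.size == 0 or fake_logits.size == 0:
        raise ValueError("empty logit vector")
    if rec_loss < 0:
        raise ValueError("rec_loss must be >= 0")
    return float(np.maximum(0.0, 1.0 - real_logits).mean()
                 + np.maximum(0.0, 1.0 + fake_logits).mean() + rec_loss)


def reconstruction_loss(real_down: np.ndarray, decoded: np.ndarray) -> float:
    """Mean absolute error between the decoded head output and the
    downsampled real image."""
    real_down = np.asarray(real_down, dtype=np.float64)
    decoded = np.asarray(decoded, dtype=np.float64)
    if real_down.shape != decoded.shape:
        raise ValueError(f"shape mismatch {real_down.shape} vs {decoded.shape}")
    return float(np.abs(real_down - decoded).mean())


# ---------------------------------------------------------------------------
# augmentation


@dataclass
class AugmentConfig:
    """Random mirroring, contrast changes and translation (probabilities and
    magnitudes are configurable; the contrast scale acts about the image
    mean, translation is zero-padded)."""

    mirror_p: float = 0.5
    contrast_p: float = 1.0
    contrast_range: tuple[float, float] = (0.8, 1.25)
    translate_p: float = 1.0
    max_translate_frac: float = 0.05


def augment(img: ImageGrid | np.ndarray, settings: AugmentConfig,
            rng: np.random.Generator) -> ImageGrid | np.ndarray:
    """Apply the training-time augmentations; output stays unit-scale."""
    is_grid = isinstance(img, ImageGrid)
    x = (img.pixels if is_grid else np.asarray(img)).astype(np.float64)
    if rng.random() < settings.mirror_p:
        x = x[:, ::-1]
    if rng.random() < settings.contrast_p:
        scale = rng.uniform(*settings.contrast_range)
        mu = x.mean()
        x = mu + scale * (x - mu)
    if rng.random() < settings.translate_p:
        limit = int(round(settings.max_translate_frac * x.shape[1]))
        if limit > 0:
            dy = int(rng.integers(-limit, limit + 1))
            dx = int(rng.integers(-limit, limit + 1))
            shifted = np.zeros_like(x)
            h, w = x.shape
            ys, yd = (max(0, -dy), max(0, dy))
            xs, xd = (max(0, -dx), max(0, dx))
            hh, ww = h - abs(dy), w - abs(dx)
            shifted[yd:yd + hh, xd:xd + ww] = x[ys:ys + hh, xs:xs + ww]
            x = shifted
    x = np.clip(x, 0.0, 1.0)
    return ImageGrid(x, scale="unit") if is_grid else x.astype(_DTYPE)


# ---------------------------------------------------------------------------
# networks


class _UpBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, noise: bool,
                 rng: np.random.Generator):
        self.up = nn.Upsample2x()
        self.conv = nn.Conv2d(c_in, 2 * c_out, 3, padding=1, rng=rng)
        self.noise = nn.NoiseInjection(2 * c_out, rng=rng) if noise else None
        self.bn = nn.BatchNorm2d(2 * c_out)
        self.glu = nn.GLU()

    def __call__(self, x):
        x = self.conv(self.up(x))
        if self.noise is not None:
            x = self.noise(x)
        return self.glu(self.bn(x))


class _SkipLayerExcitation(nn.Module):
    """Channel gate computed from a low-resolution feature map and applied
    multiplicatively to a high-resolution one."""

    def __init__(self, c_low: int, c_high: int, low_res: int,
                 rng: np.random.Generator):
        self.pool_factor = low_res // 4
        mid = max(c_high // 2, 4)
        self.conv1 = nn.Conv2d(c_low, mid, 4, rng=rng)      # 4×4 → 1×1
        self.act = nn.LeakyReLU(0.1)
        self.conv2 = nn.Conv2d(mid, c_high, 1, rng=rng)

    def __call__(self, low, high):
        g = low.avg_pool(self.pool_factor) if self.pool_factor > 1 else low
        g = self.conv2(self.act(self.conv1(g))).sigmoid()
        return high * g


class Generator(nn.Module):
    """Maps z ∈ [−1,1]^L to an N×N single-channel image in [0, 1]."""

    def __init__(self, resolution: int = 32, latent_dim: int = 512,
                 base_channels: int = 64, noise_injection: bool = False,
                 use_sle: bool | None = None,
                 rng: np.random.Generator | None = None):
        if resolution < 16 or (resolution & (resolution - 1)) != 0:
            raise ValueError("resolution must be a power of two >= 16")
        rng = rng or np.random.default_rng()
        self.resolution = resolution
        self.latent_dim = latent_dim
        self.base_channels = base_channels
        self.noise_injection = noise_injection
        n_blocks = int(np.log2(resolution)) - 2
        if use_sle is None:
            use_sle = n_blocks >= 4
        self.use_sle = use_sle
        chans = [base_channels]
        for j in range(n_blocks):
            chans.append(max(base_channels >> (j + 1), 8))
        self.channels = chans
        self.project = nn.Dense(latent_dim, 2 * chans[0] * 16, rng=rng)
        self.bn0 = nn.BatchNorm2d(2 * chans[0])
        self.glu0 = nn.GLU()
        self.blocks = [
            _UpBlock(chans[j], chans[j + 1], noise_injection, rng)
            for j in range(n_blocks)
        ]
        # SLE pairs: block j output (res 4·2^{j+1}) gates block j+3 output.
        self.sle_pairs: list[tuple[int, int]] = []
        self.sles: list[_SkipLayerExcitation] = []
        if use_sle:
            for j in range(n_blocks - 3):
                low_res = 4 * 2 ** (j + 1)
                self.sle_pairs.append((j, j + 3))
                self.sles.append(_SkipLayerExcitation(
                    chans[j + 1], chans[j + 4], low_res, rng))
        self.to_image = nn.Conv2d(chans[-1], 1, 3, padding=1, rng=rng)

    def __call__(self, z: nn.Tensor) -> nn.Tensor:
        b = z.data.shape[0]
        x = self.project(z).reshape(b, 2 * self.channels[0], 4, 4)
        x = self.glu0(self.bn0(x))
        feats: dict[int, nn.Tensor] = {}
        gate_of = {hi: (lo, sle)
                   for (lo, hi), sle in zip(self.sle_pairs, self.sles)}
        for j, block in enumerate(self.blocks):
            x = block(x)
            if j in gate_of:
                lo, sle = gate_of[j]
                x = sle(feats[lo], x)
            feats[j] = x
        y = self.to_image(x).tanh()
        return (y + nn.Tensor(np.float32(1.0))) * nn.Tensor(np.float32(0.5))

    def generate(self, z: np.ndarray) -> np.ndarray:
        """Convenience inference: (n, L) latents → (n, N, N) images."""
        z = np.asarray(z, dtype=_DTYPE)
        if z.ndim == 1:
            z = z[None]
        return self(nn.Tensor(z)).data[:, 0]


class Discriminator(nn.Module):
    """Spectral-normalized conv stack: image → logit (+ aux reconstruction).

    The auxiliary decoder consumes the 4×4 intermediate feature map and
    reconstructs an 8×-downsampled version of its (real) input.
    """

    def __init__(self, resolution: int = 32, base_channels: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.resolution = resolution
        n_blocks = int(np.log2(resolution)) - 2     # down to 4×4
        chans = [1]
        for j in range(n_blocks):
            chans.append(min(base_channels * 2 ** j, 256))
        self.downs = [
            nn.Conv2d(chans[j], chans[j + 1], 4, stride=2, padding=1,
                      spectral_norm=True, rng=rng)
            for j in range(n_blocks)
        ]
        self.act = nn.LeakyReLU(0.2)
        self.logit_head = nn.Conv2d(chans[-1], 1, 4, spectral_norm=True, rng=rng)
        # decoder: 4×4 features → max(4, N/8) image
        dec_res = max(4, resolution // 8)
        self.decode_factor = resolution // dec_res
        ups = int(np.log2(dec_res // 4))
        c = chans[-1]
        self.dec_blocks = []
        for _ in range(ups):
            c_out = max(c // 2, 8)
            self.dec_blocks.append(_UpBlock(c, c_out, False, rng))
            c = c_out
        self.dec_out = nn.Conv2d(c, 1, 3, padding=1, rng=rng)

    def features(self, x: nn.Tensor) -> nn.Tensor:
        for conv in self.downs:
            x = self.act(conv(x))
        return x

    def __call__(self, x: nn.Tensor, decode: bool = False):
        f = self.features(x)
        b = x.data.shape[0]
        logits = self.logit_head(f).reshape(b)
        if not decode:
            return logits
        d = f
        for block in self.dec_blocks:
            d = block(d)
        d = self.dec_out(d).tanh()
        decoded = (d + nn.Tensor(np.float32(1.0))) * nn.Tensor(np.float32(0.5))
        return logits, decoded


# ---------------------------------------------------------------------------
# training


@dataclass
class GanTrainConfig:
    resolution: int = 32
    latent_dim: int = 512
    base_channels_g: int = 64
    base_channels_d: int = 16
    noise_injection: bool = False
    batch_size: int = 8
    total_steps: int = 100_000
    learning_rate: float = 2e-4
    adam_betas: tuple[float, float] = (0.5, 0.999)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    checkpoint_every: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.total_steps < 1:
            raise ValueError("counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def train_gan(dataset: SliceDataset, config: GanTrainConfig,
              out_dir: str | Path | None = None,
              ) -> tuple[Generator, Discriminator, list[dict]]:
    """Alternating hinge-loss training of (G, D) on a normal-only dataset.

    One discriminator step then one generator step per iteration.  Returns the
    trained pair plus a per-step loss log; checkpoints are written to
    ``out_dir`` every ``checkpoint_every`` steps when given.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    if dataset.masks is not None:
        raise ValueError("GAN training expects a normal-only dataset")
    stack = dataset.pixel_stack().astype(_DTYPE)
    n, h, w = stack.shape
    if h != config.resolution or w != config.resolution:
        raise ValueError(
            f"dataset resolution {h}×{w} != configured {config.resolution}")

    ss = np.random.SeedSequence(config.seed)
    init_g, init_d, data_rng, aug_rng, z_rng = \
        [np.random.default_rng(s) for s in ss.spawn(5)]
    gen = Generator(config.resolution, config.latent_dim,
                    config.base_channels_g, config.noise_injection, rng=init_g)
    disc = Discriminator(config.resolution, config.base_channels_d, rng=init_d)
    opt_g = nn.Adam(gen.parameters(), lr=config.learning_rate,
                    betas=config.adam_betas)
    opt_d = nn.Adam(disc.parameters(), lr=config.learning_rate,
                    betas=config.adam_betas)
    gen.train()
    disc.train()
    log: list[dict] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    half = nn.Tensor(np.float32(0.5))
    one = nn.Tensor(np.float32(1.0))

    for step in range(1, config.total_steps + 1):
        idx = data_rng.integers(0, n, size=config.batch_size)
        real = np.stack([augment(stack[i], config.augment, aug_rng)
                         for i in idx])[:, None]
        real_t = nn.Tensor(real)
        real_down = real.reshape(
            config.batch_size, 1,
            config.resolution // disc.decode_factor, disc.decode_factor,
            config.resolution // disc.decode_factor, disc.decode_factor,
        ).mean(axis=(3, 5))

        z = sample_latent(config.batch_size, config.latent_dim, z_rng)
        fake_t = gen(nn.Tensor(z))

        # -- discriminator step (generator detached)
        real_logits, decoded = disc(real_t, decode=True)
        fake_logits_d = disc(nn.Tensor(fake_t.data))
        rec = (decoded - nn.Tensor(real_down)).abs().mean()
        loss_d = ((one - real_logits).relu().mean()
                  + (one + fake_logits_d).relu().mean() + rec)
        gen.zero_grad()
        disc.zero_grad()
        loss_d.backward()
        opt_d.step()

        # -- generator step (through the updated discriminator)
        fake_logits_g = disc(fake_t)
        loss_g = -fake_logits_g.mean()
        gen.zero_grad()
        disc.zero_grad()
        loss_g.backward()
        opt_g.step()

        ld, lg, lr_ = float(loss_d.data), float(loss_g.data), float(rec.data)
        if not (np.isfinite(ld) and np.isfinite(lg)):
            raise RuntimeError(f"non-finite loss at step {step}: "
                               f"loss_d={ld}, loss_g={lg}")
        log.append({"step": step, "loss_d": ld, "loss_g": lg, "rec": lr_})
        if out_dir is not None and (
            step % config.checkpoint_every == 0 or step == config.total_steps
        ):
            save_model(out_dir / f"gen-{step:06d}.npz", gen, step=step,
                       seed=config.seed)
            save_model(out_dir / f"disc-{step:06d}.npz", disc, step=step,
                       seed=config.seed)
    if out_dir is not None:
        with open(out_dir / "train_log.jsonl", "w") as fh:
            for row in log:
                fh.write(json.dumps(row) + "\n")
    gen.eval()
    disc.eval()
    return gen, disc, log


# ---------------------------------------------------------------------------
# checkpoint container


def _model_meta(model: nn.Module) -> dict:
    if isinstance(model, Generator):
        return {"kind": "generator", "resolution": model.resolution,
                "latent_dim": model.latent_dim,
                "base_channels": model.base_channels,
                "noise_injection": model.noise_injection,
                "use_sle": model.use_sle}
    if isinstance(model, Discriminator):
        return {"kind": "discriminator", "resolution": model.resolution,
                "base_channels": model.downs[0].weight.data.shape[0]}
    from .encoder import EncoderNet
    if isinstance(model, EncoderNet):
        return {"kind": "encoder", "resolution": model.resolution,
                "latent_dim": model.latent_dim,
                "base_channels": model.base_channels}
    raise TypeError(f"unknown model type {type(model)!r}")


def save_model(path: str | Path, model: nn.Module, **extra) -> Path:
    """Serialize a model to an .npz container with a JSON metadata record."""
    path = Path(path)
    meta = _model_meta(model)
    meta.update(extra)
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_model(path: str | Path) -> tuple[nn.Module, dict]:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[k] for k in sorted(data.files) if k != "__meta__"]
    kind = meta["kind"]
    if kind == "generator":
        model = Generator(meta["resolution"], meta["latent_dim"],
                          meta["base_channels"], meta["noise_injection"],
                          use_sle=meta["use_sle"],
                          rng=np.random.default_rng(0))
    elif kind == "discriminator":
        model = Discriminator(meta["resolution"], meta["base_channels"],
                              rng=np.random.default_rng(0))
    elif kind == "encoder":
        from .encoder import EncoderNet
        model = EncoderNet(meta["resolution"], meta["latent_dim"],
                           meta["base_channels"],
                           rng=np.random.default_rng(0))
    else:
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    model.load_state_arrays(arrays)
    model.eval()
    return model, meta
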