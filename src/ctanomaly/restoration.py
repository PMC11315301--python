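"""Per-image latent restoration: training-free GAN inversion.

Instead of a trained encoder, each image gets its own latent code by solving

    min_{−1 ≤ z ≤ 1}  w1·ℓ_percept(x, G(z)) + w2·ℓ_MSE(x, G(z)),
    w1 = 1, w2 = 10,

with Adam from the initial guess z = 0, clipping z component-wise to [−1, 1]
after every update (projection onto the latent box) and stopping after a
fixed number of steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .encoder import _as_batch, get_perceptual_backend, objective_tensor
from .gan import Generator

_DTYPE = np.float32


@dataclass
class RestorationConfig:
    w1: float = 1.0
    w2: float = 10.0
    backend: str = "randconv"
    steps: int = 8000
    learning_rate: float = 0.01
    adam_betas: tuple[float, float] = (0.9, 0.999)
    n_starts: int = 1     # optional multi-start; the default is a single
    seed: int = 0         # run from z = 0

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


def restoration_objective(x, z, gen: Generator,
                          cfg: RestorationConfig | None = None) -> float:
    """Evaluate w1·ℓ_percept(x, G(z)) + w2·ℓ_MSE(x, G(z))."""
    cfg = cfg or RestorationConfig()
    backend = get_perceptual_backend(cfg.backend)
    xb = _as_batch(x)
    zt = nn.Tensor(np.asarray(z, dtype=_DTYPE).reshape(1, -1))
    gen.eval()
    return float(objective_tensor(nn.Tensor(xb), gen(zt),
                                  cfg.w1, cfg.w2, backend).data)


def _run_restoration(xb: np.ndarray, gen: Generator, cfg: RestorationConfig,
                     z0: np.ndarray) -> tuple[np.ndarray, list[float]]:
    backend = get_perceptual_backend(cfg.backend)
    x_t = nn.Tensor(xb)
    z = nn.Tensor(z0.reshape(1, -1).astype(_DTYPE), requires_grad=True)
    opt = nn.Adam([z], lr=cfg.learning_rate, betas=cfg.adam_betas)
    trace: list[float] = []
    for step in range(cfg.steps):
        obj = objective_tensor(x_t, gen(z), cfg.w1, cfg.w2, backend)
        val = float(obj.data)
        if not np.isfinite(val):
            raise RuntimeError(
                f"non-finite restoration objective at step {step}: {val}")
        trace.append(val)
        opt.zero_grad()
        obj.backward()
        opt.step()
        np.clip(z.data, -1.0, 1.0, out=z.data)
    final = float(objective_tensor(x_t, gen(z), cfg.w1, cfg.w2, backend).data)
    trace.append(final)
    return z.data[0].copy(), trace


def restore_latent(x, gen: Generator, cfg: RestorationConfig | None = None
                   ) -> tuple[np.ndarray, list[float]]:
    """Optimize a latent code for ``x``; return (z, per-step objective trace).

    The trace has ``steps + 1`` entries: the objective before each update and
    after the last one.  Every iterate (and the result) lies in [−1, 1]^L.
    """
    cfg = cfg or RestorationConfig()
    xb = _as_batch(x)
    if xb.shape[2] != gen.resolution:
        raise ValueError(f"image resolution {xb.shape[2]} != generator "
                         f"{gen.resolution}")
    gen.eval()
    gen.set_trainable(False)
    try:
        starts = [np.zeros(gen.latent_dim, dtype=_DTYPE)]
        if cfg.n_starts > 1:
            rng = np.random.default_rng(cfg.seed)
            starts += [rng.uniform(-1, 1, gen.latent_dim).astype(_DTYPE)
                       for _ in range(cfg.n_starts - 1)]
        best_z, best_trace = None, None
        for z0 in starts:
            zf, trace = _run_restoration(xb, gen, cfg, z0)
            if best_trace is None or trace[-1] < best_trace[-1]:
                best_z, best_trace = zf, trace
    finally:
        gen.set_trainable(True)
    return best_z, best_trace
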