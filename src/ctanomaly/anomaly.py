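"""From (input, reconstruction) pairs to binary anomaly masks.

The residual function ρ is either the absolute value — detect any change —
or the positive part — detect lesions brighter than the reconstructed
tissue, e.g. acute hemorrhage.  Residuals are expressed in byte-scale
intensity units (unit-scale differences × 255) so the operating threshold is
on the 0–255 scale; a pixel is anomalous when its residual strictly exceeds
the threshold.  Masks are refined by morphological closing, combined across
an ensemble of independently trained models by per-pixel majority vote, and
optionally filtered across consecutive slices by 3-D connected-component
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .encoder import EncoderNet
from .gan import Generator
from .imaging_io import ImageGrid
from .restoration import RestorationConfig, restore_latent

_DTYPE = np.float32

RESIDUAL_KINDS = ("abs", "positive_part")


def _pixels(x) -> np.ndarray:
    return x.pixels if isinstance(x, ImageGrid) else np.asarray(x, dtype=_DTYPE)


@dataclass
class AnomalyConfig:
    residual_kind: str = "abs"
    threshold: float = 36.0              # byte-scale operating point
    closing_radius: int | None = None    # None → 2 px at 512, scaled down
    ensemble_size: int = 3
    min_component_size: int = 0
    min_slice_span: int = 1

    def __post_init__(self):
        if self.residual_kind not in RESIDUAL_KINDS:
            raise ValueError(f"unknown residual kind {self.residual_kind!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.ensemble_size % 2 == 0:
            raise ValueError("ensemble size must be odd (majority vote)")

    def closing_radius_for(self, resolution: int) -> int:
        if self.closing_radius is not None:
            return self.closing_radius
        return int(round(2 * resolution / 512))


# ---------------------------------------------------------------------------
# stage operations


def residual_map(x, xhat, kind: str = "abs", byte_scale: bool = True
                 ) -> np.ndarray:
    """ρ(x − x̂): ``abs`` → |x − x̂|; ``positive_part`` → max(x − x̂, 0)."""
    if kind not in RESIDUAL_KINDS:
        raise ValueError(f"unknown residual kind {kind!r}")
    a, b = _pixels(x), _pixels(xhat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    diff = a.astype(np.float64) - b.astype(np.float64)
    r = np.abs(diff) if kind == "abs" else np.maximum(diff, 0.0)
    return (r * 255.0 if byte_scale else r).astype(_DTYPE)


def threshold_mask(r: np.ndarray, t: float) -> np.ndarray:
    """Binarize a residual map: anomalous where r strictly exceeds t."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    return np.asarray(r) > t


def disk_element(radius: int) -> np.ndarray:
    """Rasterized disk: pixels whose center lies within radius + 1/2 of the
    origin.  Covers a full 3×3 square at radius 1 (so a one-pixel gap closes)
    and drops the extreme corners at larger radii."""
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy ** 2 + xx ** 2) <= (radius + 0.5) ** 2


def close_mask(m: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing with a disk structuring element.

    Computed on a zero-padded frame (the infinite-background convention), so
    the result always contains the input and closing is idempotent.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return m.astype(bool).copy()
    m = m.astype(bool)
    selem = disk_element(radius)
    padded = np.pad(m, radius, constant_values=False)
    dilated = ndimage.binary_dilation(padded, structure=selem)
    closed = ndimage.binary_erosion(dilated, structure=selem)
    return closed[radius:-radius, radius:-radius]


def majority_vote(masks: list[np.ndarray]) -> np.ndarray:
    """Per-pixel majority over an odd number of equally shaped masks."""
    if len(masks) % 2 == 0:
        raise ValueError("majority vote needs an odd number of masks")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    votes = np.sum([m.astype(np.int32) for m in masks], axis=0)
    return votes > len(masks) // 2


def multi_slice_filter(masks: list[np.ndarray], min_size: int = 1,
                       min_span: int = 1) -> list[np.ndarray]:
    """Remove small 3-D connected components across a stack of slice masks.

    Components are 26-connected across the slice axis; a component survives
    only if it has at least ``min_size`` voxels and spans at least
    ``min_span`` consecutive slices.
    """
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    stack = np.stack([m.astype(bool) for m in masks])
    labels, n = ndimage.label(stack, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return [s.copy() for s in stack]
    keep = np.zeros(n + 1, dtype=bool)
    for lab in range(1, n + 1):
        comp = labels == lab
        size = int(comp.sum())
        span = int(comp.any(axis=(1, 2)).sum())
        keep[lab] = size >= min_size and span >= min_span
    filtered = keep[labels] & stack
    return [filtered[i] for i in range(filtered.shape[0])]


# ---------------------------------------------------------------------------
# reconstruction + end-to-end detection


def reconstruct(x, gen: Generator, enc: EncoderNet | None = None,
                mode: str = "restore",
                restoration_cfg: RestorationConfig | None = None) -> np.ndarray:
    """Pseudo-healthy reconstruction x̂ = G(z) of one image."""
    xa = _pixels(x)
    gen.eval()
    if mode == "encoder":
        if enc is None:
            raise ValueError("encoder mode requires a trained encoder")
        enc.eval()
        z = enc.encode(xa)
    elif mode == "restore":
        z, _ = restore_latent(xa, gen, restoration_cfg or RestorationConfig())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return gen.generate(z)[0]


def detect(x, models: list[tuple[Generator, EncoderNet | None]],
           cfg: AnomalyConfig, mode: str = "restore",
           restoration_cfg: RestorationConfig | None = None,
           threshold: float | None = None,
           ) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Ensemble anomaly detection on a single slice.

    Per model: reconstruct → residual → threshold → closing; the per-model
    binary masks are then combined by majority vote.  Returns the voted mask,
    the per-model residual maps, and the mean reconstruction (for display).
    """
    if len(models) != cfg.ensemble_size:
        raise ValueError(f"expected {cfg.ensemble_size} models, "
                         f"got {len(models)}")
    xa = _pixels(x)
    resolutions = {g.resolution for g, _ in models}
    if len(resolutions) != 1 or xa.shape[0] not in resolutions:
        raise ValueError("mixed or mismatched model/image resolutions")
    t = cfg.threshold if threshold is None else threshold
    radius = cfg.closing_radius_for(xa.shape[0])
    residuals, member_masks, recons = [], [], []
    for g, e in models:
        xhat = reconstruct(xa, g, e, mode=mode, restoration_cfg=restoration_cfg)
        r = residual_map(xa, xhat, kind=cfg.residual_kind)
        residuals.append(r)
        member_masks.append(close_mask(threshold_mask(r, t), radius))
        recons.append(xhat)
    voted = majority_vote(member_masks)
    return voted, residuals, np.mean(recons, axis=0)
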