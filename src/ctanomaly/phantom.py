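"""Synthetic head-phantom slices with insertable lesions and exact masks.

The phantom emulates the intensity statistics the detection pipeline must cope
with on real brain CT: a bright elliptical skull annulus (≈0.95), mid-intensity
brain tissue (≈0.35) carrying smooth low-amplitude structure (the low-contrast
regime characteristic of CT soft tissue), darker paired ventricles (≈0.15) and
a dark background.  Two lesion families are provided: ``bright_blob`` — a
smooth positive intensity offset, hemorrhage-like — and ``textured_mass`` — a
heterogeneous offset with high-frequency texture and an optional rim,
tumor-like.  Every generated image is unit-scale; every insertion returns the
exact ground-truth mask of modified pixels.

Per-image geometry is drawn from a counter-based substream
(``default_rng([seed, split, i])``) so sample ``i`` does not depend on how many
samples are requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import ImageGrid, SliceDataset, assemble_dataset

_DTYPE = np.float32

SKULL_LEVEL = 0.95
TISSUE_LEVEL = 0.35
VENTRICLE_LEVEL = 0.15

_SPLIT_CODE = {"train": 0, "validation": 1, "test": 2}


class PlacementError(ValueError):
    """A lesion was requested outside the brain region."""


@dataclass
class PhantomSpec:
    """Geometry and noise ranges for the phantom population.

    Ranges are fractions of the image size.  ``tissue_contrast`` is the
    standard deviation of the smooth intra-tissue structure; ``noise_sd`` is
    additive Gaussian pixel noise.
    """

    resolution: int = 32
    skull_radius_range: tuple[float, float] = (0.36, 0.46)
    skull_thickness_range: tuple[float, float] = (0.05, 0.09)
    ventricle_count: int = 2
    ventricle_size_range: tuple[float, float] = (0.05, 0.10)
    tissue_contrast: float = 0.04
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        r = self.resolution
        if r < 32 or (r & (r - 1)) != 0:
            raise ValueError("resolution must be a power of two >= 32")
        for rng_ in (self.skull_radius_range, self.skull_thickness_range,
                     self.ventricle_size_range):
            if not (0.0 < rng_[0] <= rng_[1] < 1.0):
                raise ValueError(f"range {rng_} must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class AnomalySpec:
    """One lesion to insert: kind, center (row, col), radius in pixels."""

    kind: str
    center: tuple[int, int]
    radius: float
    intensity_delta: float
    seed: int = 0
    edge_softness: float = 0.0
    rim: bool = False

    def __post_init__(self):
        if self.kind not in ("bright_blob", "textured_mass"):
            raise ValueError(f"unknown anomaly kind {self.kind!r}")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.kind == "bright_blob" and self.intensity_delta <= 0:
            raise ValueError("bright_blob must have intensity_delta > 0 "
                             "(hemorrhage-like lesions are hyperdense)")


# ---------------------------------------------------------------------------
# rendering


def _ellipse_mask(r: int, center, semi_axes, rng_grid) -> np.ndarray:
    yy, xx = rng_grid
    cy, cx = center
    a, b = semi_axes
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


def _render_phantom(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    r = spec.resolution
    yy, xx = np.mgrid[0:r, 0:r].astype(np.float64)
    grid = (yy, xx)
    center = (r / 2.0 + rng.uniform(-0.02, 0.02) * r,
              r / 2.0 + rng.uniform(-0.02, 0.02) * r)
    a_out = rng.uniform(*spec.skull_radius_range) * r
    b_out = rng.uniform(*spec.skull_radius_range) * r
    thick = rng.uniform(*spec.skull_thickness_range) * r
    outer = _ellipse_mask(r, center, (a_out, b_out), grid)
    inner = _ellipse_mask(r, center, (a_out - thick, b_out - thick), grid)

    img = np.zeros((r, r), dtype=np.float64)
    img[inner] = TISSUE_LEVEL
    if spec.tissue_contrast > 0:
        texture = rng.standard_normal((r, r))
        texture = ndimage.gaussian_filter(texture, sigma=r / 16.0)
        sd = texture.std()
        if sd > 0:
            texture *= spec.tissue_contrast / sd
        img[inner] += texture[inner]
    for k in range(spec.ventricle_count):
        size = rng.uniform(*spec.ventricle_size_range) * r
        side = -1.0 if k % 2 == 0 else 1.0
        if spec.ventricle_count == 1:
            side = 0.0
        vcy = center[0] + rng.uniform(-0.05, 0.05) * r
        vcx = center[1] + side * (0.08 * r + rng.uniform(0, 0.04) * r)
        vent = _ellipse_mask(r, (vcy, vcx), (size * 1.6, size * 0.8), grid)
        img[vent & inner] = VENTRICLE_LEVEL
    img[outer & ~inner] = SKULL_LEVEL
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, (r, r))
    return np.clip(img, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec, n: int,
                     split_tag: str = "train") -> SliceDataset:
    """Generate ``n`` phantom slices as a dataset of distinct 'patients'."""
    if n < 1:
        raise ValueError("n must be >= 1")
    images, pids = [], []
    code = _SPLIT_CODE[split_tag]
    for i in range(n):
        rng = np.random.default_rng([spec.seed, code, i])
        images.append(ImageGrid(_render_phantom(spec, rng), scale="unit"))
        pids.append(f"phantom-{spec.seed}-{split_tag}-{i}")
    return assemble_dataset(images, split_tag, pids)


# ---------------------------------------------------------------------------
# brain region and lesions


def estimate_brain_mask(img: ImageGrid, margin: int = 1) -> np.ndarray:
    """Soft-tissue region inside the skull, estimated from intensities."""
    skull = img.pixels > 0.7
    filled = ndimage.binary_fill_holes(skull)
    brain = filled & ~skull
    if margin > 0:
        brain = ndimage.binary_erosion(brain, iterations=margin)
    return brain


def _disk_mask(shape, center, radius) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def insert_anomaly(img: ImageGrid, aspec: AnomalySpec
                   ) -> tuple[ImageGrid, np.ndarray]:
    """Insert one lesion; return the modified image and its exact mask.

    Outside the returned mask the image is bit-identical to the input; inside,
    the perturbation is added and the result clamped to [0, 1].
    """
    h, w = img.pixels.shape
    if aspec.radius == 0:
        return ImageGrid(img.pixels.copy(), scale=img.scale), \
            np.zeros((h, w), dtype=bool)
    cy, cx = aspec.center
    r = aspec.radius
    if cy - r < 0 or cx - r < 0 or cy + r > h - 1 or cx + r > w - 1:
        raise PlacementError("lesion footprint exceeds image bounds")
    footprint = _disk_mask((h, w), (cy, cx), r)
    brain = estimate_brain_mask(img, margin=0)
    if not footprint[brain].any() or not brain[int(round(cy)), int(round(cx))]:
        raise PlacementError("lesion center lies outside the brain region")

    rng = np.random.default_rng(aspec.seed)
    delta = np.zeros((h, w), dtype=np.float64)
    delta[footprint] = aspec.intensity_delta
    if aspec.kind == "textured_mass":
        texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=0.8)
        sd = texture.std()
        if sd > 0:
            texture *= (0.5 * abs(aspec.intensity_delta)) / sd
        delta[footprint] += texture[footprint]
        if aspec.rim:
            ring = footprint & ~ndimage.binary_erosion(footprint, iterations=2)
            delta[ring] += 0.1
    if aspec.edge_softness > 0:
        delta = ndimage.gaussian_filter(delta, sigma=aspec.edge_softness)
        delta[~footprint] = 0.0  # keep the perturbation local to the footprint

    mask = footprint & (delta != 0.0)
    out = img.pixels.astype(np.float64).copy()
    out[mask] = np.clip(out[mask] + delta[mask], 0.0, 1.0)
    return ImageGrid(out, scale="unit"), mask


def make_abnormal_dataset(spec: PhantomSpec, n: int, split_tag: str,
                          kind: str = "bright_blob",
                          radius_frac_range: tuple[float, float] = (0.08, 0.12),
                          intensity_delta_range: tuple[float, float] = (0.25, 0.40),
                          ) -> SliceDataset:
    """Phantoms with one randomly placed lesion each, plus reference masks.

    Lesion centers are drawn uniformly from pixels of the estimated brain
    region whose full footprint stays inside it; radius is a fraction of the
    image width.
    """
    base = generate_phantom(spec, n, split_tag=split_tag)
    code = _SPLIT_CODE[split_tag]
    images, masks = [], []
    for i, img in enumerate(base.images):
        rng = np.random.default_rng([spec.seed, code, i, 1])
        radius = rng.uniform(*radius_frac_range) * spec.resolution
        delta = rng.uniform(*intensity_delta_range)
        brain = estimate_brain_mask(img, margin=0)
        interior = ndimage.binary_erosion(
            brain, iterations=max(1, int(np.ceil(radius))))
        candidates = np.argwhere(interior)
        if len(candidates) == 0:
            candidates = np.argwhere(brain)
        cy, cx = candidates[rng.integers(len(candidates))]
        aspec = AnomalySpec(kind=kind, center=(int(cy), int(cx)), radius=radius,
                            intensity_delta=delta,
                            seed=int(rng.integers(2 ** 31)))
        lesioned, mask = insert_anomaly(img, aspec)
        images.append(lesioned)
        masks.append(mask)
    return assemble_dataset(images, split_tag, base.patient_ids, masks)
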