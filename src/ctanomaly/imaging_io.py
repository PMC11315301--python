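"""Reading, writing and normalizing 2-D tomographic slice images.

Supports the three slice formats commonly seen around brain-CT work —
DICOM (via pydicom, with rescale slope/intercept and HU display windowing),
NIfTI (via nibabel, single slices or slice-indexed volumes) and 8/16-bit
grayscale PNG (via Pillow).  All loaders deliver a unit-scale
:class:`ImageGrid`; datasets are plain ordered collections with patient-level
split bookkeeping so that no patient contributes to more than one split.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_DTYPE = np.float32

INTENSITY_SCALES = ("unit", "byte", "hounsfield")

#: Default CT display window (center, width) in HU: the standard brain window.
DEFAULT_BRAIN_WINDOW = (40.0, 80.0)


class FormatError(ValueError):
    """The file could not be parsed under the named standard."""


class ShapeError(ValueError):
    """The payload is not a usable 2-D grayscale raster."""


class ConsistencyError(ValueError):
    """Dataset invariants (patient splits, mask shapes) are violated."""


@dataclass
class ImageGrid:
    """An H×W grayscale intensity raster.

    ``scale`` records the intensity convention: ``unit`` ([0, 1]), ``byte``
    ([0, 255]) or ``hounsfield`` (calibrated HU).
    """

    pixels: np.ndarray
    scale: str = "unit"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=_DTYPE)
        if self.pixels.ndim != 2:
            raise ShapeError(f"expected a 2-D raster, got shape {self.pixels.shape}")
        if not np.isfinite(self.pixels).all():
            raise ValueError("image contains non-finite values")
        if self.scale not in INTENSITY_SCALES:
            raise ValueError(f"unknown intensity scale {self.scale!r}")
        if self.scale == "unit" and (
            self.pixels.min() < -1e-6 or self.pixels.max() > 1 + 1e-6
        ):
            raise ValueError("unit-scale image has values outside [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SliceDataset:
    """An ordered collection of slices with optional reference lesion masks."""

    images: list[ImageGrid]
    split_tag: str
    patient_ids: list[str]
    masks: list[np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.split_tag not in ("train", "validation", "test"):
            raise ValueError(f"unknown split {self.split_tag!r}")
        if len(self.patient_ids) != len(self.images):
            raise ConsistencyError("patient_ids must parallel images")
        if self.masks is not None:
            if self.split_tag == "train":
                raise ConsistencyError(
                    "train split is normal-only and carries no lesion masks"
                )
            if len(self.masks) != len(self.images):
                raise ConsistencyError("masks must parallel images")
            for img, m in zip(self.images, self.masks):
                if m is not None and m.shape != img.pixels.shape:
                    raise ShapeError(
                        f"mask shape {m.shape} != image shape {img.pixels.shape}"
                    )

    def __len__(self) -> int:
        return len(self.images)

    @property
    def patients(self) -> set[str]:
        return set(self.patient_ids)

    def pixel_stack(self) -> np.ndarray:
        """All images as a (n, H, W) array (requires uniform shapes)."""
        return np.stack([im.pixels for im in self.images])


# ---------------------------------------------------------------------------
# loading


def _window_to_unit(hu: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    center, width = window
    lo = center - width / 2.0
    return np.clip((hu - lo) / width, 0.0, 1.0)


def load_slice(path: str | Path, format: str | None = None,
               window: tuple[float, float] | None = None,
               index: int | None = None) -> ImageGrid:
    """Load one slice as a unit-scale :class:`ImageGrid`.

    Parameters
    ----------
    path : file path.
    format : ``"dicom"``, ``"nifti"`` or ``"png"``; inferred from the suffix
        when omitted.
    window : HU display window ``(center, width)``; mapped linearly so that
        ``center - width/2`` → 0 and ``center + width/2`` → 1, then clamped.
        Defaults to the brain window (40, 80) for DICOM input and to ``None``
        (per-slice min-max) otherwise.
    index : slice index along the last axis for NIfTI volumes.
    """
    path = Path(path)
    if format is None:
        suffix = "".join(path.suffixes).lower()
        if suffix.endswith(".dcm"):
            format = "dicom"
        elif suffix.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif suffix.endswith(".png"):
            format = "png"
        else:
            raise FormatError(f"cannot infer format from {path.name!r}")
    if format == "dicom":
        return _load_dicom(path, window if window is not None else DEFAULT_BRAIN_WINDOW)
    if format == "nifti":
        return _load_nifti(path, window, index)
    if format == "png":
        if window is not None:
            raise ValueError("HU windows do not apply to PNG input")
        return _load_png(path)
    raise FormatError(f"unknown format {format!r}")


def _load_dicom(path: Path, window: tuple[float, float]) -> ImageGrid:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        raw = ds.pixel_array
    except Exception as exc:  # noqa: BLE001 - normalize library errors
        raise FormatError(f"unreadable DICOM file {path}: {exc}") from exc
    if raw.ndim != 2:
        raise ShapeError(f"DICOM payload is {raw.ndim}-D, expected 2-D")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = raw.astype(np.float64) * slope + intercept
    return ImageGrid(_window_to_unit(hu, window), scale="unit")


def _load_nifti(path: Path, window, index) -> ImageGrid:
    import nibabel as nib

    try:
        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable NIfTI file {path}: {exc}") from exc
    if vol.ndim == 3:
        if index is None:
            if vol.shape[2] != 1:
                raise ShapeError("NIfTI volume needs a slice index")
            vol = vol[:, :, 0]
        else:
            vol = vol[:, :, index]
    if vol.ndim != 2:
        raise ShapeError(f"NIfTI payload is {vol.ndim}-D, expected 2-D")
    if window is not None:
        return ImageGrid(_window_to_unit(vol, window), scale="unit")
    return normalize_unit(ImageGrid(vol.astype(_DTYPE), scale="hounsfield"))


def _load_png(path: Path) -> ImageGrid:
    from PIL import Image

    try:
        with Image.open(path) as im:
            if im.mode == "I;16":
                arr = np.asarray(im, dtype=np.float64) / 65535.0
            elif im.mode in ("I", "I;16B"):
                arr = np.asarray(im, dtype=np.float64) / 65535.0
            elif im.mode == "L":
                arr = np.asarray(im, dtype=np.float64) / 255.0
            else:
                raise ShapeError(
                    f"PNG mode {im.mode!r} is not single-channel grayscale"
                )
    except ShapeError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable PNG file {path}: {exc}") from exc
    return ImageGrid(arr, scale="unit")


def save_png(img: ImageGrid, path: str | Path, bitdepth: int = 16) -> Path:
    """Write a unit-scale image as an 8- or 16-bit grayscale PNG."""
    from PIL import Image

    if img.scale != "unit":
        img = normalize_unit(img)
    path = Path(path)
    if bitdepth == 16:
        data = np.round(img.pixels.astype(np.float64) * 65535.0).astype(np.uint16)
        Image.fromarray(data).save(path)
    elif bitdepth == 8:
        data = np.round(img.pixels.astype(np.float64) * 255.0).astype(np.uint8)
        Image.fromarray(data, mode="L").save(path)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    return path


# ---------------------------------------------------------------------------
# normalization and dataset assembly


def normalize_unit(img: ImageGrid) -> ImageGrid:
    """Affine min-max rescale to [0, 1]; a constant image maps to all zeros."""
    lo = float(img.pixels.min())
    hi = float(img.pixels.max())
    if hi == lo:
        return ImageGrid(np.zeros_like(img.pixels), scale="unit")
    return ImageGrid((img.pixels - lo) / (hi - lo), scale="unit")


def assemble_dataset(images: list[ImageGrid], split_tag: str,
                     patient_ids: list[str],
                     masks: list[np.ndarray] | None = None) -> SliceDataset:
    """Build a :class:`SliceDataset`, enforcing its invariants."""
    return SliceDataset(images=list(images), split_tag=split_tag,
                        patient_ids=list(patient_ids),
                        masks=None if masks is None else list(masks))


def check_patient_disjoint(*datasets: SliceDataset) -> None:
    """Raise if any patient appears in more than one split."""
    seen: dict[str, str] = {}
    for ds in datasets:
        for pid in ds.patients:
            if pid in seen and seen[pid] != ds.split_tag:
                raise ConsistencyError(
                    f"patient {pid!r} appears in both {seen[pid]!r} "
                    f"and {ds.split_tag!r}"
                )
            seen.setdefault(pid, ds.split_tag)


# ---------------------------------------------------------------------------
# manifests


def write_manifest(path: str | Path, rows: list[dict]) -> Path:
    """Write a dataset manifest (TSV: path, patient_id, split, mask_path)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["path", "patient_id", "split", "mask_path"],
            delimiter="\t",
        )
        writer.writeheader()
        for row in rows:
            writer.writerow({"mask_path": "", **row})
    return path


def read_manifest(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_manifest_split(path: str | Path, split: str,
                        base_dir: str | Path | None = None) -> SliceDataset:
    """Load every manifest row belonging to ``split`` into a dataset."""
    base = Path(base_dir) if base_dir is not None else Path(path).parent
    images, pids, masks = [], [], []
    any_mask = False
    for row in read_manifest(path):
        if row["split"] != split:
            continue
        images.append(load_slice(base / row["path"]))
        pids.append(row["patient_id"])
        mpath = row.get("mask_path") or ""
        if mpath:
            any_mask = True
            masks.append(load_slice(base / mpath).pixels > 0.5)
        else:
            masks.append(None)
    return assemble_dataset(images, split, pids, masks if any_mask else None)
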