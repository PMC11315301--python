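"""Evaluation machinery: Dice sweeps, pixel-wise ROC, operating points,
reconstruction-error statistics and lesion-level detection.

Conventions: the pixel-wise ROC pools pixels across all images of a set
(rather than averaging per-image curves); the operating point is the grid
threshold maximizing median Dice on the validation split, ties broken toward
the smaller threshold; a lesion counts as detected when its Dice strictly
exceeds 0.1; reconstruction statistics (RMSE, mean ± sd absolute difference,
90th-percentile difference) are computed on unit-scale [0, 1] images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .anomaly import close_mask, threshold_mask
from .imaging_io import ImageGrid


def _pixels(x) -> np.ndarray:
    return x.pixels if isinstance(x, ImageGrid) else np.asarray(x)


# ---------------------------------------------------------------------------
# Dice


def dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); defined as 1.0 when both are empty."""
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {ref.shape}")
    denom = int(pred.sum()) + int(ref.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pred & ref).sum()) / denom


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    pooled: bool = True

    def auc(self) -> float:
        """Area under the curve, anchored at (0,0) and (1,1)."""
        order = np.lexsort((self.tpr, self.fpr))
        fpr = np.concatenate([[0.0], np.asarray(self.fpr)[order], [1.0]])
        tpr = np.concatenate([[0.0], np.asarray(self.tpr)[order], [1.0]])
        return float(np.trapezoid(tpr, fpr))


def roc_curve(residuals: list[np.ndarray], refs: list[np.ndarray],
              thresholds: np.ndarray | None = None) -> ROCCurve:
    """Pixel-pooled ROC over a set of residual maps and reference masks."""
    if thresholds is None:
        thresholds = np.arange(0, 256, dtype=float)
    r = np.concatenate([np.asarray(x).ravel() for x in residuals])
    y = np.concatenate([np.asarray(m).astype(bool).ravel() for m in refs])
    pos = int(y.sum())
    neg = int(y.size - pos)
    if pos == 0 or neg == 0:
        raise ValueError("pooled pixel set needs both positives and negatives")
    # counts via sorted residuals: for each t, #(r > t) among pos / neg pixels
    r_pos = np.sort(r[y])
    r_neg = np.sort(r[~y])
    tp = pos - np.searchsorted(r_pos, thresholds, side="right")
    fp = neg - np.searchsorted(r_neg, thresholds, side="right")
    return ROCCurve(np.asarray(thresholds, dtype=float),
                    fp / neg, tp / pos, pooled=True)


# ---------------------------------------------------------------------------
# operating-point sweep


def sweep_operating_point(residuals: list[np.ndarray],
                          refs: list[np.ndarray],
                          thresholds: np.ndarray | None = None,
                          criterion: str = "median_dice",
                          closing_radius: int = 0,
                          ) -> tuple[float, list[dict]]:
    """Sweep thresholds on a validation set; return (t*, sweep table).

    For every grid threshold each residual map is binarized (and closed),
    Dice against the reference is computed per image, and the summary row
    records the median and mean ± sd.  t* maximizes the criterion (default:
    median Dice); ties break toward the smallest threshold.
    """
    if thresholds is None:
        thresholds = np.arange(0, 256, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold grid")
    if len(residuals) == 0:
        raise ValueError("empty validation set")
    table: list[dict] = []
    for t in thresholds:
        dvals = []
        for r, ref in zip(residuals, refs):
            m = threshold_mask(r, t)
            if closing_radius > 0:
                m = close_mask(m, closing_radius)
            dvals.append(dice(m, ref))
        dvals = np.asarray(dvals)
        table.append({
            "threshold": float(t),
            "median_dice": float(np.median(dvals)),
            "mean_dice": float(dvals.mean()),
            "sd_dice": float(dvals.std()),
        })
    scores = np.asarray([row[criterion] for row in table])
    best = int(np.argmax(scores))          # argmax returns the first maximum
    return float(thresholds[best]), table


# ---------------------------------------------------------------------------
# reconstruction statistics


def _pair_stats(xs: list[np.ndarray], xhats: list[np.ndarray]) -> dict:
    diffs = np.concatenate(
        [(np.asarray(_pixels(a), dtype=np.float64)
          - np.asarray(_pixels(b), dtype=np.float64)).ravel()
         for a, b in zip(xs, xhats)])
    absd = np.abs(diffs)
    return {
        "rmse": float(np.sqrt(np.mean(diffs ** 2))),
        "mean_abs": float(absd.mean()),
        "sd_abs": float(absd.std()),
        "p90_abs": float(np.percentile(absd, 90)),
        "n_pairs": len(xs),
    }


def reconstruction_stats(pairs: list[tuple], abnormal: list[bool] | None = None
                         ) -> dict:
    """RMSE / mean±sd / P90 of per-pixel differences, by group.

    ``pairs`` is a list of (input, reconstruction); ``abnormal`` flags each
    pair.  Statistics pool pixels within each group.
    """
    if abnormal is None:
        abnormal = [False] * len(pairs)
    out: dict = {}
    for label, flag in (("normal", False), ("abnormal", True)):
        group = [(a, b) for (a, b), f in zip(pairs, abnormal) if f == flag]
        if group:
            out[label] = _pair_stats([a for a, _ in group],
                                     [b for _, b in group])
    return out


# ---------------------------------------------------------------------------
# lesion-level detection


def per_lesion_dice(pred: np.ndarray, ref: np.ndarray,
                    neighborhood_dilation: int = 3) -> list[float]:
    """Dice per connected reference lesion, with the prediction restricted to
    a dilated neighborhood of that lesion (8-connectivity in-plane)."""
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    labels, n = ndimage.label(ref, structure=np.ones((3, 3), dtype=int))
    vals = []
    for lab in range(1, n + 1):
        comp = labels == lab
        neigh = ndimage.binary_dilation(comp, iterations=neighborhood_dilation)
        vals.append(dice(pred & neigh, comp))
    return vals


def detection_rate(dice_values: list[float], cutoff: float = 0.1) -> float:
    """Fraction of lesions with Dice strictly above the cutoff."""
    if len(dice_values) == 0:
        raise ValueError("empty Dice list")
    return float(np.mean(np.asarray(dice_values) > cutoff))


def compare_paired(a: list[float], b: list[float]) -> dict:
    """Wilcoxon signed-rank comparison of two paired metric lists."""
    res = stats.wilcoxon(a, b)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}


# ---------------------------------------------------------------------------
# report container


@dataclass
class EvalReport:
    operating_threshold: float
    per_image_dice: list[float]
    median_dice: float
    mean_dice: float
    sd_dice: float
    lesion_detection_rate: float
    reconstruction: dict = field(default_factory=dict)
    roc: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "operating_threshold": self.operating_threshold,
            "per_image_dice": list(map(float, self.per_image_dice)),
            "median_dice": self.median_dice,
            "mean_dice": self.mean_dice,
            "sd_dice": self.sd_dice,
            "lesion_detection_rate": self.lesion_detection_rate,
            "reconstruction": self.reconstruction,
            "roc": self.roc,
            "notes": self.notes,
        }


def evaluate_masks(preds: list[np.ndarray], refs: list[np.ndarray],
                   operating_threshold: float,
                   residuals: list[np.ndarray] | None = None,
                   pairs: list[tuple] | None = None,
                   abnormal: list[bool] | None = None) -> EvalReport:
    """Assemble the full report from predicted and reference masks."""
    dvals = [dice(p, r) for p, r in zip(preds, refs)]
    lesion_dice: list[float] = []
    for p, r in zip(preds, refs):
        lesion_dice.extend(per_lesion_dice(p, r))
    both_empty = sum(1 for p, r in zip(preds, refs)
                     if not np.asarray(p).any() and not np.asarray(r).any())
    report = EvalReport(
        operating_threshold=float(operating_threshold),
        per_image_dice=dvals,
        median_dice=float(np.median(dvals)),
        mean_dice=float(np.mean(dvals)),
        sd_dice=float(np.std(dvals)),
        lesion_detection_rate=(detection_rate(lesion_dice)
                               if lesion_dice else float("nan")),
        notes={"both_empty_pairs": both_empty, "roc_convention": "pooled"},
    )
    if residuals is not None:
        curve = roc_curve(residuals, refs)
        report.roc = {"thresholds": curve.thresholds.tolist(),
                      "fpr": curve.fpr.tolist(),
                      "tpr": curve.tpr.tolist(),
                      "auc": curve.auc()}
    if pairs is not None:
        report.reconstruction = reconstruction_stats(pairs, abnormal)
    return report
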