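"""Similarity metrics and lesion analyses.

Conventions, fixed across the package:

* dice of two empty masks is 1 (a healthy subject with an empty prediction
  scores perfect agreement);
* binarization uses a closed threshold (``value >= threshold``), so the 33%
  lesion and 80% tissue thresholds are inclusive;
* ground-truth lesions are 26-connected components; a lesion counts as
  detected as soon as the predicted mask overlaps it in at least one voxel —
  the most permissive criterion, consistent with detection rates exceeding
  dice coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "dice",
    "binarize",
    "lesion_detection_rate",
    "threshold_sweep",
    "ThresholdSweep",
    "mean_relative_deviation",
    "per_lesion_stats",
    "lesion_profile",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); both-empty defined as 1."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    _check_shapes(a, b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def binarize(prob_map: np.ndarray, threshold: float) -> np.ndarray:
    """Closed-threshold binarization: voxel true iff value >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(prob_map) >= threshold


def lesion_detection_rate(gt_mask: np.ndarray, pred_mask: np.ndarray) -> float:
    """Fraction of 26-connected ground-truth lesions overlapped by the prediction.

    An empty ground truth is defined as rate 1 (nothing to miss).
    """
    gt = np.asarray(gt_mask).astype(bool)
    pred = np.asarray(pred_mask).astype(bool)
    _check_shapes(gt, pred)
    labels, n = ndimage.label(gt, structure=_CONN26)
    if n == 0:
        return 1.0
    hit = np.unique(labels[pred & gt])
    detected = int((hit > 0).sum())
    return detected / n


@dataclass
class ThresholdSweep:
    thresholds: np.ndarray
    dice_values: np.ndarray
    detection_rates: np.ndarray
    best_threshold: float  # argmax-dice threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "dice": self.dice_values,
                "detection_rate": self.detection_rates,
            }
        )


def threshold_sweep(
    prob_map: np.ndarray, gt_mask: np.ndarray, thresholds
) -> ThresholdSweep:
    """Dice and lesion detection rate as a function of binarization threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    gt = np.asarray(gt_mask).astype(bool)
    dices = np.empty(thresholds.size)
    rates = np.empty(thresholds.size)
    for i, th in enumerate(thresholds):
        mask = binarize(prob_map, th)
        dices[i] = dice(mask, gt)
        rates[i] = lesion_detection_rate(gt, mask)
    return ThresholdSweep(
        thresholds=thresholds,
        dice_values=dices,
        detection_rates=rates,
        best_threshold=float(thresholds[int(np.argmax(dices))]),
    )


def mean_relative_deviation(
    test_map: np.ndarray, ref_map: np.ndarray, mask: np.ndarray
) -> float:
    """Mean over the mask of |test - ref| / ref."""
    test = np.asarray(test_map, dtype=float)
    ref = np.asarray(ref_map, dtype=float)
    m = np.asarray(mask).astype(bool)
    _check_shapes(test, ref)
    _check_shapes(ref, m)
    if not m.any():
        raise ValueError("mask is empty")
    if np.any(ref[m] <= 0):
        raise ValueError("reference map must be positive inside the mask")
    return float(np.mean(np.abs(test[m] - ref[m]) / ref[m]))


def per_lesion_stats(
    gt_mask: np.ndarray,
    pred_mask: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 2.0),
) -> pd.DataFrame:
    """Per-ground-truth-lesion volume, dice, predicted volume and detection.

    Volumes are in microliters (mm^3).  The per-lesion dice is computed
    between the component and the predicted voxels inside the component's
    bounding box dilated by 2 voxels — a local comparison so neighbouring
    lesions do not dilute each other.  The predicted volume sums the
    predicted components that overlap the lesion.
    """
    gt = np.asarray(gt_mask).astype(bool)
    pred = np.asarray(pred_mask).astype(bool)
    _check_shapes(gt, pred)
    voxel_ul = float(np.prod(voxel_size))
    labels, n = ndimage.label(gt, structure=_CONN26)
    pred_labels, _ = ndimage.label(pred, structure=_CONN26)
    rows = []
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        comp = labels == i
        box = tuple(
            slice(max(s.start - 2, 0), min(s.stop + 2, dim))
            for s, dim in zip(sl, gt.shape)
        )
        local_dice = dice(comp[box], pred[box])
        overlap_ids = np.unique(pred_labels[comp & pred])
        overlap_ids = overlap_ids[overlap_ids > 0]
        pred_vol = float(np.isin(pred_labels, overlap_ids).sum() * voxel_ul) if overlap_ids.size else 0.0
        rows.append(
            {
                "lesion_id": i,
                "volume_ul": float(comp.sum() * voxel_ul),
                "dice": local_dice,
                "predicted_volume_ul": pred_vol,
                "detected": bool(np.any(comp & pred)),
            }
        )
    return pd.DataFrame(
        rows, columns=["lesion_id", "volume_ul", "dice", "predicted_volume_ul", "detected"]
    )


def lesion_profile(
    t1_map: np.ndarray,
    t2s_map: np.ndarray,
    prob_map: np.ndarray,
    lesion_component: np.ndarray,
    nawm_mask: np.ndarray,
) -> dict:
    """Cross-section profiles of a single lesion.

    Computes voxel-wise percent increases of T1 and T2* relative to the mean
    over normal-appearing white matter, and extracts one horizontal and one
    vertical line (in-plane) through the lesion's centroid voxel, each as a
    DataFrame of (position, dt1_percent, dt2s_percent, probability).
    """
    comp = np.asarray(lesion_component).astype(bool)
    nawm = np.asarray(nawm_mask).astype(bool)
    _check_shapes(comp, nawm)
    if not nawm.any():
        raise ValueError("nawm_mask is empty")
    _, n = ndimage.label(comp, structure=_CONN26)
    if n != 1:
        raise ValueError(
            f"lesion_component has {n} connected components; pass exactly one "
            "(select a single label from scipy.ndimage.label first)"
        )
    t1_ref = float(t1_map[nawm].mean())
    t2s_ref = float(t2s_map[nawm].mean())
    dt1 = 100.0 * (np.asarray(t1_map, float) - t1_ref) / t1_ref
    dt2s = 100.0 * (np.asarray(t2s_map, float) - t2s_ref) / t2s_ref
    cx, cy, cz = (int(round(c)) for c in ndimage.center_of_mass(comp))

    def line(axis: str) -> pd.DataFrame:
        if axis == "horizontal":
            sel = (slice(None), cy, cz)
        else:
            sel = (cx, slice(None), cz)
        return pd.DataFrame(
            {
                "position": np.arange(comp.shape[0 if axis == "horizontal" else 1]),
                "dt1_percent": dt1[sel],
                "dt2s_percent": dt2s[sel],
                "probability": np.asarray(prob_map, float)[sel],
            }
        )

    return {
        "mean_nawm_t1_ms": t1_ref,
        "mean_nawm_t2s_ms": t2s_ref,
        "dt1_percent": dt1,
        "dt2s_percent": dt2s,
        "centroid": (cx, cy, cz),
        "horizontal": line("horizontal"),
        "vertical": line("vertical"),
    }
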