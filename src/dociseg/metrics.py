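"""Segmentation evaluation suite: Dice, IoU, Dice (non-empty), empty
penalty, balanced Dice, and the global operating-threshold sweep.

Dice (non-empty) is the mean Sørensen–Dice over images whose ground truth is
non-empty; the empty penalty is 1 − FP rate on tumor-absent images, where the
FP rate is the fraction of predicted-positive pixels within the evaluated
region; balanced Dice is the mean of those two aggregates.  Both-empty
masks score Dice = IoU = 1 (a correct empty prediction is perfect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _counts(pred: np.ndarray, true: np.ndarray) -> tuple[int, int, int]:
    pred = np.asarray(pred).astype(bool)
    true = np.asarray(true).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    return tp, fp, fn


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Sørensen–Dice coefficient 2TP / (2TP + FP + FN); both-empty → 1."""
    tp, fp, fn = _counts(pred_mask, true_mask)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def iou(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Jaccard index TP / (TP + FP + FN); both-empty → 1."""
    tp, fp, fn = _counts(pred_mask, true_mask)
    denom = tp + fp + fn
    return 1.0 if denom == 0 else tp / denom


def empty_penalty(pred_mask: np.ndarray, region_mask: np.ndarray) -> float:
    """1 − (predicted-positive pixels in region) / (region pixels)."""
    pred = np.asarray(pred_mask).astype(bool)
    region = np.asarray(region_mask).astype(bool)
    if pred.shape != region.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {region.shape}")
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError("evaluated region is empty")
    return 1.0 - int((pred & region).sum()) / n_region


def balanced_dice(dice_nonempty: float, empty_pen: float) -> float:
    """Mean of Dice (non-empty) and the empty penalty."""
    return (dice_nonempty + empty_pen) / 2.0


@dataclass
class MetricsReport:
    dice_nonempty: float | None
    empty_penalty: float | None
    balanced_dice: float
    threshold: float
    per_image: list[dict] = field(default_factory=list)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "dice_nonempty": self.dice_nonempty,
            "empty_penalty": self.empty_penalty,
            "balanced_dice": self.balanced_dice,
            "threshold": self.threshold,
            "degenerate": self.degenerate,
        }


@dataclass
class OperatingPoint:
    t_star: float
    grid: np.ndarray
    criterion: np.ndarray  # mean Dice per grid point


def _as_region(region_masks, i, shape):
    if region_masks is None:
        return np.ones(shape, dtype=bool)
    return np.asarray(region_masks[i]).astype(bool)


def evaluate_split(
    prob_maps,
    true_masks,
    threshold: float,
    region_masks=None,
) -> MetricsReport:
    """Threshold probability maps and compute the aggregate metric triple.

    ``prob_maps`` is a sequence of H×W tumor-probability maps (NaN treated as
    0), ``true_masks`` the aligned binary ground truths and ``region_masks``
    (optional, e.g. tissue masks) the region over which the empty penalty's
    FP rate is measured.  If the split has no empty (or no non-empty) images
    the balanced Dice equals the defined component and the report is flagged
    degenerate.
    """
    if len(prob_maps) == 0 or len(prob_maps) != len(true_masks):
        raise ValueError("prob_maps and true_masks must be nonempty and aligned")
    dices, penalties, per_image = [], [], []
    for i, (pm, tm) in enumerate(zip(prob_maps, true_masks)):
        pm = np.nan_to_num(np.asarray(pm, dtype=float), nan=0.0)
        pred = pm >= threshold
        true = np.asarray(tm).astype(bool)
        region = _as_region(region_masks, i, pm.shape)
        rec = {"index": i, "nonempty": bool(true.any())}
        if true.any():
            rec["dice"] = dice(pred, true)
            dices.append(rec["dice"])
        else:
            rec["empty_penalty"] = empty_penalty(pred, region)
            penalties.append(rec["empty_penalty"])
        per_image.append(rec)
    dn = float(np.mean(dices)) if dices else None
    ep = float(np.mean(penalties)) if penalties else None
    if dn is not None and ep is not None:
        bd, degenerate = balanced_dice(dn, ep), False
    else:
        bd, degenerate = (dn if dn is not None else ep), True
    return MetricsReport(
        dice_nonempty=dn,
        empty_penalty=ep,
        balanced_dice=bd,
        threshold=threshold,
        per_image=per_image,
        degenerate=degenerate,
    )


def default_threshold_grid() -> np.ndarray:
    return np.linspace(0.2, 0.9, 15)


def select_threshold(
    prob_maps_val,
    true_masks_val,
    grid: np.ndarray | None = None,
) -> OperatingPoint:
    """Pick the global threshold t* maximizing mean validation Dice.

    Mean Dice is taken over all validation images with the both-empty → 1
    convention; ties resolve to the smallest threshold.
    """
    grid = default_threshold_grid() if grid is None else np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    maps = [np.nan_to_num(np.asarray(p, float), nan=0.0) for p in prob_maps_val]
    trues = [np.asarray(t).astype(bool) for t in true_masks_val]
    crit = np.empty(grid.size)
    for j, t in enumerate(grid):
        crit[j] = np.mean([dice(pm >= t, tm) for pm, tm in zip(maps, trues)])
    best = int(np.argmax(crit))  # argmax returns the first (smallest t) tie
    return OperatingPoint(t_star=float(grid[best]), grid=grid, criterion=crit)
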