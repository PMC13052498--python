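"""Permutation-based spectral channel importance and reduced-subset selection.

A trained segmenter is evaluated on the validation set with one channel at a
time disrupted by spatially permuting its pixels (independently per image),
which preserves the channel's global intensity distribution while destroying
spatial structure.  The drop in split-aggregate Dice/IoU relative to the
intact baseline (ΔDice_c, ΔIoU_c; positive = important), averaged over three
seeded repeats, ranks the channels; the top-k per model and the union across
models define the reduced spectral subset.  Channel zeroing is available as a
sanity-check disruption mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmodel import SEUNet
from .trainer import SegItem
from .voxelio import VoxelStack


def permute_channel(
    stack: VoxelStack, channel: int, rng: np.random.Generator
) -> VoxelStack:
    """Spatially permute one channel's values; all others stay bit-identical."""
    if not 0 <= channel < stack.n_channels:
        raise IndexError(
            f"channel {channel} out of range for {stack.n_channels} channels"
        )
    data = stack.data.copy()
    flat = data[:, :, channel].ravel()
    data[:, :, channel] = rng.permutation(flat).reshape(data.shape[:2])
    return VoxelStack(data, list(stack.channel_ids), stack.specimen_id)


def _permute_array_channel(
    x: np.ndarray, channel: int, rng: np.random.Generator
) -> np.ndarray:
    out = x.copy()
    flat = out[:, :, channel].ravel()
    out[:, :, channel] = rng.permutation(flat).reshape(out.shape[:2])
    return out


def _pooled_dice_iou(
    preds: np.ndarray, trues: np.ndarray
) -> tuple[float, float]:
    """Split-aggregate Dice/IoU from pixel counts pooled over all images."""
    p = preds.astype(bool)
    t = trues.astype(bool)
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    dice = 1.0 if 2 * tp + fp + fn == 0 else 2.0 * tp / (2 * tp + fp + fn)
    iou = 1.0 if tp + fp + fn == 0 else tp / (tp + fp + fn)
    return dice, iou


@dataclass
class ChannelImportance:
    delta_dice: np.ndarray          # (C,) mean baseline − disrupted
    delta_iou: np.ndarray
    baseline_dice: float
    baseline_iou: float
    ranking: np.ndarray             # channel indices, most important first
    n_repeats: int
    seed: int
    dice_per_repeat: np.ndarray = field(default=None)  # (C, n_repeats)

    @property
    def repeat_sd(self) -> np.ndarray:
        return self.dice_per_repeat.std(axis=1, ddof=1)


def _rank_channels(delta_dice: np.ndarray, delta_iou: np.ndarray) -> np.ndarray:
    order = np.lexsort(
        (np.arange(len(delta_dice)), -delta_iou, -delta_dice)
    )
    return order


def channel_importance(
    model: SEUNet,
    val_items: list[SegItem],
    t_star: float,
    n_repeats: int = 3,
    seed: int = 0,
    mode: str = "permute",
    batch_size: int = 8,
) -> ChannelImportance:
    """Measure per-channel importance of a trained model at threshold t*.

    ``mode`` is 'permute' (primary analysis) or 'zero' (sanity comparison).
    """
    if not hasattr(model, "forward"):
        raise ValueError("a trained SEUNet is required")
    if mode not in ("permute", "zero"):
        raise ValueError("mode must be 'permute' or 'zero'")
    x = np.stack([i.voxels for i in val_items])
    y = np.stack([i.tumor_mask for i in val_items])
    n_channels = x.shape[3]
    base_pred = model.predict(x, batch_size=batch_size) >= t_star
    baseline_dice, baseline_iou = _pooled_dice_iou(base_pred, y)
    dices = np.empty((n_channels, n_repeats))
    ious = np.empty((n_channels, n_repeats))
    for c in range(n_channels):
        for r in range(n_repeats):
            xa = x.copy()
            if mode == "permute":
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, c, r])
                )
                for i in range(len(xa)):
                    xa[i] = _permute_array_channel(xa[i], c, rng)
            else:
                xa[:, :, :, c] = 0.0
            pred = model.predict(xa, batch_size=batch_size) >= t_star
            dices[c, r], ious[c, r] = _pooled_dice_iou(pred, y)
            if mode == "zero":
                dices[c, 1:], ious[c, 1:] = dices[c, 0], ious[c, 0]
                break
    delta_dice = baseline_dice - dices.mean(axis=1)
    delta_iou = baseline_iou - ious.mean(axis=1)
    return ChannelImportance(
        delta_dice=delta_dice,
        delta_iou=delta_iou,
        baseline_dice=baseline_dice,
        baseline_iou=baseline_iou,
        ranking=_rank_channels(delta_dice, delta_iou),
        n_repeats=n_repeats,
        seed=seed,
        dice_per_repeat=dices,
    )


@dataclass
class ReducedSubset:
    channels: list[int]                    # sorted union
    per_model_top: dict[str, list[int]]    # model name -> its top-k list
    provenance: dict[int, list[str]]       # channel -> contributing models


def select_reduced_subset(
    importances: dict[str, ChannelImportance] | list[ChannelImportance],
    k: int = 6,
) -> ReducedSubset:
    """Union of the top-k channels of each model, in ascending channel order."""
    if isinstance(importances, list):
        importances = {f"model{i}": imp for i, imp in enumerate(importances)}
    per_model_top = {}
    for name, imp in importances.items():
        if k > len(imp.ranking):
            raise ValueError(
                f"k={k} exceeds channel count {len(imp.ranking)}"
            )
        per_model_top[name] = [int(c) for c in imp.ranking[:k]]
    union = sorted({c for top in per_model_top.values() for c in top})
    provenance = {
        c: sorted(n for n, top in per_model_top.items() if c in top)
        for c in union
    }
    return ReducedSubset(
        channels=union, per_model_top=per_model_top, provenance=provenance
    )


def slice_specimen_channels(specimens, channels: list[int]):
    """Slice every specimen's voxel stack to the given channel indices."""
    from copy import copy

    out = []
    for spec in specimens:
        for c in channels:
            if c >= spec.voxels.n_channels:
                raise IndexError(
                    f"channel {c} missing from specimen {spec.specimen_id}"
                )
        new = copy(spec)
        new.voxels = VoxelStack(
            spec.voxels.data[:, :, channels],
            [spec.voxels.channel_ids[c] for c in channels],
            spec.voxels.specimen_id,
        )
        out.append(new)
    return out


def retrain_reduced(
    specimens,
    subset: ReducedSubset,
    targets: tuple[str, ...] = ("papillary", "follicular"),
    **pipeline_kwargs,
):
    """Re-run gate fitting and segmentation training on reduced tensors.

    Slices all voxel stacks to the subset channels and repeats the full
    fitting procedure (identical pixel sampling, PCA with up to 8 components,
    feature construction, augmentation schedule, optimizer, loss and early
    stopping) from scratch.  Returns the same report structure as
    :func:`dociseg.pipeline.run_analysis`.
    """
    from .pipeline import run_analysis

    reduced = slice_specimen_channels(specimens, subset.channels)
    return run_analysis(reduced, targets=targets, **pipeline_kwargs)
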