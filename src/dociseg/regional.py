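"""Regional majority-vote gating: from pixel probability maps to a
specimen-level diagnosis, with confusion matrices and patient-level bootstrap
confidence intervals.

A sliding window is moved over the tissue region; a window with at least
``min_tissue_px`` tissue pixels is assigned a tumor class when at least
``dominance`` (default 85%) of its tissue pixels favor (argmax) that class.
A slide is called normal when no window fires, otherwise by the tumor class
present — ties between both tumor classes are broken by the larger
slide-wide fraction of tumor-predicted tissue pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .gate import ClassProbabilityMaps
from .voxelio import BinaryMask

GATE_CLASSES = ("normal", "follicular", "papillary")
_LABEL_TO_CLASS = {1: "follicular", 2: "papillary"}


@dataclass
class GateConfig:
    """Sliding-window majority filter parameters.

    The study operating range is a 45-64 px window with 20-32 px stride
    (defaults at the upper ends); smaller windows are valid for smaller
    images as long as ``window >= stride > 0``.
    """

    window_px: int = 64
    stride_px: int = 32
    min_tissue_px: int = 30
    dominance: float = 0.85

    def __post_init__(self):
        if not (self.window_px >= self.stride_px > 0):
            raise ValueError("require window_px >= stride_px > 0")
        if not (0.5 < self.dominance <= 1.0):
            raise ValueError("dominance must lie in (0.5, 1]")
        if self.min_tissue_px < 1:
            raise ValueError("min_tissue_px must be >= 1")


@dataclass
class WindowCall:
    row: int
    col: int
    call: str  # 'follicular', 'papillary', or 'no-call'
    n_tissue: int


@dataclass
class SpecimenCall:
    predicted_class: str
    tumor_fraction_F: float
    tumor_fraction_P: float
    window_calls: list[WindowCall] = field(default_factory=list)


@dataclass
class BootstrapCI:
    point_estimate: float
    lower: float
    upper: float
    n_reps: int = 2000
    percentiles: tuple[float, float] = (2.5, 97.5)
    seed: int = 0


def _window_starts(extent: int, window: int, stride: int) -> list[int]:
    if window >= extent:
        return [0]
    starts = list(range(0, extent - window + 1, stride))
    last = extent - window
    if starts[-1] != last:
        starts.append(last)  # flush window so the border is covered
    return starts


def window_majority_filter(
    prob_maps: ClassProbabilityMaps,
    tissue_mask: BinaryMask,
    config: GateConfig | None = None,
) -> list[WindowCall]:
    """Tile the slide and assign per-window tumor calls by argmax dominance."""
    config = config or GateConfig()
    h, w = tissue_mask.shape
    win = config.window_px
    if win > h or win > w:
        warnings.warn(
            "window larger than image; using a single whole-image window"
        )
    labels = prob_maps.argmax_labels()  # -1 bg, 0 N, 1 F, 2 P
    tis = tissue_mask.data.astype(bool)
    calls = []
    for r0 in _window_starts(h, win, config.stride_px):
        for c0 in _window_starts(w, win, config.stride_px):
            sub_t = tis[r0 : r0 + win, c0 : c0 + win]
            n_tis = int(sub_t.sum())
            if n_tis < config.min_tissue_px:
                continue
            sub_l = labels[r0 : r0 + win, c0 : c0 + win][sub_t]
            call = "no-call"
            for lab, cls in _LABEL_TO_CLASS.items():
                if (sub_l == lab).sum() / n_tis >= config.dominance:
                    call = cls
                    break
            calls.append(WindowCall(row=r0, col=c0, call=call, n_tissue=n_tis))
    return calls


def specimen_call(
    window_calls: list[WindowCall],
    prob_maps: ClassProbabilityMaps,
    tissue_mask: BinaryMask,
) -> SpecimenCall:
    """Aggregate window calls into a slide-level diagnosis.

    Tumor fractions are computed over all tissue pixels (slide-wide argmax),
    not only pixels inside tumor-called windows.  An exact F/P fraction tie
    resolves to follicular with a warning.
    """
    labels = prob_maps.argmax_labels()
    tis = tissue_mask.data.astype(bool)
    n_tis = max(int(tis.sum()), 1)
    frac_f = float((labels[tis] == 1).sum()) / n_tis
    frac_p = float((labels[tis] == 2).sum()) / n_tis
    called = {c.call for c in window_calls if c.call != "no-call"}
    if not called:
        pred = "normal"
    elif called == {"follicular"}:
        pred = "follicular"
    elif called == {"papillary"}:
        pred = "papillary"
    else:
        if frac_f == frac_p:
            warnings.warn("exact tumor-fraction tie; calling follicular")
            pred = "follicular"
        else:
            pred = "papillary" if frac_p > frac_f else "follicular"
    return SpecimenCall(
        predicted_class=pred,
        tumor_fraction_F=frac_f,
        tumor_fraction_P=frac_p,
        window_calls=window_calls,
    )


def gate_specimen(
    prob_maps: ClassProbabilityMaps,
    tissue_mask: BinaryMask,
    config: GateConfig | None = None,
) -> SpecimenCall:
    """Convenience: window filter + slide-level aggregation."""
    calls = window_majority_filter(prob_maps, tissue_mask, config)
    return specimen_call(calls, prob_maps, tissue_mask)


def confusion_and_accuracy(
    calls: list[str], truths: list[str]
) -> tuple[np.ndarray, float]:
    """3×3 confusion matrix (rows = truth, cols = call, N/F/P order) and
    accuracy = trace / total."""
    if len(calls) == 0 or len(calls) != len(truths):
        raise ValueError("calls and truths must be nonempty and aligned")
    for v in list(calls) + list(truths):
        if v not in GATE_CLASSES:
            raise ValueError(f"label {v!r} outside {GATE_CLASSES}")
    cm = _sk_confusion(truths, calls, labels=list(GATE_CLASSES))
    acc = float(np.trace(cm)) / float(cm.sum())
    return cm, acc


def _nearest_rank(sorted_vals: np.ndarray, pct: float) -> float:
    n = len(sorted_vals)
    k = int(np.ceil(pct / 100.0 * n))
    k = min(max(k, 1), n)
    return float(sorted_vals[k - 1])


def bootstrap_accuracy_ci(
    per_patient_outcomes: list[list[bool]],
    n_reps: int = 2000,
    seed: int = 0,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> BootstrapCI:
    """Patient-level bootstrap CI for slide-level accuracy.

    Each patient contributes a list of per-slide correct/incorrect flags.
    Patients are resampled with replacement ``n_reps`` times; per replicate
    the accuracy over the aggregated slides is recorded, and the CI is the
    empirical (2.5, 97.5) percentile pair (nearest rank).
    """
    if len(per_patient_outcomes) == 0:
        raise ValueError("at least one patient required")
    correct = np.array([sum(map(bool, o)) for o in per_patient_outcomes], float)
    total = np.array([len(o) for o in per_patient_outcomes], float)
    if np.any(total == 0):
        raise ValueError("each patient needs at least one slide")
    n_pat = len(total)
    point = correct.sum() / total.sum()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_pat, size=(n_reps, n_pat))
    accs = correct[idx].sum(axis=1) / total[idx].sum(axis=1)
    accs.sort()
    lower = _nearest_rank(accs, percentiles[0])
    upper = _nearest_rank(accs, percentiles[1])
    return BootstrapCI(
        point_estimate=float(point),
        lower=lower,
        upper=upper,
        n_reps=n_reps,
        percentiles=percentiles,
        seed=seed,
    )
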