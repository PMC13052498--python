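import numpy as np
import pytest
from scipy.stats import binom

from dociseg.gate import ClassProbabilityMaps
from dociseg.regional import (
    GateConfig,
    bootstrap_accuracy_ci,
    confusion_and_accuracy,
    gate_specimen,
    specimen_call,
    window_majority_filter,
)
from dociseg.voxelio import BinaryMask


def maps_from_labels(labels: np.ndarray, tissue: np.ndarray) -> ClassProbabilityMaps:
    """Hard one-hot probability maps from a 0/1/2 label image."""
    h, w = labels.shape
    stack = np.zeros((h, w, 3))
    for k in range(3):
        stack[:, :, k] = (labels == k).astype(float)
    return ClassProbabilityMaps(
        P_N=stack[:, :, 0], P_F=stack[:, :, 1], P_P=stack[:, :, 2],
        tissue_mask=BinaryMask(tissue, role="tissue"),
    )


def test_gate_config_validation():
    GateConfig(window_px=24, stride_px=12)  # smaller windows are valid
    with pytest.raises(ValueError):
        GateConfig(window_px=10, stride_px=20)
    with pytest.raises(ValueError):
        GateConfig(stride_px=0)
    with pytest.raises(ValueError):
        GateConfig(dominance=0.4)
    with pytest.raises(ValueError):
        GateConfig(min_tissue_px=0)


def test_window_filter_all_normal_gives_no_tumor_call():
    tissue = np.ones((32, 32), np.uint8)
    labels = np.zeros((32, 32), int)  # all normal
    maps = maps_from_labels(labels, tissue)
    cfg = GateConfig(window_px=16, stride_px=8, min_tissue_px=10)
    calls = window_majority_filter(maps, maps.tissue_mask, cfg)
    assert calls and all(c.call == "no-call" for c in calls)
    assert specimen_call(calls, maps, maps.tissue_mask).predicted_class == "normal"


def test_window_filter_detects_dominant_tumor():
    tissue = np.ones((32, 32), np.uint8)
    labels = np.zeros((32, 32), int)
    labels[:16, :16] = 2  # pure papillary quadrant
    maps = maps_from_labels(labels, tissue)
    cfg = GateConfig(window_px=16, stride_px=16, min_tissue_px=10)
    call = gate_specimen(maps, maps.tissue_mask, cfg)
    assert call.predicted_class == "papillary"
    assert call.tumor_fraction_P == pytest.approx(256 / 1024)


def test_dominance_threshold_is_respected():
    """80% papillary in every window with dominance=0.85 -> normal slide."""
    tissue = np.ones((20, 20), np.uint8)
    labels = np.zeros((20, 20), int)
    labels[:16, :] = 2  # 80% of each full-image window
    maps = maps_from_labels(labels, tissue)
    cfg = GateConfig(window_px=20, stride_px=20, min_tissue_px=10)
    assert gate_specimen(maps, maps.tissue_mask, cfg).predicted_class == "normal"


def test_windows_cover_borders():
    """A tumor flush against the far border is still seen (flush window)."""
    tissue = np.ones((30, 30), np.uint8)
    labels = np.zeros((30, 30), int)
    labels[18:, 18:] = 1  # 12x12 follicular block at the far corner
    maps = maps_from_labels(labels, tissue)
    cfg = GateConfig(window_px=12, stride_px=8, min_tissue_px=10)
    call = gate_specimen(maps, maps.tissue_mask, cfg)
    assert call.predicted_class == "follicular"


def test_oversized_window_warns_and_uses_whole_image():
    tissue = np.ones((8, 8), np.uint8)
    labels = np.full((8, 8), 2)
    maps = maps_from_labels(labels, tissue)
    with pytest.warns(UserWarning, match="window larger"):
        calls = window_majority_filter(maps, maps.tissue_mask,
                                       GateConfig(window_px=16, stride_px=8))
    assert len(calls) == 1 and calls[0].call == "papillary"


def test_mixed_tumor_tie_break_by_slide_fraction():
    tissue = np.ones((32, 32), np.uint8)
    labels = np.zeros((32, 32), int)
    labels[:16, :16] = 1            # follicular window
    labels[:16, 16:] = 2            # papillary window
    labels[16:, :8] = 2             # extra papillary pixels (no window fires)
    maps = maps_from_labels(labels, tissue)
    cfg = GateConfig(window_px=16, stride_px=16, min_tissue_px=10)
    call = gate_specimen(maps, maps.tissue_mask, cfg)
    assert call.predicted_class == "papillary"
    assert call.tumor_fraction_P > call.tumor_fraction_F


def test_exact_tie_warns_follicular():
    tissue = np.ones((32, 32), np.uint8)
    labels = np.zeros((32, 32), int)
    labels[:16, :16] = 1
    labels[:16, 16:] = 2  # exactly equal F and P fractions
    maps = maps_from_labels(labels, tissue)
    cfg = GateConfig(window_px=16, stride_px=16, min_tissue_px=10)
    with pytest.warns(UserWarning, match="tie"):
        call = gate_specimen(maps, maps.tissue_mask, cfg)
    assert call.predicted_class == "follicular"


def test_confusion_and_accuracy_layout():
    truths = ["normal", "follicular", "papillary"]
    calls = ["normal", "papillary", "papillary"]
    cm, acc = confusion_and_accuracy(calls, truths)
    assert cm.shape == (3, 3)
    assert cm[0, 0] == 1          # normal -> normal
    assert cm[1, 2] == 1          # follicular -> papillary
    assert acc == pytest.approx(2 / 3)


def test_confusion_rejects_bad_input():
    with pytest.raises(ValueError):
        confusion_and_accuracy([], [])
    with pytest.raises(ValueError):
        confusion_and_accuracy(["normal"], ["weird"])


def test_bootstrap_point_estimate_and_bounds():
    outcomes = [[True]] * 12 + [[False]]
    ci = bootstrap_accuracy_ci(outcomes, seed=0)
    assert ci.point_estimate == pytest.approx(12 / 13)
    assert 0.0 <= ci.lower <= ci.point_estimate <= ci.upper <= 1.0


def test_bootstrap_matches_binomial_oracle():
    """Single-slide patients: the bootstrap accuracy is Binomial(n, p)/n, so
    the percentile endpoints must match the exact binomial quantiles."""
    n, correct = 13, 12
    ci = bootstrap_accuracy_ci([[True]] * correct + [[False]], seed=0)
    lo = binom.ppf(0.025, n, correct / n) / n
    hi = binom.ppf(0.975, n, correct / n) / n
    assert ci.lower == pytest.approx(lo)
    assert ci.upper == pytest.approx(hi)


def test_bootstrap_degenerate_cases():
    all_right = bootstrap_accuracy_ci([[True]] * 12, seed=0)
    assert (all_right.lower, all_right.upper) == (1.0, 1.0)
    all_wrong = bootstrap_accuracy_ci([[False]] * 5, seed=0)
    assert (all_wrong.lower, all_wrong.upper) == (0.0, 0.0)


def test_bootstrap_seed_reproducible():
    outcomes = [[True, False], [True], [True, True, False]]
    a = bootstrap_accuracy_ci(outcomes, seed=7)
    b = bootstrap_accuracy_ci(outcomes, seed=7)
    assert (a.lower, a.upper) == (b.lower, b.upper)


def test_bootstrap_rejects_empty():
    with pytest.raises(ValueError):
        bootstrap_accuracy_ci([])
    with pytest.raises(ValueError):
        bootstrap_accuracy_ci([[True], []])
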