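"""Gate-driven dataset assembly, synchronized voxel-only augmentation and
SE-UNet training orchestration.

Only slides the regional gate categorized as normal or as the target tumor
class enter a target-specific training set (atypical slides optionally join
when the gate called them the target class).  Augmentation applies one random
combination of flips, ±15° rotation and [0.90, 1.10] isotropic zoom
synchronously to voxels, tissue map ("cutoff volume") and tumor mask —
bilinear for voxels, nearest-neighbor for masks, zero fill — followed by
crop/pad to the working resolution; additive Gaussian noise (σ = 0.001 on
[0, 1]-normalized voxels) touches voxels only.  Tumor-containing images
receive four augmented instances each, empty-mask images one; validation and
test data are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .nn import Adam
from .segmodel import (
    HybridLossConfig,
    SegModelConfig,
    SEUNet,
    TverskyParams,
    build_se_unet,
    hybrid_grad,
    hybrid_loss,
    w_pos_from_prevalence,
)


@dataclass
class AugmentConfig:
    allow_flips: bool = True
    rotation_range: float = 15.0          # degrees, uniform in ±range
    zoom_range: tuple[float, float] = (0.90, 1.10)
    noise_sd: float = 0.001               # on [0,1]-normalized voxels only
    augs_per_positive: int = 4
    augs_per_empty: int = 1
    output_size: int = 256
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.zoom_range
        if not (lo <= 1.0 <= hi):
            raise ValueError("zoom_range must contain 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.augs_per_positive < 0 or self.augs_per_empty < 0:
            raise ValueError("augmentation counts must be >= 0")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3   # Adam
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 8
    restore_best: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


@dataclass
class SegItem:
    """One assembled training example: voxels + label + tissue map."""

    specimen_id: str
    voxels: np.ndarray        # H×W×C
    tumor_mask: np.ndarray    # H×W {0,1}
    tissue_mask: np.ndarray   # H×W {0,1}


def assemble_gated_dataset(
    specimens,
    gate_calls: dict[str, str],
    target: str,
    include_atypical_if_gated: bool = False,
) -> list[SegItem]:
    """Retain slides gated normal or gated as the target tumor class.

    Label masks come from pathology annotations of retained slides; masks of
    non-target tumor classes never enter (such slides contribute empty
    labels).  Atypical slides join only when the flag is set and the gate
    called them the target class.
    """
    if target not in ("papillary", "follicular"):
        raise ValueError("target must be 'papillary' or 'follicular'")
    items: list[SegItem] = []
    for spec in specimens:
        call = gate_calls.get(spec.specimen_id)
        if call is None:
            raise ValueError(f"no gate call for specimen {spec.specimen_id}")
        if spec.true_class == "atypical":
            if not (include_atypical_if_gated and call == target):
                continue
        elif call not in ("normal", target):
            continue
        use_mask = spec.true_class == target or (
            spec.true_class == "atypical" and include_atypical_if_gated
        )
        tumor = (
            spec.tumor_mask.data.copy()
            if use_mask
            else np.zeros(spec.tumor_mask.shape, dtype=np.uint8)
        )
        items.append(
            SegItem(
                specimen_id=spec.specimen_id,
                voxels=spec.voxels.data.copy(),
                tumor_mask=tumor,
                tissue_mask=spec.tissue_mask.data.copy(),
            )
        )
    if not items:
        raise ValueError(f"gated dataset for target {target!r} is empty")
    return items


@dataclass
class GeometricDraw:
    flip_h: bool
    flip_v: bool
    angle_deg: float
    zoom: float


def draw_geometry(config: AugmentConfig, rng: np.random.Generator) -> GeometricDraw:
    return GeometricDraw(
        flip_h=config.allow_flips and bool(rng.random() < 0.5),
        flip_v=config.allow_flips and bool(rng.random() < 0.5),
        angle_deg=float(rng.uniform(-config.rotation_range, config.rotation_range)),
        zoom=float(rng.uniform(*config.zoom_range)),
    )


def _affine_params(shape: tuple[int, int], geom: GeometricDraw):
    th = np.deg2rad(geom.angle_deg)
    # output -> input map: p_in = center + (1/z) R(-th) (p_out - center)
    rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
    m = rot / geom.zoom
    center = (np.asarray(shape, float) - 1.0) / 2.0
    offset = center - m @ center
    return m, offset


def _apply_geometry(img: np.ndarray, geom: GeometricDraw, order: int) -> np.ndarray:
    if geom.flip_v:
        img = img[::-1]
    if geom.flip_h:
        img = img[:, ::-1]
    if geom.angle_deg == 0.0 and geom.zoom == 1.0:
        return np.ascontiguousarray(img)
    m, offset = _affine_params(img.shape[:2], geom)
    if img.ndim == 3:
        m3 = np.eye(3)
        m3[:2, :2] = m
        off3 = np.array([offset[0], offset[1], 0.0])
        return ndimage.affine_transform(
            img, m3, offset=off3, order=order, mode="constant", cval=0.0
        )
    return ndimage.affine_transform(
        img, m, offset=offset, order=order, mode="constant", cval=0.0
    )


def _crop_or_pad(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[:2]
    out_shape = (size, size) + img.shape[2:]
    out = np.zeros(out_shape, dtype=img.dtype)
    r0 = max((h - size) // 2, 0)
    c0 = max((w - size) // 2, 0)
    o0 = max((size - h) // 2, 0)
    o1 = max((size - w) // 2, 0)
    hh, ww = min(h, size), min(w, size)
    out[o0 : o0 + hh, o1 : o1 + ww] = img[r0 : r0 + hh, c0 : c0 + ww]
    return out


def augment_instance(
    voxels: np.ndarray,
    tumor_mask: np.ndarray,
    tissue_mask: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
    geom: GeometricDraw | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One synchronized augmented (voxels, tumor, tissue) triple.

    The identical geometric transform is applied to all three inputs; noise
    is then added to the voxels only, which stay clipped to [0, 1]; masks
    remain exactly binary.
    """
    geom = geom or draw_geometry(config, rng)
    vox = _apply_geometry(voxels.astype(float), geom, order=1)
    tum = _apply_geometry(tumor_mask.astype(float), geom, order=0)
    tis = _apply_geometry(tissue_mask.astype(float), geom, order=0)
    size = config.output_size
    vox = _crop_or_pad(vox, size)
    tum = _crop_or_pad(tum, size)
    tis = _crop_or_pad(tis, size)
    if config.noise_sd > 0:
        vox = vox + rng.standard_normal(vox.shape) * config.noise_sd
    vox = np.clip(vox, 0.0, 1.0)
    return vox, (tum > 0.5).astype(np.uint8), (tis > 0.5).astype(np.uint8)


def build_training_stream(
    dataset: list[SegItem], config: AugmentConfig | None = None
) -> list[SegItem]:
    """Expand the assembled dataset into augmented training instances.

    Positives yield ``augs_per_positive`` instances each, empty-mask images
    ``augs_per_empty``.  Evaluation data must never pass through here.
    """
    config = config or AugmentConfig()
    rng = np.random.default_rng(config.seed)
    out: list[SegItem] = []
    for item in dataset:
        n = (
            config.augs_per_positive
            if item.tumor_mask.any()
            else config.augs_per_empty
        )
        for j in range(n):
            vox, tum, tis = augment_instance(
                item.voxels, item.tumor_mask, item.tissue_mask, config, rng
            )
            out.append(
                SegItem(f"{item.specimen_id}_aug{j}", vox, tum, tis)
            )
    return out


def dataset_prevalence(dataset: list[SegItem]) -> float:
    """Tumor-pixel fraction over the assembled training masks."""
    pos = sum(int(i.tumor_mask.sum()) for i in dataset)
    tot = sum(i.tumor_mask.size for i in dataset)
    return pos / tot if tot else 0.0


def train_segmenter(
    model: SEUNet,
    train_stream: list[SegItem],
    val_set: list[SegItem] | None,
    loss_cfg: HybridLossConfig | None = None,
    train_cfg: TrainConfig | None = None,
    tversky: TverskyParams | None = None,
) -> tuple[SEUNet, dict]:
    """Minimize the hybrid loss with Adam and early stopping.

    Early stopping monitors the validation hybrid loss (training loss when no
    validation set is given) with the configured patience, restoring the best
    weights.  Returns the model and a per-epoch loss history.
    """
    loss_cfg = loss_cfg or HybridLossConfig()
    train_cfg = train_cfg or TrainConfig()
    tversky = tversky or TverskyParams()
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    if train_cfg.max_epochs == 0:
        return model, history
    x_tr = np.stack([i.voxels for i in train_stream])
    y_tr = np.stack([i.tumor_mask.astype(float) for i in train_stream])
    if val_set:
        x_val = np.stack([i.voxels for i in val_set])
        y_val = np.stack([i.tumor_mask.astype(float) for i in val_set])
    opt = Adam(model.params(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    best_loss, best_weights, best_bn, wait = np.inf, None, None, 0
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), train_cfg.batch_size):
            idx = order[i : i + train_cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            probs = model.forward(xb, training=True)[..., 0]
            loss = hybrid_loss(probs, yb, loss_cfg, tversky)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            losses.append(loss)
            g = hybrid_grad(probs, yb, loss_cfg, tversky)[..., None]
            opt.zero_grad()
            model.backward(g)
            opt.step()
        train_loss = float(np.mean(losses))
        history["train_loss"].append(train_loss)
        if val_set:
            val_probs = model.predict(x_val, batch_size=train_cfg.batch_size)
            monitor = hybrid_loss(val_probs, y_val, loss_cfg, tversky)
            history["val_loss"].append(float(monitor))
        else:
            monitor = train_loss
        if monitor < best_loss - 1e-9:
            best_loss = monitor
            wait = 0
            if train_cfg.restore_best:
                best_weights = model.get_weights()
                best_bn = [
                    (l.running_mean.copy(), l.running_var.copy())
                    for l in model._all_layers()
                    if l.__class__.__name__ == "BatchNorm"
                ]
        else:
            wait += 1
            if wait >= train_cfg.patience:
                break
    if train_cfg.restore_best and best_weights is not None:
        model.set_weights(best_weights)
        bn_layers = [
            l for l in model._all_layers()
            if l.__class__.__name__ == "BatchNorm"
        ]
        for layer, (rm, rv) in zip(bn_layers, best_bn):
            layer.running_mean, layer.running_var = rm, rv
    return model, history


class SEUNetSegmenter(BaseEstimator):
    """Sklearn-style wrapper around the SE-UNet training workflow.

    ``fit(X, y)`` takes image tensors ``X`` of shape (N, H, W, C) with [0, 1]
    voxel values and binary masks ``y`` of shape (N, H, W); augmentation,
    prevalence-derived BCE weighting, Adam training and early stopping run
    inside.  ``predict_proba`` returns probability maps, ``predict`` binary
    masks at the selected (or default 0.5) operating threshold.
    """

    def __init__(
        self,
        model_config: SegModelConfig | None = None,
        augment: AugmentConfig | None = None,
        train: TrainConfig | None = None,
        tversky: TverskyParams | None = None,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.model_config = model_config
        self.augment = augment
        self.train = train
        self.tversky = tversky
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None, tissue=None):
        X = np.asarray(X, float)
        y = np.asarray(y)
        n, h, w, c = X.shape
        cfg = self.model_config or SegModelConfig(input=(h, w, c))
        aug = self.augment or AugmentConfig(output_size=h, seed=self.random_state)
        tr = self.train or TrainConfig(seed=self.random_state)
        tis = (
            np.asarray(tissue)
            if tissue is not None
            else np.ones((n, h, w), dtype=np.uint8)
        )
        dataset = [
            SegItem(f"img{i}", X[i], y[i].astype(np.uint8), tis[i])
            for i in range(n)
        ]
        self.prevalence_ = dataset_prevalence(dataset)
        self.w_pos_ = w_pos_from_prevalence(self.prevalence_)
        loss_cfg = HybridLossConfig(w_pos=self.w_pos_)
        stream = build_training_stream(dataset, aug)
        val_set = None
        if X_val is not None:
            X_val = np.asarray(X_val, float)
            y_val = np.asarray(y_val)
            val_set = [
                SegItem(
                    f"val{i}", X_val[i], y_val[i].astype(np.uint8),
                    np.ones((h, w), np.uint8),
                )
                for i in range(len(X_val))
            ]
        model = build_se_unet(cfg, seed=self.random_state)
        self.model_, self.history_ = train_segmenter(
            model, stream, val_set, loss_cfg, tr, self.tversky
        )
        self.threshold_ = self.threshold
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValueError("SEUNetSegmenter is not fitted")
        return self.model_.predict(np.asarray(X, float))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold_).astype(np.uint8)

    def set_operating_threshold(self, t_star: float) -> "SEUNetSegmenter":
        self.threshold_ = float(t_star)
        return self
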