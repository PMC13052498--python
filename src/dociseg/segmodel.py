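"""Squeeze-and-excitation U-Net and the hybrid imbalance-aware loss.

The network maps an H×W×C voxel tensor to a single-channel sigmoid tumor
probability map.  Each encoder stage applies paired 3×3 convolutions with
batch normalization and ReLU, squeeze-and-excitation in stages with at least
``se_min_channels`` channels, spatial dropout, and a strided 3×3 downsampling
convolution; the bottleneck adds 20% dropout; the decoder mirrors the encoder
with 2× nearest-neighbor upsampling, skip concatenation and paired
convolutions, ending in a 1×1 convolution with sigmoid.

Training minimizes ``L = 0.5 L_wBCE + 0.5 L_Focal-Tversky`` with the Tversky
index ``TI = TP / (TP + α FN + β FP)``, α = 0.7, β = 0.3, focal exponent
γ = 0.75, and a BCE positive-class weight ``min(1/prevalence, 5)``.  Inside
the loss TP/FP/FN are soft (probabilistic) counts; hard counts are used only
at evaluation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn


@dataclass
class SegModelConfig:
    input: tuple[int, int, int] = (256, 256, 23)
    encoder_filters: tuple[int, ...] = (32, 64, 128, 256, 512)
    se_min_channels: int = 128
    bottleneck_filters: int = 1024
    bottleneck_dropout: float = 0.20
    encoder_spatial_dropout: float = 0.10
    se_reduction: int = 16

    def __post_init__(self):
        f = self.encoder_filters
        if any(f[i] >= f[i + 1] for i in range(len(f) - 1)):
            raise ValueError("encoder_filters must be strictly increasing")
        for r in (self.bottleneck_dropout, self.encoder_spatial_dropout):
            if not 0.0 <= r < 1.0:
                raise ValueError("dropout rates must lie in [0, 1)")
        h, w, _ = self.input
        div = 2 ** len(f)
        if h % div or w % div:
            raise ValueError(
                f"input H and W must be divisible by 2^{len(f)} = {div}"
            )

    @property
    def n_stages(self) -> int:
        return len(self.encoder_filters)


@dataclass
class TverskyParams:
    alpha: float = 0.7
    beta: float = 0.3
    gamma: float = 0.75
    smooth: float = 1e-6

    def __post_init__(self):
        if not np.isclose(self.alpha + self.beta, 1.0):
            raise ValueError("alpha + beta must equal 1")
        if self.gamma <= 0 or self.smooth <= 0:
            raise ValueError("gamma and smooth must be positive")


@dataclass
class HybridLossConfig:
    mix: tuple[float, float] = (0.5, 0.5)   # (wBCE, Focal-Tversky)
    w_pos: float = 1.0

    def __post_init__(self):
        if not np.isclose(sum(self.mix), 1.0):
            raise ValueError("mix weights must sum to 1")
        if not 1.0 <= self.w_pos <= 5.0:
            raise ValueError("w_pos must lie in [1, 5]")


def w_pos_from_prevalence(prevalence: float, cap: float = 5.0) -> float:
    """Positive-class BCE weight: 1/prevalence capped at 5."""
    if prevalence <= 0:
        return cap
    return float(min(1.0 / prevalence, cap))


def _batched(probs: np.ndarray, truth: np.ndarray):
    p = np.asarray(probs, dtype=float)
    y = np.asarray(truth, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if p.ndim == 2:
        p, y = p[None], y[None]
    return p.reshape(p.shape[0], -1), y.reshape(y.shape[0], -1)


def focal_tversky_loss(
    probs: np.ndarray, truth: np.ndarray, params: TverskyParams | None = None
) -> float:
    """(1 − TI)^γ with soft per-image counts, averaged over the batch."""
    params = params or TverskyParams()
    p, y = _batched(probs, truth)
    tp = (p * y).sum(axis=1)
    fn = ((1 - p) * y).sum(axis=1)
    fp = (p * (1 - y)).sum(axis=1)
    ti = (tp + params.smooth) / (
        tp + params.alpha * fn + params.beta * fp + params.smooth
    )
    return float(np.mean((1.0 - ti) ** params.gamma))


def focal_tversky_grad(
    probs: np.ndarray, truth: np.ndarray, params: TverskyParams | None = None
) -> np.ndarray:
    """d(loss)/d(probs) for the focal-Tversky loss (same shape as probs)."""
    params = params or TverskyParams()
    orig_shape = np.asarray(probs).shape
    p, y = _batched(probs, truth)
    n = p.shape[0]
    tp = (p * y).sum(axis=1, keepdims=True)
    fn = ((1 - p) * y).sum(axis=1, keepdims=True)
    fp = (p * (1 - y)).sum(axis=1, keepdims=True)
    num = tp + params.smooth
    den = tp + params.alpha * fn + params.beta * fp + params.smooth
    ti = num / den
    # d(den)/dp_i = y - alpha*y + beta*(1-y); d(num)/dp_i = y
    dden = y - params.alpha * y + params.beta * (1 - y)
    dti = (y * den - num * dden) / den**2
    one_minus = np.maximum(1.0 - ti, 1e-12)
    dl_dti = -params.gamma * one_minus ** (params.gamma - 1.0)
    return (dl_dti * dti / n).reshape(orig_shape)


def weighted_bce_loss(
    probs: np.ndarray, truth: np.ndarray, w_pos: float = 1.0, eps: float = 1e-7
) -> float:
    """Mean over pixels of −[w_pos·y·log p + (1−y)·log(1−p)]."""
    p, y = _batched(probs, truth)
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.mean(-(w_pos * y * np.log(p) + (1 - y) * np.log(1 - p))))


def weighted_bce_grad(
    probs: np.ndarray, truth: np.ndarray, w_pos: float = 1.0, eps: float = 1e-7
) -> np.ndarray:
    orig_shape = np.asarray(probs).shape
    p, y = _batched(probs, truth)
    pc = np.clip(p, eps, 1.0 - eps)
    g = (-w_pos * y / pc + (1 - y) / (1 - pc)) / p.size
    g[(p < eps) | (p > 1 - eps)] = 0.0
    return g.reshape(orig_shape)


def hybrid_loss(
    probs: np.ndarray,
    truth: np.ndarray,
    cfg: HybridLossConfig | None = None,
    params: TverskyParams | None = None,
) -> float:
    cfg = cfg or HybridLossConfig()
    return cfg.mix[0] * weighted_bce_loss(probs, truth, cfg.w_pos) + cfg.mix[
        1
    ] * focal_tversky_loss(probs, truth, params)


def hybrid_grad(
    probs: np.ndarray,
    truth: np.ndarray,
    cfg: HybridLossConfig | None = None,
    params: TverskyParams | None = None,
) -> np.ndarray:
    cfg = cfg or HybridLossConfig()
    return cfg.mix[0] * weighted_bce_grad(probs, truth, cfg.w_pos) + cfg.mix[
        1
    ] * focal_tversky_grad(probs, truth, params)


class SEUNet:
    """The SE-UNet network itself (see module docstring for the topology)."""

    def __init__(self, config: SegModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        self.dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        f = config.encoder_filters
        cin = config.input[2]

        def conv_bn_relu(ci, co, k=3, stride=1):
            return [
                nn.Conv2D(ci, co, k=k, stride=stride, rng=rng),
                nn.BatchNorm(co),
                nn.ReLU(),
            ]

        self.enc_blocks: list[list[nn.Layer]] = []
        self.down_blocks: list[list[nn.Layer]] = []
        prev = cin
        for fi in f:
            block = conv_bn_relu(prev, fi) + conv_bn_relu(fi, fi)
            if fi >= config.se_min_channels:
                block.append(nn.SEBlock(fi, config.se_reduction, rng=rng))
            if config.encoder_spatial_dropout > 0:
                block.append(
                    nn.SpatialDropout(config.encoder_spatial_dropout,
                                      rng=self.dropout_rng)
                )
            self.enc_blocks.append(block)
            self.down_blocks.append(conv_bn_relu(fi, fi, stride=2))
            prev = fi

        bf = config.bottleneck_filters
        self.bottleneck: list[nn.Layer] = (
            conv_bn_relu(prev, bf)
            + [nn.Dropout(config.bottleneck_dropout, rng=self.dropout_rng)]
            + conv_bn_relu(bf, bf)
        )

        self.dec_up: list[nn.Upsample2x] = []
        self.dec_cat: list[nn.Concat] = []
        self.dec_blocks: list[list[nn.Layer]] = []
        prev = bf
        for fi in reversed(f):
            self.dec_up.append(nn.Upsample2x())
            self.dec_cat.append(nn.Concat())
            self.dec_blocks.append(
                conv_bn_relu(fi + prev, fi) + conv_bn_relu(fi, fi)
            )
            prev = fi
        self.head: list[nn.Layer] = [
            nn.Conv2D(prev, 1, k=1, rng=rng),
            nn.Sigmoid(),
        ]

    # -- parameter plumbing --------------------------------------------------
    def _all_layers(self) -> list[nn.Layer]:
        layers: list[nn.Layer] = []
        for b in self.enc_blocks + self.down_blocks + [self.bottleneck] + self.dec_blocks:
            layers.extend(b)
        layers.extend(self.head)
        return layers

    def params(self) -> list[nn.Param]:
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (N, H, W, C) → tumor probabilities (N, H, W, 1) in (0, 1)."""
        n_st = self.config.n_stages
        if x.ndim != 4 or x.shape[3] != self.config.input[2]:
            raise ValueError(
                f"expected (N, H, W, {self.config.input[2]}), got {x.shape}"
            )
        if x.shape[1] % 2**n_st or x.shape[2] % 2**n_st:
            raise ValueError(f"H and W must be divisible by 2^{n_st}")
        skips = []
        for block, down in zip(self.enc_blocks, self.down_blocks):
            x = nn.run_forward(block, x, training)
            skips.append(x)
            x = nn.run_forward(down, x, training)
        x = nn.run_forward(self.bottleneck, x, training)
        for j, (up, cat, block) in enumerate(
            zip(self.dec_up, self.dec_cat, self.dec_blocks)
        ):
            skip = skips[self.config.n_stages - 1 - j]
            x = up.forward(x, training)
            x = cat.forward_pair(skip, x)
            x = nn.run_forward(block, x, training)
        return nn.run_forward(self.head, x, training)

    def backward(self, g: np.ndarray) -> None:
        """Backpropagate d(loss)/d(output); accumulates parameter grads."""
        g = nn.run_backward(self.head, g)
        skip_grads = [None] * self.config.n_stages
        for j in range(len(self.dec_blocks) - 1, -1, -1):
            g = nn.run_backward(self.dec_blocks[j], g)
            gskip, g = self.dec_cat[j].backward(g)
            skip_grads[self.config.n_stages - 1 - j] = gskip
            g = self.dec_up[j].backward(g)
        g = nn.run_backward(self.bottleneck, g)
        for i in range(self.config.n_stages - 1, -1, -1):
            g = nn.run_backward(self.down_blocks[i], g)
            g = g + skip_grads[i]
            g = nn.run_backward(self.enc_blocks[i], g)

    def predict(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Inference-mode tumor probability maps, (N, H, W)."""
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i : i + batch_size], training=False)[..., 0])
        return np.concatenate(outs)

    # -- persistence: npz weights + architecture JSON ------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(params, weights):
            p.value[...] = w

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        bn_state = []
        for layer in self._all_layers():
            if isinstance(layer, nn.BatchNorm):
                bn_state.extend([layer.running_mean, layer.running_var])
        arrays.update({f"bn{i}": a for i, a in enumerate(bn_state)})
        np.savez(path.with_suffix(".npz"), **arrays)
        cfg = asdict(self.config)
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "SEUNet":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        cfg["input"] = tuple(cfg["input"])
        cfg["encoder_filters"] = tuple(cfg["encoder_filters"])
        model = cls(SegModelConfig(**cfg), seed=seed)
        data = np.load(path.with_suffix(".npz"))
        model.set_weights([data[f"w{i}"] for i in range(len(model.params()))])
        i = 0
        for layer in model._all_layers():
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = data[f"bn{i}"]
                layer.running_var = data[f"bn{i + 1}"]
                i += 2
        return model


def build_se_unet(config: SegModelConfig | None = None, seed: int = 0) -> SEUNet:
    """Construct a randomly initialized SE-UNet for the given configuration."""
    return SEUNet(config or SegModelConfig(), seed=seed)
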