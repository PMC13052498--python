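import numpy as np
import pytest

from dociseg.segmodel import (
    HybridLossConfig,
    SegModelConfig,
    SEUNet,
    TverskyParams,
    build_se_unet,
    focal_tversky_grad,
    focal_tversky_loss,
    hybrid_grad,
    hybrid_loss,
    w_pos_from_prevalence,
    weighted_bce_grad,
    weighted_bce_loss,
)

TINY = dict(
    input=(16, 16, 2),
    encoder_filters=(4, 8),
    se_min_channels=8,
    bottleneck_filters=12,
    se_reduction=2,
    bottleneck_dropout=0.0,
    encoder_spatial_dropout=0.0,
)


def test_config_validation():
    with pytest.raises(ValueError, match="increasing"):
        SegModelConfig(encoder_filters=(64, 32))
    with pytest.raises(ValueError, match="dropout"):
        SegModelConfig(bottleneck_dropout=1.0)
    with pytest.raises(ValueError, match="divisible"):
        SegModelConfig(input=(100, 100, 4), encoder_filters=(8, 16, 32))
    assert SegModelConfig().n_stages == 5


def test_tversky_and_hybrid_validation():
    with pytest.raises(ValueError):
        TverskyParams(alpha=0.6, beta=0.6)
    with pytest.raises(ValueError):
        HybridLossConfig(mix=(0.7, 0.7))
    with pytest.raises(ValueError):
        HybridLossConfig(w_pos=7.0)


def test_w_pos_cap():
    assert w_pos_from_prevalence(0.5) == pytest.approx(2.0)
    assert w_pos_from_prevalence(0.25) == pytest.approx(4.0)
    for prev in (0.2, 0.1, 0.01, 0.0):
        assert w_pos_from_prevalence(prev) == 5.0


def test_focal_tversky_printed_oracle():
    """Hard counts TP=FN=FP=1: TI = 1/(1+0.7+0.3) = 0.5, loss = 0.5^0.75."""
    probs = np.array([[1.0, 0.0, 1.0]])
    truth = np.array([[1.0, 1.0, 0.0]])
    loss = focal_tversky_loss(probs, truth, TverskyParams(smooth=1e-12))
    assert loss == pytest.approx(0.5**0.75, abs=1e-9)
    assert loss == pytest.approx(0.5946, abs=5e-4)


def test_focal_tversky_limits():
    y = np.array([[1.0, 0.0, 1.0, 0.0]])
    assert focal_tversky_loss(y, y) == pytest.approx(0.0, abs=1e-4)
    assert focal_tversky_loss(1 - y, y, TverskyParams(smooth=1e-12)) == (
        pytest.approx(1.0, abs=1e-6)
    )


def test_focal_tversky_soft_dice_identity(rng):
    """At alpha = beta = 0.5, gamma = 1 the loss is 1 − soft Dice."""
    p = rng.random((2, 5, 5))  # batch of two 5x5 images
    y = (rng.random((2, 5, 5)) > 0.5).astype(float)
    s = 1e-6
    loss = focal_tversky_loss(p, y, TverskyParams(alpha=0.5, beta=0.5,
                                                  gamma=1.0, smooth=s))
    pf, yf = p.reshape(2, -1), y.reshape(2, -1)
    soft_dice = (2 * (pf * yf).sum(1) + 2 * s) / (
        pf.sum(1) + yf.sum(1) + 2 * s
    )
    assert loss == pytest.approx(float(np.mean(1 - soft_dice)), abs=1e-12)


def test_weighted_bce_printed_oracle():
    """Single positive pixel at p = 0.5, w_pos = 5 → 5·ln 2."""
    loss = weighted_bce_loss(np.array([[0.5]]), np.array([[1.0]]), w_pos=5.0)
    assert loss == pytest.approx(5 * np.log(2.0), abs=1e-12)


def test_loss_grads_match_finite_differences(rng):
    p = rng.uniform(0.05, 0.95, size=(2, 3, 3))
    y = (rng.random((2, 3, 3)) > 0.5).astype(float)
    cfg = HybridLossConfig(w_pos=3.0)
    for fn, grad_fn in (
        (lambda q: weighted_bce_loss(q, y, 3.0),
         lambda q: weighted_bce_grad(q, y, 3.0)),
        (lambda q: focal_tversky_loss(q, y),
         lambda q: focal_tversky_grad(q, y)),
        (lambda q: hybrid_loss(q, y, cfg),
         lambda q: hybrid_grad(q, y, cfg)),
    ):
        g = grad_fn(p)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 1), (0, 1, 2)]:
            pp, pm = p.copy(), p.copy()
            pp[idx] += eps
            pm[idx] -= eps
            num = (fn(pp) - fn(pm)) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-5, abs=1e-9)


def test_hybrid_is_even_mixture(rng):
    p = rng.uniform(0.1, 0.9, (1, 16))
    y = (rng.random((1, 16)) > 0.5).astype(float)
    cfg = HybridLossConfig(w_pos=2.0)
    expect = 0.5 * weighted_bce_loss(p, y, 2.0) + 0.5 * focal_tversky_loss(p, y)
    assert hybrid_loss(p, y, cfg) == pytest.approx(expect, abs=1e-12)


def test_parameter_count_arithmetic():
    """Hand-counted parameter total for the tiny architecture."""
    model = build_se_unet(SegModelConfig(**TINY), seed=0)

    def cbr(ci, co):  # conv 3x3 + bias + BN gamma/beta
        return 9 * ci * co + co + 2 * co

    enc1 = cbr(2, 4) + cbr(4, 4) + cbr(4, 4)             # two convs + down
    se2 = 8 * 4 + 4 + 4 * 8 + 8                           # SE on 8-ch stage
    enc2 = cbr(4, 8) + cbr(8, 8) + se2 + cbr(8, 8)
    bottleneck = cbr(8, 12) + cbr(12, 12)
    dec1 = cbr(12 + 8, 8) + cbr(8, 8)
    dec2 = cbr(8 + 4, 4) + cbr(4, 4)
    head = 1 * 4 * 1 + 1                                  # 1x1 conv
    assert model.n_parameters == enc1 + enc2 + bottleneck + dec1 + dec2 + head


def test_forward_shape_and_range(rng):
    model = build_se_unet(SegModelConfig(**TINY), seed=0)
    x = rng.random((2, 16, 16, 2))
    out = model.forward(x, training=False)
    assert out.shape == (2, 16, 16, 1)
    assert np.all((out > 0) & (out < 1))
    with pytest.raises(ValueError, match="expected"):
        model.forward(rng.random((1, 16, 16, 3)))
    with pytest.raises(ValueError, match="divisible"):
        model.forward(rng.random((1, 10, 10, 2)))


def test_se_placement_respects_threshold():
    model = build_se_unet(SegModelConfig(**TINY), seed=0)
    from dociseg import nn
    has_se = [any(isinstance(l, nn.SEBlock) for l in block)
              for block in model.enc_blocks]
    assert has_se == [False, True]  # 4 < se_min_channels=8 <= 8


def test_seed_determinism(rng):
    x = rng.random((1, 16, 16, 2))
    a = build_se_unet(SegModelConfig(**TINY), seed=5).forward(x)
    b = build_se_unet(SegModelConfig(**TINY), seed=5).forward(x)
    c = build_se_unet(SegModelConfig(**TINY), seed=6).forward(x)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


def test_save_load_round_trip(tmp_path, rng):
    model = build_se_unet(SegModelConfig(**TINY), seed=0)
    x = rng.random((1, 16, 16, 2))
    before = model.forward(x, training=False)
    model.save(tmp_path / "net")
    loaded = SEUNet.load(tmp_path / "net")
    np.testing.assert_allclose(loaded.forward(x, training=False), before,
                               atol=1e-12)
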