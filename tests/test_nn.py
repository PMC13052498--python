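import numpy as np
import pytest
from scipy import ndimage

from dociseg import nn


def test_conv_matches_scipy_correlate(rng):
    """Stride-1 'same' Conv2D equals channel-summed cross-correlation."""
    cin, cout, k = 3, 2, 3
    conv = nn.Conv2D(cin, cout, k=k, rng=rng)
    x = rng.standard_normal((1, 7, 9, cin))
    out = conv.forward(x)
    # weight layout: W[(i*k + j)*cin + c, o]
    kernel = conv.W.value.reshape(k, k, cin, cout)
    expect = np.zeros_like(out)
    for o in range(cout):
        acc = np.zeros((7, 9))
        for c in range(cin):
            acc += ndimage.correlate(
                x[0, :, :, c], kernel[:, :, c, o], mode="constant"
            )
        expect[0, :, :, o] = acc + conv.b.value[o]
    np.testing.assert_allclose(out, expect, atol=1e-10)


def test_conv_stride2_output_shape(rng):
    conv = nn.Conv2D(2, 4, k=3, stride=2, rng=rng)
    out = conv.forward(rng.standard_normal((2, 8, 8, 2)))
    assert out.shape == (2, 4, 4, 4)


def test_upsample_is_nearest_and_adjoint(rng):
    up = nn.Upsample2x()
    x = rng.standard_normal((1, 3, 3, 2))
    y = up.forward(x)
    assert y.shape == (1, 6, 6, 2)
    np.testing.assert_array_equal(y[0, :2, :2, 0], np.full((2, 2), x[0, 0, 0, 0]))
    g = rng.standard_normal(y.shape)
    # adjoint identity <Ux, g> == <x, U^T g>
    assert np.vdot(y, g) == pytest.approx(np.vdot(x, up.backward(g)))


def test_batchnorm_training_statistics(rng):
    bn = nn.BatchNorm(3)
    x = rng.standard_normal((4, 5, 5, 3)) * 3 + 2
    y = bn.forward(x, training=True)
    np.testing.assert_allclose(y.mean(axis=(0, 1, 2)), 0, atol=1e-10)
    np.testing.assert_allclose(y.std(axis=(0, 1, 2)), 1, atol=1e-3)
    # running stats move toward the batch stats
    assert np.all(np.abs(bn.running_mean - 0.1 * x.mean(axis=(0, 1, 2))) < 1e-10)


def test_dropout_inference_is_identity(rng):
    for layer in (nn.SpatialDropout(0.5, rng=rng), nn.Dropout(0.5, rng=rng)):
        x = rng.standard_normal((2, 4, 4, 3))
        np.testing.assert_array_equal(layer.forward(x, training=False), x)
        dropped = layer.forward(x, training=True)
        assert np.any(dropped == 0.0)


def test_spatial_dropout_drops_whole_channels(rng):
    layer = nn.SpatialDropout(0.5, rng=np.random.default_rng(0))
    x = np.ones((1, 6, 6, 16))
    y = layer.forward(x, training=True)
    per_channel = y[0].reshape(-1, 16)
    for c in range(16):
        vals = np.unique(per_channel[:, c])
        assert len(vals) == 1  # each channel fully kept (scaled) or fully zero


def test_concat_backward_splits(rng):
    cat = nn.Concat()
    a = rng.standard_normal((1, 4, 4, 2))
    b = rng.standard_normal((1, 4, 4, 3))
    y = cat.forward_pair(a, b)
    assert y.shape == (1, 4, 4, 5)
    ga, gb = cat.backward(y)
    np.testing.assert_array_equal(ga, a)
    np.testing.assert_array_equal(gb, b)


def _loss_and_grads(layers, x, gfix):
    out = nn.run_forward(layers, x, training=True)
    loss = float(np.sum(out * gfix))
    for layer in layers:
        for p in layer.params():
            p.grad[...] = 0.0
    gx = nn.run_backward(layers, gfix)
    return loss, gx, out


@pytest.mark.parametrize("make_layers", [
    lambda rng: [nn.Conv2D(2, 3, rng=rng), nn.BatchNorm(3), nn.ReLU()],
    lambda rng: [nn.Conv2D(2, 4, stride=2, rng=rng), nn.Sigmoid()],
    lambda rng: [nn.SEBlock(2, reduction=2, rng=rng)],
])
def test_finite_difference_gradients(make_layers, rng):
    """Analytic parameter and input gradients match central differences."""
    layers = make_layers(rng)
    x = rng.standard_normal((2, 4, 4, 2))
    out_shape = nn.run_forward(layers, x, training=True).shape
    gfix = rng.standard_normal(out_shape)
    _, gx, _ = _loss_and_grads(layers, x, gfix)
    eps = 1e-6

    def numeric(setter, getter):
        base = getter()
        setter(base + eps)
        lp, _, _ = _loss_and_grads(layers, x, gfix)
        setter(base - eps)
        lm, _, _ = _loss_and_grads(layers, x, gfix)
        setter(base)
        return (lp - lm) / (2 * eps)

    # sample a few parameter entries per layer
    check_rng = np.random.default_rng(0)
    _, _, _ = _loss_and_grads(layers, x, gfix)  # refresh caches/grads
    for layer in layers:
        for p in layer.params():
            flat = p.value.ravel()
            for idx in check_rng.choice(flat.size, size=min(4, flat.size),
                                        replace=False):
                def setv(v, f=flat, i=idx):
                    f[i] = v
                num = numeric(setv, lambda f=flat, i=idx: f[i])
                _, _, _ = _loss_and_grads(layers, x, gfix)
                ana = p.grad.ravel()[idx]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-6)
    # a few input entries
    xf = x.ravel()
    for idx in check_rng.choice(xf.size, size=5, replace=False):
        def setx(v, f=xf, i=idx):
            f[i] = v
        num = numeric(setx, lambda f=xf, i=idx: f[i])
        assert gx.ravel()[idx] == pytest.approx(num, rel=1e-4, abs=1e-6)


def test_adam_decreases_quadratic():
    p = nn.Param(np.array([5.0, -3.0]))
    opt = nn.Adam([p], lr=0.1)
    for _ in range(200):
        opt.zero_grad()
        p.grad[...] = 2 * p.value  # d/dp of ||p||^2
        opt.step()
    assert np.linalg.norm(p.value) < 0.05
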