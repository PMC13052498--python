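import numpy as np
import pytest

from dociseg.segmodel import SegModelConfig, build_se_unet
from dociseg.trainer import (
    AugmentConfig,
    GeometricDraw,
    SegItem,
    SEUNetSegmenter,
    TrainConfig,
    assemble_gated_dataset,
    augment_instance,
    build_training_stream,
    dataset_prevalence,
    draw_geometry,
    train_segmenter,
)
from dociseg.voxelio import BinaryMask, VoxelStack


class FakeSpecimen:
    def __init__(self, sid, cls, tumor):
        self.specimen_id = sid
        self.true_class = cls
        h = w = 8
        self.voxels = VoxelStack(np.random.default_rng(0).random((h, w, 2)),
                                 ["a", "b"], sid)
        self.tissue_mask = BinaryMask(np.ones((h, w), np.uint8), role="tissue")
        tm = np.zeros((h, w), np.uint8)
        if tumor:
            tm[2:5, 2:5] = 1
        self.tumor_mask = BinaryMask(tm, role="tumor")


def make_specimens():
    return [
        FakeSpecimen("s0", "normal", False),
        FakeSpecimen("s1", "papillary", True),
        FakeSpecimen("s2", "follicular", True),
        FakeSpecimen("s3", "atypical", True),
        FakeSpecimen("s4", "papillary", True),
    ]


def test_assembly_retention_and_labels():
    specs = make_specimens()
    calls = {"s0": "normal", "s1": "papillary", "s2": "follicular",
             "s3": "papillary", "s4": "normal"}  # s4 gate-missed
    items = assemble_gated_dataset(specs, calls, "papillary")
    ids = [i.specimen_id for i in items]
    assert ids == ["s0", "s1", "s4"]  # follicular excluded; atypical excluded
    by_id = {i.specimen_id: i for i in items}
    assert by_id["s1"].tumor_mask.any()     # target class keeps its mask
    assert not by_id["s0"].tumor_mask.any()
    # gate-missed target slide retained via its 'normal' call, mask kept
    assert by_id["s4"].tumor_mask.any()


def test_assembly_atypical_flag():
    specs = make_specimens()
    calls = {"s0": "normal", "s1": "papillary", "s2": "follicular",
             "s3": "papillary", "s4": "papillary"}
    items = assemble_gated_dataset(specs, calls, "papillary",
                                   include_atypical_if_gated=True)
    by_id = {i.specimen_id: i for i in items}
    assert "s3" in by_id and by_id["s3"].tumor_mask.any()


def test_assembly_errors():
    specs = make_specimens()
    with pytest.raises(ValueError, match="target"):
        assemble_gated_dataset(specs, {}, "anaplastic")
    with pytest.raises(ValueError, match="no gate call"):
        assemble_gated_dataset(specs, {"s0": "normal"}, "papillary")
    calls = {s.specimen_id: "follicular" for s in specs}
    with pytest.raises(ValueError, match="empty"):
        assemble_gated_dataset(specs[:2], calls, "papillary")


def test_augment_config_validation():
    with pytest.raises(ValueError):
        AugmentConfig(zoom_range=(1.1, 1.2))
    with pytest.raises(ValueError):
        AugmentConfig(noise_sd=-0.1)
    with pytest.raises(ValueError):
        TrainConfig(max_epochs=-1)


def test_augment_synchronized_and_binary(rng):
    vox = rng.random((20, 20, 3))
    tum = np.zeros((20, 20), np.uint8)
    tum[5:10, 5:10] = 1
    tis = np.ones((20, 20), np.uint8)
    cfg = AugmentConfig(output_size=16, seed=0)
    v, t, s = augment_instance(vox, tum, tis, cfg, rng)
    assert v.shape == (16, 16, 3) and t.shape == (16, 16)
    assert set(np.unique(t)) <= {0, 1} and set(np.unique(s)) <= {0, 1}
    assert v.min() >= 0.0 and v.max() <= 1.0


def test_noise_touches_voxels_only(rng):
    """With identical geometry, noise changes voxels but never the masks."""
    vox = rng.random((16, 16, 2))
    tum = (rng.random((16, 16)) > 0.7).astype(np.uint8)
    tis = np.ones((16, 16), np.uint8)
    geom = GeometricDraw(flip_h=True, flip_v=False, angle_deg=7.0, zoom=1.05)
    quiet = AugmentConfig(noise_sd=0.0, output_size=16)
    noisy = AugmentConfig(noise_sd=0.05, output_size=16)
    v0, t0, s0 = augment_instance(vox, tum, tis, quiet, rng, geom=geom)
    v1, t1, s1 = augment_instance(vox, tum, tis, noisy, rng, geom=geom)
    assert not np.array_equal(v0, v1)
    np.testing.assert_array_equal(t0, t1)
    np.testing.assert_array_equal(s0, s1)


def test_identity_geometry_preserves_content(rng):
    vox = rng.random((16, 16, 2))
    tum = (rng.random((16, 16)) > 0.8).astype(np.uint8)
    tis = np.ones((16, 16), np.uint8)
    geom = GeometricDraw(flip_h=False, flip_v=False, angle_deg=0.0, zoom=1.0)
    cfg = AugmentConfig(noise_sd=0.0, output_size=16)
    v, t, s = augment_instance(vox, tum, tis, cfg, rng, geom=geom)
    np.testing.assert_allclose(v, vox)
    np.testing.assert_array_equal(t, tum)


def test_draw_geometry_ranges():
    cfg = AugmentConfig(seed=0)
    rng = np.random.default_rng(0)
    for _ in range(50):
        g = draw_geometry(cfg, rng)
        assert -15.0 <= g.angle_deg <= 15.0
        assert 0.90 <= g.zoom <= 1.10


def test_training_stream_counts(rng):
    def item(sid, tumor):
        tm = np.zeros((16, 16), np.uint8)
        if tumor:
            tm[4:8, 4:8] = 1
        return SegItem(sid, rng.random((16, 16, 2)), tm,
                       np.ones((16, 16), np.uint8))

    dataset = [item("a", True), item("b", True), item("c", True),
               item("d", False), item("e", False)]
    cfg = AugmentConfig(output_size=16, seed=0)
    stream = build_training_stream(dataset, cfg)
    assert len(stream) == 3 * 4 + 2 * 1  # 4 per positive, 1 per empty
    again = build_training_stream(dataset, cfg)
    for x, y in zip(stream, again):
        np.testing.assert_array_equal(x.voxels, y.voxels)  # seeded


def test_dataset_prevalence(rng):
    tm = np.zeros((10, 10), np.uint8)
    tm[:2] = 1  # 20 of 100
    items = [SegItem("a", rng.random((10, 10, 1)), tm, np.ones((10, 10), np.uint8)),
             SegItem("b", rng.random((10, 10, 1)), np.zeros((10, 10), np.uint8),
                     np.ones((10, 10), np.uint8))]
    assert dataset_prevalence(items) == pytest.approx(20 / 200)
    assert dataset_prevalence([]) == 0.0


def test_zero_epoch_training_is_noop(rng):
    model = build_se_unet(
        SegModelConfig(input=(16, 16, 1), encoder_filters=(2, 4),
                       se_min_channels=4, bottleneck_filters=6,
                       se_reduction=2), seed=0)
    item = SegItem("a", rng.random((16, 16, 1)),
                   np.zeros((16, 16), np.uint8), np.ones((16, 16), np.uint8))
    before = model.get_weights()
    _, hist = train_segmenter(model, [item], None,
                              train_cfg=TrainConfig(max_epochs=0))
    assert hist == {"train_loss": [], "val_loss": []}
    for a, b in zip(before, model.get_weights()):
        np.testing.assert_array_equal(a, b)


def test_overfit_single_image():
    """Training on one image reaches Dice >= 0.95 quickly — a direct check
    that the loss, gradients and optimizer cooperate."""
    from dociseg.metrics import dice

    rng = np.random.default_rng(0)
    h = w = 64
    tum = np.zeros((h, w), np.uint8)
    rr, cc = np.mgrid[0:h, 0:w]
    tum[(rr - 32) ** 2 + (cc - 32) ** 2 < 14**2] = 1
    vox = np.clip(0.3 + 0.4 * tum[..., None] +
                  rng.standard_normal((h, w, 8)) * 0.05, 0, 1)
    seg = SEUNetSegmenter(
        model_config=SegModelConfig(
            input=(h, w, 8), encoder_filters=(4, 8), se_min_channels=8,
            bottleneck_filters=12, se_reduction=2,
            bottleneck_dropout=0.0, encoder_spatial_dropout=0.0,
        ),
        augment=AugmentConfig(allow_flips=False, rotation_range=0.0,
                              zoom_range=(1.0, 1.0), noise_sd=0.0,
                              augs_per_positive=1, output_size=h, seed=0),
        train=TrainConfig(max_epochs=150, patience=150, batch_size=1, seed=0),
        random_state=0,
    )
    seg.fit(vox[None], tum[None])
    pred = seg.predict(vox[None])[0]
    assert dice(pred, tum) >= 0.95
    assert seg.w_pos_ == pytest.approx(
        min(1.0 / (tum.sum() / tum.size), 5.0)
    )
    assert len(seg.history_["train_loss"]) >= 1


def test_segmenter_sklearn_interface():
    seg = SEUNetSegmenter(threshold=0.4)
    assert seg.get_params()["threshold"] == 0.4
    with pytest.raises(ValueError, match="not fitted"):
        seg.predict_proba(np.zeros((1, 16, 16, 1)))
    seg.set_operating_threshold(0.35)
    assert seg.threshold_ == 0.35
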