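"""Model architectures and training regimes at miniature scale:
shape arithmetic, contracts, freeze guarantees, checkpoints, and
sanity-learnable synthetic tasks."""

import numpy as np
import pytest

from bedweight.models import (
    TrainConfig,
    build_unet,
    build_weight_cnn,
    classify_cover,
    load_checkpoint,
    predict_weight,
    route_and_predict,
    save_checkpoint,
    train_cover_classifier,
    train_uncover,
    train_weight,
)

RES = (16, 32, 16)  # miniature grid divisible by 8


def theta_checksum(model):
    return [a.copy() for a in model.state_arrays()]


def assert_same(arrays_a, arrays_b):
    assert all(np.array_equal(a, b) for a, b in zip(arrays_a, arrays_b))


@pytest.fixture(scope="module")
def blob_dataset():
    """Volumes whose occupied-voxel count encodes the weight linearly:
    weight = 0.002 kg per occupied voxel * 1000."""
    rng = np.random.default_rng(0)
    n = 96
    x = np.zeros((n, *RES), dtype=np.float32)
    for i in range(n):
        cx, cy, cz = rng.integers(4, 12), rng.integers(8, 24), rng.integers(4, 12)
        r = rng.integers(2, 6)
        X, Y, Z = np.mgrid[:RES[0], :RES[1], :RES[2]]
        x[i] = ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r * r).astype(np.float32)
    y = 0.05 * x.sum(axis=(1, 2, 3))
    return x, y


def test_unet_shape_contract_and_bottleneck():
    model = build_unet((48, 96, 32), base_channels=4, seed=0)
    out = model.forward(np.zeros((1, 1, 48, 96, 32), np.float32))
    assert out.shape == (1, 1, 48, 96, 32)
    assert model.bottleneck_shape == (6, 12, 4)
    proba = model.predict_proba(np.zeros((48, 96, 32), np.float32))
    assert proba.min() >= 0.0 and proba.max() <= 1.0


def test_unet_rejects_indivisible_resolution():
    with pytest.raises(ValueError):
        build_unet((44, 96, 32), levels=4)  # 44 not divisible by 8
    build_unet((44, 96, 32), levels=3)  # 44 divisible by 4: fine


def test_weight_cnn_architecture_arithmetic():
    model = build_weight_cnn((48, 96, 32))
    assert model.downsampling_factor == 32
    assert model.final_channels == 64
    assert model.feature_shape == (1, 3, 1)  # flattened length 64*3 = 192
    flat_layer = model.stack.layers[-4]
    assert flat_layer.weight.data.shape == (192, 128)


def test_weight_cnn_rejects_too_small_input():
    with pytest.raises(ValueError):
        build_weight_cnn((16, 16, 16))  # cannot survive five halvings


@pytest.mark.parametrize("resolution", [(32, 96, 32), (64, 64, 32), (48, 96, 32)])
def test_weight_cnn_downsampling_property(resolution):
    model = build_weight_cnn(resolution)
    expected = tuple(r // 32 for r in resolution)
    assert model.feature_shape == expected
    out = model.predict(np.zeros(resolution, np.float32))
    assert out.shape == (1,) and np.isfinite(out[0])


def test_train_uncover_zero_epochs_returns_initialized_model():
    x = np.zeros((4, *RES), np.float32)
    cfg = TrainConfig(epochs=0, milestones=(), seed=0)
    fresh = build_unet(RES, base_channels=2, seed=0)
    before = theta_checksum(fresh)
    model = train_uncover(x, x, config=cfg, model=fresh)
    assert_same(before, theta_checksum(model))
    with pytest.raises(ValueError):
        train_uncover(np.zeros((0, *RES), np.float32), np.zeros((0, *RES), np.float32), config=cfg)


def test_train_uncover_identity_task_reaches_high_dice(blob_dataset):
    # covered == target: the skip connections make the identity learnable
    # by a miniature model in a short schedule
    x, _ = blob_dataset
    cfg = TrainConfig(epochs=60, milestones=(45,), seed=0, batch_size=4, learning_rate=3e-3)
    model = train_uncover(x[:16], x[:16], config=cfg, base_channels=4)
    from bedweight.metrics import dice

    proba = model.predict_proba(x[16:24])[:, 0]
    scores = [dice(x[16 + i] > 0.5, proba[i] > 0.5) for i in range(8)]
    assert np.mean(scores) > 0.95


def test_two_stage_freezes_uncover_parameters(blob_dataset):
    x, y = blob_dataset
    unet = build_unet(RES, base_channels=2, seed=3)
    before = theta_checksum(unet)
    cfg = TrainConfig(epochs=2, milestones=(), seed=0)
    train_weight(x[:16], y[:16], mode="two-stage", uncover_model=unet, config=cfg,
                 channel_schedule=(4, 6), head_width=8, dropout=0.0)
    assert_same(before, theta_checksum(unet))  # bitwise unchanged


def test_two_stage_requires_uncover_model(blob_dataset):
    x, y = blob_dataset
    with pytest.raises(ValueError):
        train_weight(x[:8], y[:8], mode="two-stage", config=TrainConfig(epochs=1, milestones=()))


def test_plain_regressor_learns_linear_voxel_count_target(blob_dataset):
    x, y = blob_dataset
    cfg = TrainConfig(epochs=25, milestones=(18,), seed=0)
    model = train_weight(x[:80], y[:80], mode="plain", config=cfg,
                         channel_schedule=(6, 8, 12), head_width=32, dropout=0.0)
    pred = model.predict(x[80:])
    assert np.mean(np.abs(pred - y[80:])) < 2.0  # kg


def test_e2e_returns_updated_composition(blob_dataset):
    x, y = blob_dataset
    cfg = TrainConfig(epochs=1, milestones=(), seed=0)
    reg, unet = train_weight(x[:16], y[:16], mode="e2e", config=cfg,
                             channel_schedule=(4, 6), head_width=8, dropout=0.0,
                             base_channels=2)
    fresh = build_unet(RES, base_channels=2, seed=cfg.seed + 1)
    changed = [not np.array_equal(a, b)
               for a, b in zip(unet.state_arrays(), fresh.state_arrays())]
    assert any(changed)  # the weight loss reached theta_f


def test_predict_weight_contract(blob_dataset):
    x, y = blob_dataset
    unet = build_unet(RES, base_channels=2, seed=0)
    reg = build_weight_cnn(RES, channel_schedule=(4, 6), head_width=8, dropout=0.0)
    w1, vol1 = predict_weight(x[0], unet, reg)
    w2, vol2 = predict_weight(x[0], unet, reg)
    assert np.isfinite(w1) and vol1.shape == RES
    assert w1 == w2 and np.array_equal(vol1, vol2)  # inference determinism
    other = build_weight_cnn((16, 32, 32), channel_schedule=(4, 6), head_width=8)
    with pytest.raises(ValueError):
        predict_weight(x[0], unet, other)


def test_classifier_contracts_and_tie_break(blob_dataset):
    x, y = blob_dataset
    with pytest.raises(ValueError):
        train_cover_classifier(x[:8], np.ones(8), config=TrainConfig.classifier())
    clf = build_weight_cnn(RES, channel_schedule=(4, 6), head_width=8, mode="classifier")
    label = classify_cover(x[0], clf)
    assert label in ("covered", "uncovered")
    reg = build_weight_cnn(RES, channel_schedule=(4, 6), head_width=8)
    with pytest.raises(ValueError):
        classify_cover(x[0], reg)  # not a classifier
    # exact 0.5 resolves to uncovered
    from bedweight import models as m

    class Half:
        mode = "classifier"

        def predict(self, v):
            return np.array([0.5])

    assert m.classify_cover(x[0], Half()) == "uncovered"


def test_training_is_seed_repeatable(blob_dataset):
    x, y = blob_dataset
    cfg = TrainConfig(epochs=2, milestones=(), seed=9)
    m1 = train_weight(x[:16], y[:16], mode="plain", config=cfg,
                      channel_schedule=(4, 6), head_width=8, dropout=0.5)
    m2 = train_weight(x[:16], y[:16], mode="plain", config=cfg,
                      channel_schedule=(4, 6), head_width=8, dropout=0.5)
    assert [l for _, l, _ in m1.train_log] == [l for _, l, _ in m2.train_log]
    assert_same(theta_checksum(m1), theta_checksum(m2))


def test_learning_rate_schedule_divides_by_ten():
    x = np.zeros((4, *RES), np.float32)
    cfg = TrainConfig(epochs=4, milestones=(1, 3), seed=0, learning_rate=1e-3)
    model = train_uncover(x, x, config=cfg, base_channels=2)
    lrs = [lr for _, _, lr in model.train_log]
    assert lrs == [1e-3, 1e-4, 1e-4, 1e-5]
    with pytest.raises(ValueError):
        TrainConfig(epochs=10, milestones=(60,))


def test_checkpoint_round_trip(tmp_path, blob_dataset):
    x, y = blob_dataset
    unet = build_unet(RES, base_channels=2, seed=5)
    save_checkpoint(unet, tmp_path / "u.npz", TrainConfig.unet())
    loaded = load_checkpoint(tmp_path / "u.npz")
    assert_same(theta_checksum(unet), theta_checksum(loaded))
    assert np.array_equal(unet.predict_proba(x[0]), loaded.predict_proba(x[0]))

    reg = build_weight_cnn(RES, channel_schedule=(4, 6), head_width=8, dropout=0.3)
    save_checkpoint(reg, tmp_path / "g.npz")
    loaded_reg = load_checkpoint(tmp_path / "g.npz")
    assert loaded_reg.descriptor == reg.descriptor
    assert np.array_equal(reg.predict(x[:3]), loaded_reg.predict(x[:3]))
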