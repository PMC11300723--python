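"""The multi-output U-net: architecture, losses, gradients, training."""

import numpy as np
import pytest

from enterogram.grid import VolumeGrid
from enterogram.nn import (
    TrainConfig,
    TrainingSample,
    UNetConfig,
    build_unet,
    count_parameters,
    load_checkpoint,
    make_training_sample,
    multitask_loss,
    predict,
    resolve_weights,
    save_checkpoint,
    train,
)
from enterogram.nn.engine import Conv3d
from enterogram.phantom import PhantomConfig, generate_sample
from enterogram.preprocess import window_level


def _random_sample(rng, n=8, spacing=6.0):
    grid = VolumeGrid((n, n, n), (spacing,) * 3)
    return TrainingSample(
        ct=rng.random((n, n, n)).astype(np.float32),
        segmentation=(rng.random((n, n, n)) < 0.3).astype(np.float32),
        longitude=(rng.random((n, n, n)) * 80).astype(np.float32),
        diameter=(rng.random((n, n, n)) * 6).astype(np.float32),
        grid=grid,
    )


# ---------------------------------------------------------------------------
# architecture / parameter counting
# ---------------------------------------------------------------------------


def test_single_conv_parameter_count():
    # one 3^3 convolution, 1 channel in/out, with bias: 27 + 1
    assert Conv3d(1, 1, 3).n_params == 28


def test_default_ladder_matches_published_architecture():
    cfg = UNetConfig()
    assert cfg.encoder_channels() == [16, 32, 64, 128, 256, 512]
    assert cfg.bottleneck_channels() == 512
    assert cfg.decoder_channels() == [256, 128, 64, 32, 16]
    # 256 x 256 x 192 input reaches a 4 x 4 x 3 bottleneck after 6 poolings
    cfg.validate_shape((256, 256, 192))
    assert tuple(s // 2 ** (cfg.depth - 1) for s in (256, 256, 192)) == (4, 4, 3)


def test_default_parameter_count_rounds_to_37m():
    model = build_unet(UNetConfig())
    assert round(count_parameters(model) / 1e6) == 37


def test_parameter_count_independent_of_input_shape():
    cfg = UNetConfig(base_channels=4, depth=3)
    n32 = count_parameters(build_unet(cfg, input_shape=(32, 32, 32)))
    n64 = count_parameters(build_unet(cfg, input_shape=(64, 64, 64)))
    assert n32 == n64


def test_tiny_config_count_matches_hand_computation():
    """Two-level net, base 2: every conv/BN counted by hand."""
    cfg = UNetConfig(base_channels=2, depth=2)
    # encoder level (2 ch): conv(1->2) 56, conv(2->2) 110, 2 BN of 4 -> 174
    # bottleneck (4 ch):    conv(2->4) 220, conv(4->4) 436, 2 BN of 8 -> 672
    # no decoder levels; final upsample; heads: 3 x (1x1x1 conv 4->1) = 15
    assert count_parameters(build_unet(cfg)) == 174 + 672 + 15


def test_doubling_channels_quadruples_conv_parameters():
    small = count_parameters(build_unet(UNetConfig(base_channels=4, depth=3)))
    big = count_parameters(build_unet(UNetConfig(base_channels=8, depth=3)))
    assert 3.3 < big / small < 4.0


def test_indivisible_shape_rejected_naming_axis():
    with pytest.raises(ValueError, match="axis z"):
        build_unet(UNetConfig(depth=3), input_shape=(32, 32, 30))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def test_loss_zero_for_perfect_predictions():
    rng = np.random.default_rng(0)
    s = _random_sample(rng)
    outputs = {
        "segmentation": np.where(s.segmentation > 0, 30.0, -30.0),
        "longitude": s.longitude.astype(np.float64),
        "diameter": s.diameter.astype(np.float64),
    }
    total, breakdown, _ = multitask_loss(outputs, s, (1.0, 1.0, 1.0))
    assert breakdown["long"] == 0.0
    assert breakdown["diam"] == 0.0
    assert breakdown["seg"] < 1e-10


def test_loss_matches_pencil_and_paper():
    """Two-voxel example against closed-form BCE/MSE arithmetic."""
    grid = VolumeGrid((2, 1, 1))
    s = TrainingSample(
        ct=np.zeros((2, 1, 1), np.float32),
        segmentation=np.array([1.0, 0.0], np.float32).reshape(2, 1, 1),
        longitude=np.array([50.0, 0.0], np.float32).reshape(2, 1, 1),
        diameter=np.array([4.0, 0.0], np.float32).reshape(2, 1, 1),
        grid=grid,
    )
    z = np.array([0.0, 2.0]).reshape(2, 1, 1)
    out = {
        "segmentation": z,
        "longitude": np.array([40.0, 10.0]).reshape(2, 1, 1),
        "diameter": np.array([5.0, 1.0]).reshape(2, 1, 1),
    }
    w = (1.0, 1e-3, 1e-2)
    total, breakdown, _ = multitask_loss(out, s, w)
    bce = (np.log(2.0) + (2.0 + np.log1p(np.exp(-2.0)))) / 2.0  # -log s(0); -log(1-s(2))
    assert breakdown["seg"] == pytest.approx(bce, rel=1e-12)
    assert breakdown["long"] == pytest.approx(1e-3 * (100 + 100) / 2)
    assert breakdown["diam"] == pytest.approx(1e-2 * (1 + 1) / 2)
    assert total == pytest.approx(sum(breakdown.values()))


def test_loss_shape_mismatch_rejected():
    rng = np.random.default_rng(1)
    s = _random_sample(rng)
    out = {
        "segmentation": np.zeros((4, 4, 4)),
        "longitude": np.zeros((4, 4, 4)),
        "diameter": np.zeros((4, 4, 4)),
    }
    with pytest.raises(ValueError):
        multitask_loss(out, s, (1, 1, 1))


def test_auto_weights_balance_terms_within_one_order(obstructed_phantom):
    """With auto-balanced weights the three weighted terms of the first
    training sample lie within one order of magnitude of each other."""
    s = make_training_sample(window_level(obstructed_phantom.ct), obstructed_phantom.truth)
    cfg = UNetConfig(base_channels=4, depth=3, seed=0)
    model = build_unet(cfg)
    w = resolve_weights(TrainConfig(), [s])
    out = model.forward(s.ct, train=False)
    _, breakdown, _ = multitask_loss(out, s, w)
    vals = np.array(list(breakdown.values()))
    assert vals.max() / vals.min() <= 10.0


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------


def test_backward_matches_numerical_gradient():
    cfg = UNetConfig(base_channels=2, depth=2, dropout=0.0, seed=3)
    model = build_unet(cfg)
    rng = np.random.default_rng(0)
    s = _random_sample(rng, n=4)
    w = (1.0, 1e-3, 1e-2)

    def value():
        out = model.forward(s.ct, train=True)
        total, _, grads = multitask_loss(out, s, w)
        return total, grads

    total, grads = value()
    model.backward(grads)
    params = model.params()
    for pi in (0, 2, 5, len(params) - 1):
        p = params[pi]
        idx = p.value.size // 2
        analytic = p.grad.flat[idx]
        eps = 1e-3
        orig = p.value.flat[idx]
        p.value.flat[idx] = orig + eps
        up, _ = value()
        p.value.flat[idx] = orig - eps
        dn, _ = value()
        p.value.flat[idx] = orig
        numeric = (up - dn) / (2 * eps)
        # float32 forward passes put a ~1e-5 noise floor on the central
        # difference; gradients above that must agree to 5%
        assert analytic == pytest.approx(numeric, rel=5e-2, abs=2e-5)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_phantom_sample():
    cfg = PhantomConfig(grid=VolumeGrid((16, 16, 16), (8.0, 8.0, 8.0)))
    sample = generate_sample(cfg, 21)
    return make_training_sample(window_level(sample.ct), sample.truth)


def test_overfit_single_phantom_decreases_loss(tiny_phantom_sample):
    model = build_unet(UNetConfig(base_channels=4, depth=3, seed=5))
    res = train(
        model,
        [tiny_phantom_sample],
        TrainConfig(epochs=20, seed=5, val_fraction=0.0),
    )
    h = res.history
    assert h.train_total.iloc[-1] < h.train_total.iloc[0]
    assert "val_total" not in h.columns


def test_training_is_deterministic_given_seed(tiny_phantom_sample):
    histories = []
    for _ in range(2):
        model = build_unet(UNetConfig(base_channels=2, depth=2, seed=9))
        res = train(model, [tiny_phantom_sample], TrainConfig(epochs=3, seed=9, val_fraction=0.0))
        histories.append(res.history.train_total.to_numpy())
    np.testing.assert_array_equal(histories[0], histories[1])


def test_empty_dataset_rejected():
    model = build_unet(UNetConfig(base_channels=2, depth=2))
    with pytest.raises(ValueError):
        train(model, [], TrainConfig(epochs=1))


def test_predict_masks_regression_outputs(tiny_phantom_sample):
    model = build_unet(UNetConfig(base_channels=2, depth=2, seed=2))
    vols = predict(model, tiny_phantom_sample.ct, tiny_phantom_sample.grid)
    vols.validate_support()  # diameter/longitude support == mask
    with pytest.raises(ValueError):
        predict(model, np.zeros((8, 8, 8), np.float32), tiny_phantom_sample.grid)


def test_checkpoint_round_trip(tmp_path, tiny_phantom_sample):
    model = build_unet(UNetConfig(base_channels=2, depth=2, seed=4))
    train(model, [tiny_phantom_sample], TrainConfig(epochs=2, seed=4, val_fraction=0.0))
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, model)
    back = load_checkpoint(path)
    out1 = predict(model, tiny_phantom_sample.ct, tiny_phantom_sample.grid)
    out2 = predict(back, tiny_phantom_sample.ct, tiny_phantom_sample.grid)
    np.testing.assert_array_equal(out1.segmentation, out2.segmentation)
    np.testing.assert_array_equal(out1.diameter, out2.diameter)
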