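import numpy as np
import pytest

from kneemark import nn
from kneemark.model import (
    NetworkConfig,
    TrainConfig,
    build_network,
    load_checkpoint,
    predict_landmarks,
    save_checkpoint,
    train,
)
from kneemark.phantom import generate_cohort


@pytest.mark.parametrize(
    "protocol,channels",
    [("trochlear_sulcus", 6), ("proximal_trochlea", 3), ("patellar_height", 7)],
)
def test_output_channels_per_protocol(protocol, channels):
    cfg = NetworkConfig(protocol=protocol, input_size=(64, 64), base_filters=4)
    assert cfg.out_channels == channels
    pred = build_network(cfg, seed=0)
    stack = pred.predict_stack(np.zeros((64, 64), dtype=np.float32))
    assert stack.channels.shape == (channels, 64, 64)


def test_softmax_conservation_and_shape():
    cfg = NetworkConfig(protocol="proximal_trochlea", input_size=(32, 32), base_filters=4)
    pred = build_network(cfg, seed=1)
    rng = np.random.default_rng(0)
    stack = pred.predict_stack(rng.random((32, 32), dtype=np.float32))
    assert np.allclose(stack.channels.sum(axis=0), 1.0, atol=1e-6)
    assert np.all(stack.channels >= 0)


def test_indivisible_input_size_rejected():
    with pytest.raises(ValueError, match="divisible"):
        NetworkConfig(protocol="patellar_height", input_size=(100, 100))


def test_encoder_widths_double_from_base():
    cfg = NetworkConfig(protocol="patellar_height", input_size=(64, 64), base_filters=8)
    net = build_network(cfg, seed=0).net
    widths = [blk[0].w.shape[-1] for blk in net.enc]
    assert widths == [8, 16, 32, 64, 128]
    assert net.head.w.shape == (8, 7)


def test_uniform_prediction_loss_is_log_channels():
    # zero logits -> uniform softmax; CE against any normalised target = ln C
    logits = np.zeros((2, 8, 8, 7), dtype=np.float32)
    rng = np.random.default_rng(0)
    t = rng.random((2, 8, 8, 7)).astype(np.float32)
    t /= t.sum(axis=-1, keepdims=True)
    loss, dlogits = nn.softmax_cross_entropy(logits, t)
    assert loss == pytest.approx(np.log(7), rel=1e-5)
    assert dlogits.shape == logits.shape


def test_gradients_match_finite_differences(monkeypatch):
    """Backprop through the full U-Net agrees with numerical gradients.

    The core runs in float64 here so central differences resolve the
    gradient to ~1e-7 and any structural backprop error stands out.
    """
    monkeypatch.setattr(nn, "F32", np.float64)
    rng = np.random.default_rng(0)
    net = nn.UNet(
        in_channels=1, out_channels=3, levels=2, base_filters=2,
        encoder_dropouts=[0.0, 0.0], decoder_dropouts=[0.0],
        rng=np.random.default_rng(1),
    )
    x = rng.random((2, 8, 8, 1))
    t = rng.random((2, 8, 8, 3))
    t /= t.sum(axis=-1, keepdims=True)
    # keep pre-activations away from the ReLU/max-pool kinks so central
    # differences measure the same linearisation branch as backprop
    for layer in net.layers():
        if isinstance(layer, (nn.Conv3x3, nn.ConvT2x2)) and layer.b.size:
            layer.b += 0.3

    def loss_fn():
        return nn.softmax_cross_entropy(net.forward(x, train=False), t)[0]

    loss, dlogits = nn.softmax_cross_entropy(net.forward(x, train=True), t)
    assert loss > 0
    net.backward(dlogits)

    eps = 1e-6
    checked = 0
    for p, g in net.params():
        flat_p, flat_g = p.ravel(), g.ravel()
        for idx in rng.choice(flat_p.size, size=min(4, flat_p.size), replace=False):
            orig = flat_p[idx]
            flat_p[idx] = orig + eps
            up = loss_fn()
            flat_p[idx] = orig - eps
            down = loss_fn()
            flat_p[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert flat_g[idx] == pytest.approx(numeric, abs=5e-7), (
                f"param shape {p.shape} idx {idx}"
            )
            checked += 1
    assert checked >= 40


def test_overfit_tiny_cohort_and_memorisation_roundtrip():
    images, _ = generate_cohort(5, seed=6, protocol="proximal_trochlea", canvas=(64, 64))
    cfg = NetworkConfig(
        protocol="proximal_trochlea", input_size=(64, 64), base_filters=8, sigma=4.0
    )
    pred = build_network(cfg, seed=0)
    tcfg = TrainConfig(
        epochs=120, batch_size=5, seed=0, learning_rate=3e-3,
        select_best_validation=False,
    )
    history = train(pred, images, [], tcfg)
    assert history["train_loss"][-1] < history["train_loss"][0]
    assert len(history["train_loss"]) == 120
    # memorisation: decoded coords land near the training annotations
    coords, stack = predict_landmarks(pred, images[0])
    assert np.allclose(stack.channels.sum(axis=0), 1.0, atol=1e-5)
    for lbl, (tx, ty) in images[0].landmarks.items():
        px, py = coords[lbl]
        assert np.hypot(px - tx, py - ty) < 5.0


def test_untrained_predictions_are_in_grid(small_axial_cohort):
    images, _ = small_axial_cohort
    cfg = NetworkConfig(
        protocol="trochlear_sulcus", input_size=(128, 128), base_filters=4
    )
    pred = build_network(cfg, seed=3)
    coords, _ = predict_landmarks(pred, images[0])
    assert set(coords) == {"T1", "T2", "T3", "T4", "T5"}
    for x, y in coords.values():
        assert 0 <= x <= 127 and 0 <= y <= 127


def test_protocol_mismatch_rejected(small_axial_cohort):
    images, _ = small_axial_cohort
    cfg = NetworkConfig(protocol="patellar_height", input_size=(128, 128), base_filters=4)
    pred = build_network(cfg, seed=0)
    with pytest.raises(ValueError, match="protocol"):
        train(pred, list(images), [], TrainConfig(epochs=1, batch_size=2, seed=0))


def test_empty_training_set_rejected():
    cfg = NetworkConfig(protocol="patellar_height", input_size=(64, 64), base_filters=4)
    pred = build_network(cfg, seed=0)
    with pytest.raises(ValueError, match="empty"):
        train(pred, [], [], TrainConfig(epochs=1, seed=0))


def test_checkpoint_roundtrip(tmp_path, small_axial_cohort):
    images, _ = small_axial_cohort
    cfg = NetworkConfig(
        protocol="trochlear_sulcus", input_size=(128, 128), base_filters=4, sigma=3.0
    )
    pred = build_network(cfg, seed=9)
    path = tmp_path / "model.npz"
    save_checkpoint(pred, path)
    loaded = load_checkpoint(path)
    assert loaded.cfg.sigma == 3.0
    assert loaded.cfg.landmark_order == pred.cfg.landmark_order
    a = pred.predict_stack(images[0].pixels)
    b = loaded.predict_stack(images[0].pixels)
    assert np.array_equal(a.channels, b.channels)


def test_training_is_deterministic_given_seeds():
    images, _ = generate_cohort(4, seed=2, protocol="proximal_trochlea", canvas=(32, 32))
    cfg = NetworkConfig(
        protocol="proximal_trochlea", input_size=(32, 32), base_filters=4, sigma=2.0
    )
    runs = []
    for _ in range(2):
        pred = build_network(cfg, seed=5)
        train(pred, images, [], TrainConfig(epochs=3, batch_size=4, seed=5))
        runs.append(pred.net.get_weights())
    for a, b in zip(*runs):
        assert np.array_equal(a, b)
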