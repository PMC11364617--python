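"""U-Net landmark detector: configuration, training, prediction, checkpoints.

One model is trained per acquisition protocol; its output has one channel per
landmark plus a shared background channel (6, 3 and 7 channels for the
trochlear-sulcus, proximal-trochlea and patellar-height protocols). Targets
are the soft Gaussian heatmap stacks produced by :mod:`kneemark.heatmaps`,
and the loss is mean per-pixel categorical cross-entropy against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import heatmaps, nn
from .landmarks import landmarks_for

DEFAULT_ENCODER_DROPOUTS = (0.1, 0.1, 0.2, 0.2, 0.3)
DEFAULT_DECODER_DROPOUTS = (0.2, 0.2, 0.1, 0.1)


@dataclass
class NetworkConfig:
    """Topology of the landmark-detection U-Net.

    ``out_channels`` must equal the protocol's landmark count + 1. The spatial
    input size must be divisible by ``2**(levels-1)`` so the pooling pyramid
    closes.
    """

    protocol: str
    input_size: tuple[int, int] = (320, 320)  # (H, W)
    levels: int = 5
    base_filters: int = 32
    encoder_dropouts: tuple[float, ...] = DEFAULT_ENCODER_DROPOUTS
    decoder_dropouts: tuple[float, ...] = DEFAULT_DECODER_DROPOUTS
    sigma: float = 5.0

    def __post_init__(self) -> None:
        self.landmark_order = list(landmarks_for(self.protocol))
        h, w = self.input_size
        f = 2 ** (self.levels - 1)
        if h % f or w % f:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2^(levels-1)={f}"
            )
        if len(self.encoder_dropouts) != self.levels:
            raise ValueError("encoder_dropouts must have one entry per level")
        if len(self.decoder_dropouts) != self.levels - 1:
            raise ValueError("decoder_dropouts must have levels-1 entries")

    @property
    def out_channels(self) -> int:
        return len(self.landmark_order) + 1


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the training protocol)."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 200
    seed: int = 0
    select_best_validation: bool = True


class Predictor:
    """A configured U-Net plus the bookkeeping to go coords <-> heatmaps."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.net = nn.UNet(
            in_channels=1,
            out_channels=cfg.out_channels,
            levels=cfg.levels,
            base_filters=cfg.base_filters,
            encoder_dropouts=cfg.encoder_dropouts,
            decoder_dropouts=cfg.decoder_dropouts,
            rng=self.rng,
        )

    def predict_stack(self, pixels: np.ndarray) -> heatmaps.HeatmapStack:
        """Run one (H, W) image through the network; returns softmax heatmaps."""
        h, w = self.cfg.input_size
        if pixels.shape != (h, w):
            raise ValueError(
                f"image shape {pixels.shape} does not match input size {(h, w)}"
            )
        x = pixels.astype(np.float32)[None, :, :, None]
        probs = nn.softmax(self.net.forward(x, train=False))[0]
        return heatmaps.HeatmapStack(
            channels=probs.transpose(2, 0, 1).astype(np.float64),
            sigma=self.cfg.sigma,
            landmark_order=list(self.cfg.landmark_order),
        )


def build_network(cfg: NetworkConfig, seed: int = 0) -> Predictor:
    """Construct an initialised (untrained) predictor for ``cfg``."""
    return Predictor(cfg, seed=seed)


def _encode_targets(images, cfg: NetworkConfig) -> np.ndarray:
    h, w = cfg.input_size
    t = np.empty((len(images), h, w, cfg.out_channels), dtype=np.float32)
    for i, img in enumerate(images):
        stack = heatmaps.encode(
            img.landmarks, (h, w), cfg.sigma, list(cfg.landmark_order)
        )
        t[i] = stack.channels.transpose(1, 2, 0)
    return t


def _stack_pixels(images, cfg: NetworkConfig) -> np.ndarray:
    h, w = cfg.input_size
    x = np.empty((len(images), h, w, 1), dtype=np.float32)
    for i, img in enumerate(images):
        if img.pixels.shape != (h, w):
            raise ValueError(
                f"image {img.image_id}: shape {img.pixels.shape} != input {(h, w)}"
            )
        x[i, :, :, 0] = img.pixels
    return x


def _check_protocol(images, cfg: NetworkConfig) -> None:
    bad = [im.image_id for im in images if im.protocol != cfg.protocol]
    if bad:
        raise ValueError(f"images {bad} do not match protocol {cfg.protocol!r}")


def train(
    predictor: Predictor,
    train_set,
    val_set,
    tcfg: TrainConfig,
    aug_cfg=None,
) -> dict:
    """Train in place with Adam on mean per-pixel cross-entropy.

    Returns a history dict with per-epoch ``train_loss`` and ``val_loss``.
    With ``select_best_validation`` the weights of the epoch with the lowest
    validation loss are restored at the end. If ``aug_cfg`` is given, each
    training sample is re-augmented every epoch (image and coordinates
    together) before target encoding.
    """
    if not train_set:
        raise ValueError("empty training set")
    cfg = predictor.cfg
    _check_protocol(train_set, cfg)
    if val_set:
        _check_protocol(val_set, cfg)

    rng = np.random.default_rng(tcfg.seed)
    x_train = _stack_pixels(train_set, cfg)
    t_train = _encode_targets(train_set, cfg)
    if val_set:
        x_val = _stack_pixels(val_set, cfg)
        t_val = _encode_targets(val_set, cfg)

    opt = nn.Adam(predictor.net.params(), lr=tcfg.learning_rate)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = None

    n = len(train_set)
    for _epoch in range(tcfg.epochs):
        if aug_cfg is not None:
            from .augment import augment_pair

            aug = [augment_pair(im, aug_cfg, rng) for im in train_set]
            x_ep = _stack_pixels(aug, cfg)
            t_ep = _encode_targets(aug, cfg)
        else:
            x_ep, t_ep = x_train, t_train

        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            logits = predictor.net.forward(x_ep[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, t_ep[idx])
            predictor.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))

        if val_set:
            vlosses = []
            for start in range(0, len(val_set), tcfg.batch_size):
                logits = predictor.net.forward(
                    x_val[start : start + tcfg.batch_size], train=False
                )
                loss, _ = nn.softmax_cross_entropy(
                    logits, t_val[start : start + tcfg.batch_size]
                )
                vlosses.append(loss * len(logits))
            vloss = float(np.sum(vlosses) / len(val_set))
            history["val_loss"].append(vloss)
            if tcfg.select_best_validation and vloss < best_val:
                best_val = vloss
                best_weights = predictor.net.get_weights()

    if best_weights is not None:
        predictor.net.set_weights(best_weights)
        history["best_val_loss"] = best_val
    return history


def predict_landmarks(predictor: Predictor, img):
    """Predict landmark coordinates for one annotated/unannotated image.

    The image must already be resized to the network input size. Returns
    ``(coords, stack)`` where ``coords`` maps label -> (x, y) integer pixel
    coordinates in the input frame (the image's spacing applies unchanged).
    """
    stack = predictor.predict_stack(np.asarray(img.pixels, dtype=np.float32))
    return heatmaps.decode(stack), stack


def predict_batch(predictor: Predictor, images) -> list:
    """Predict landmark coordinates for a sequence of images, order-preserving."""
    return [predict_landmarks(predictor, img)[0] for img in images]


# -- checkpoints ------------------------------------------------------------

def save_checkpoint(predictor: Predictor, path) -> None:
    """Serialise config + weights to an ``.npz`` checkpoint."""
    import json

    meta = {
        "protocol": predictor.cfg.protocol,
        "input_size": list(predictor.cfg.input_size),
        "levels": predictor.cfg.levels,
        "base_filters": predictor.cfg.base_filters,
        "encoder_dropouts": list(predictor.cfg.encoder_dropouts),
        "decoder_dropouts": list(predictor.cfg.decoder_dropouts),
        "sigma": predictor.cfg.sigma,
        "landmark_order": list(predictor.cfg.landmark_order),
    }
    weights = predictor.net.get_weights()
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"w{i}": w for i, w in enumerate(weights)},
    )


def load_checkpoint(path) -> Predictor:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    cfg = NetworkConfig(
        protocol=meta["protocol"],
        input_size=tuple(meta["input_size"]),
        levels=meta["levels"],
        base_filters=meta["base_filters"],
        encoder_dropouts=tuple(meta["encoder_dropouts"]),
        decoder_dropouts=tuple(meta["decoder_dropouts"]),
        sigma=meta["sigma"],
    )
    if cfg.landmark_order != meta["landmark_order"]:
        raise ValueError("checkpoint landmark order does not match protocol taxonomy")
    predictor = Predictor(cfg)
    predictor.net.set_weights(weights)
    return predictor
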