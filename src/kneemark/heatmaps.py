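"""Gaussian heatmap encoding/decoding for landmark coordinates.

Each landmark is encoded as an unnormalised 2-D Gaussian

    H_i(x, y) = exp(-((x - a)^2 + (y - b)^2) / (2 sigma^2))

scaled so its maximum over the discrete grid is 1 (the identity for integer
centres), and a shared background channel makes the per-pixel sum over all
L + 1 channels exactly 1. The background absorbs the class imbalance between
the small landmark neighbourhoods and the rest of the image. Decoding takes
the hard argmax of each landmark channel (no sub-pixel refinement); ties
break to the first maximum in row-major scan order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DecodeError(RuntimeError):
    """Raised when a landmark channel carries no signal (failed detection)."""


@dataclass
class HeatmapStack:
    """(L+1)-channel heatmap stack; channel L is the shared background.

    ``channels`` has shape (L+1, H, W); ``landmark_order[i]`` names channel i.
    """

    channels: np.ndarray
    sigma: float
    landmark_order: list[str]

    @property
    def background(self) -> np.ndarray:
        return self.channels[-1]

    def __post_init__(self) -> None:
        if self.channels.ndim != 3 or self.channels.shape[0] != len(self.landmark_order) + 1:
            raise ValueError(
                f"channels shape {self.channels.shape} inconsistent with "
                f"{len(self.landmark_order)} landmarks + background"
            )


def encode(
    coords: dict[str, tuple[float, float]],
    shape: tuple[int, int],
    sigma: float,
    landmark_order: list[str] | None = None,
) -> HeatmapStack:
    """Encode landmark coordinates into a normalised heatmap stack.

    Parameters
    ----------
    coords : dict
        label -> (x, y) continuous pixel coordinates inside ``shape``.
    shape : (H, W)
    sigma : float
        Gaussian width in pixels, > 0.
    landmark_order : list of str, optional
        Channel order; defaults to the sorted labels of ``coords``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    h, w = shape
    if landmark_order is None:
        landmark_order = sorted(coords)
    if len(set(landmark_order)) != len(landmark_order):
        raise ValueError("duplicate labels in landmark_order")
    missing = [k for k in landmark_order if k not in coords]
    if missing:
        raise ValueError(f"coords missing labels {missing}")

    xs = np.arange(w, dtype=np.float64)
    ys = np.arange(h, dtype=np.float64)
    stack = np.empty((len(landmark_order) + 1, h, w), dtype=np.float64)
    for i, label in enumerate(landmark_order):
        a, b = coords[label]
        if not (0 <= a <= w - 1 and 0 <= b <= h - 1):
            raise ValueError(f"landmark {label} at ({a}, {b}) outside {h}x{w} grid")
        g = np.exp(
            -((xs[None, :] - a) ** 2 + (ys[:, None] - b) ** 2) / (2.0 * sigma**2)
        )
        # rescale so the discrete max is exactly 1 (no-op for integer centres)
        stack[i] = g / g.max()

    fg = stack[:-1].sum(axis=0)
    stack[-1] = np.clip(1.0 - fg, 0.0, None)
    # overlapping Gaussians can push the foreground sum past 1; renormalise
    # per pixel so conservation always holds
    total = stack.sum(axis=0)
    stack /= total[None]
    return HeatmapStack(channels=stack, sigma=float(sigma), landmark_order=list(landmark_order))


def decode(stack: HeatmapStack) -> dict[str, tuple[int, int]]:
    """Return each landmark channel's argmax as integer (x, y) coordinates.

    The background channel is ignored. An all-zero channel raises
    :class:`DecodeError` to flag a failed detection.
    """
    if len(stack.landmark_order) < 1:
        raise ValueError("stack has no landmark channels")
    out: dict[str, tuple[int, int]] = {}
    for i, label in enumerate(stack.landmark_order):
        chan = stack.channels[i]
        if not np.any(chan > 0):
            raise DecodeError(f"channel {label} is all zero: failed detection")
        y, x = np.unravel_index(int(np.argmax(chan)), chan.shape)
        out[label] = (int(x), int(y))
    return out


def write_channel_pngs(stack: HeatmapStack, out_dir) -> list[str]:
    """Debug helper: dump each channel as an 8-bit PNG; returns written paths."""
    from pathlib import Path

    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = list(stack.landmark_order) + ["background"]
    paths = []
    for name, chan in zip(names, stack.channels):
        p = out_dir / f"heatmap_{name}.png"
        Image.fromarray((np.clip(chan, 0, 1) * 255).astype(np.uint8)).save(p)
        paths.append(str(p))
    return paths
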