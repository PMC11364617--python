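"""Training-time augmentation with landmark-consistent geometry.

Eight operations: pixel multiplication, pixel shift, left-right flip, zoom,
rotation, translation, Gaussian noise, Gaussian blur. Geometric operations
(flip/zoom/rotation/translation) are composed into a single affine map about
the image centre and applied identically to pixels (bilinear, zero padding)
and to landmark coordinates; photometric operations touch pixels only and
never move a landmark. Each operation fires independently with probability
0.5 per sample. Intensities are re-clipped to [0, 1] at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class AugmentConfig:
    """Augmentation ranges; the defaults are the training-protocol values."""

    pixel_multiply: tuple[float, float] = (0.75, 1.25)
    pixel_shift: tuple[float, float] = (-0.15, 0.15)
    flip_lr: bool = True
    zoom: tuple[float, float] = (0.9, 1.1)
    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    translation_frac: tuple[float, float] = (-0.05, 0.05)
    gaussian_noise_std: float = 0.01
    gaussian_blur_sigma: tuple[float, float] = (0.5, 1.5)
    op_probability: float = 0.5
    max_retries: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_multiply", "pixel_shift", "zoom", "rotation_deg",
                     "translation_frac", "gaussian_blur_sigma"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range {lo, hi} is not well-ordered")


class AugmentationError(RuntimeError):
    """Raised when no in-bounds geometric transform is found within retries."""


def _draw_affine(cfg: AugmentConfig, rng: np.random.Generator, shape) -> np.ndarray:
    """Sample a 3x3 forward affine map (pixel coords, about image centre)."""
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0

    def _maybe(p=cfg.op_probability):
        return rng.random() < p

    flip = cfg.flip_lr and _maybe()
    zoom = rng.uniform(*cfg.zoom) if _maybe() else 1.0
    theta = np.deg2rad(rng.uniform(*cfg.rotation_deg)) if _maybe() else 0.0
    if _maybe():
        tx = rng.uniform(*cfg.translation_frac) * w
        ty = rng.uniform(*cfg.translation_frac) * h
    else:
        tx = ty = 0.0

    c, s = np.cos(theta), np.sin(theta)
    lin = zoom * np.array([[c, -s], [s, c]])
    if flip:
        lin = lin @ np.array([[-1.0, 0.0], [0.0, 1.0]])
    m = np.eye(3)
    m[:2, :2] = lin
    m[:2, 2] = [cx + tx, cy + ty] - lin @ [cx, cy]
    return m


def _apply_affine_coords(m: np.ndarray, coords: dict) -> dict:
    return {
        k: tuple((m[:2, :2] @ [x, y]) + m[:2, 2]) for k, (x, y) in coords.items()
    }


def _in_grid(coords: dict, shape) -> bool:
    h, w = shape
    return all(0 <= x <= w - 1 and 0 <= y <= h - 1 for x, y in coords.values())


def warp_image(pixels: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Apply forward affine ``m`` to an image (bilinear, zero padding)."""
    from skimage.transform import AffineTransform, warp

    tf = AffineTransform(matrix=m)
    return warp(
        pixels.astype(np.float64), tf.inverse, order=1, mode="constant", cval=0.0
    ).astype(np.float32)


def augment_pair(img, cfg: AugmentConfig, rng: np.random.Generator):
    """Return an augmented copy of an AnnotatedImage, coordinates included.

    Geometric draws that push any landmark outside the grid are resampled up
    to ``cfg.max_retries`` times before raising :class:`AugmentationError`.
    Deterministic for a given generator state.
    """
    shape = img.pixels.shape
    for _ in range(cfg.max_retries):
        m = _draw_affine(cfg, rng, shape)
        coords = _apply_affine_coords(m, img.landmarks)
        if _in_grid(coords, shape):
            break
    else:
        raise AugmentationError(
            f"no in-bounds geometric transform found in {cfg.max_retries} tries"
        )
    pixels = warp_image(img.pixels, m)

    # photometric ops: multiply, then shift, then noise, then blur, then clip
    if rng.random() < cfg.op_probability:
        pixels = pixels * rng.uniform(*cfg.pixel_multiply)
    if rng.random() < cfg.op_probability:
        pixels = pixels + rng.uniform(*cfg.pixel_shift)
    if rng.random() < cfg.op_probability and cfg.gaussian_noise_std > 0:
        pixels = pixels + rng.normal(0.0, cfg.gaussian_noise_std, size=pixels.shape)
    if rng.random() < cfg.op_probability:
        from scipy.ndimage import gaussian_filter

        pixels = gaussian_filter(pixels, sigma=rng.uniform(*cfg.gaussian_blur_sigma))
    pixels = np.clip(pixels, 0.0, 1.0).astype(np.float32)

    return replace(img, pixels=pixels, landmarks=coords)
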