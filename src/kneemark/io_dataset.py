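"""Reading, writing and geometric normalisation of annotated knee images.

Images are 2-D grayscale arrays with a physical pixel spacing in mm per axis.
Annotations are per-image sidecar records mapping landmark labels to
continuous, 0-based ``(x, y)`` pixel coordinates (x = column, y = row).
Resizing rescales coordinates and spacing together so that the physical
position ``coordinate * spacing`` of every landmark is preserved per axis.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .landmarks import PROTOCOLS, validate_labels


class AnnotationError(ValueError):
    """Raised for schema or validation problems in annotation records."""


@dataclass
class AnnotatedImage:
    """One protocol slice: intensities in [0, 1] plus landmark annotations.

    Attributes
    ----------
    patient_id : str
    knee_side : str
        ``"left"`` or ``"right"``.
    protocol : str
        One of the three acquisition protocols.
    pixels : ndarray, shape (H, W)
        Grayscale intensities scaled to [0, 1].
    spacing : tuple of float
        ``(sx, sy)`` mm per pixel along x (columns) and y (rows).
    landmarks : dict
        label -> ``(x, y)`` continuous 0-based pixel coordinates.
    image_id : str
        Unique record id; defaults to ``patient_id/protocol``.
    """

    patient_id: str
    knee_side: str
    protocol: str
    pixels: np.ndarray
    spacing: tuple[float, float]
    landmarks: dict[str, tuple[float, float]]
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise AnnotationError(f"unknown protocol {self.protocol!r}")
        if self.knee_side not in ("left", "right"):
            raise AnnotationError(f"knee_side must be left/right, got {self.knee_side!r}")
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise AnnotationError("pixels must be a 2-D grayscale grid")
        sx, sy = self.spacing
        if not (sx > 0 and sy > 0):
            raise AnnotationError(f"spacing must be positive, got {self.spacing}")
        validate_labels(self.landmarks, self.protocol)
        h, w = self.pixels.shape
        for label, (x, y) in self.landmarks.items():
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                raise AnnotationError(
                    f"landmark {label} at ({x}, {y}) outside {w}x{h} grid"
                )
        if not self.image_id:
            self.image_id = f"{self.patient_id}/{self.protocol}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _minmax_scale(pixels: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant image maps to all zeros."""
    pixels = np.asarray(pixels, dtype=np.float32)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi == lo:
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


def _read_pixels(image_path: Path) -> tuple[np.ndarray, tuple[float, float] | None]:
    """Read a grayscale image; returns (raw pixels, spacing from file or None)."""
    image_path = Path(image_path)
    suffix = image_path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(image_path))
        pixels = ds.pixel_array.astype(np.float32)
        if pixels.ndim != 2:
            raise AnnotationError("only single-frame grayscale DICOM is supported")
        spacing = None
        if getattr(ds, "PixelSpacing", None):
            # DICOM PixelSpacing is (row spacing, column spacing) = (sy, sx)
            sy, sx = (float(v) for v in ds.PixelSpacing)
            spacing = (sx, sy)
        return pixels, spacing
    with Image.open(image_path) as im:
        pixels = np.asarray(im.convert("F"), dtype=np.float32)
    return pixels, None


def load_annotated_image(image_path, annotation_record: dict) -> AnnotatedImage:
    """Load one image + sidecar annotation record into an :class:`AnnotatedImage`.

    The record must provide ``patient_id``, ``side``, ``protocol`` and
    ``landmarks`` (label -> [x, y]); ``spacing`` may come from the record or,
    for DICOM, from the PixelSpacing tag. Missing spacing is an explicit
    error -- 1 mm is never silently assumed.
    """
    pixels, file_spacing = _read_pixels(Path(image_path))
    spacing = annotation_record.get("spacing") or file_spacing
    if spacing is None:
        raise AnnotationError(
            f"{image_path}: no pixel spacing in sidecar or DICOM PixelSpacing tag"
        )
    return AnnotatedImage(
        patient_id=str(annotation_record["patient_id"]),
        knee_side=annotation_record["side"],
        protocol=annotation_record["protocol"],
        pixels=_minmax_scale(pixels),
        spacing=(float(spacing[0]), float(spacing[1])),
        landmarks={
            str(k): (float(v[0]), float(v[1]))
            for k, v in annotation_record["landmarks"].items()
        },
        image_id=annotation_record.get("image_id", ""),
    )


def annotation_record(img: AnnotatedImage) -> dict:
    """Serialise the annotation sidecar of ``img`` as a JSON-ready dict."""
    return {
        "patient_id": img.patient_id,
        "side": img.knee_side,
        "protocol": img.protocol,
        "spacing": [img.spacing[0], img.spacing[1]],
        "image_id": img.image_id,
        "landmarks": {k: [float(x), float(y)] for k, (x, y) in img.landmarks.items()},
    }


def write_annotation(img: AnnotatedImage, path) -> None:
    Path(path).write_text(json.dumps(annotation_record(img), indent=1))


def read_annotation(path) -> dict:
    return json.loads(Path(path).read_text())


def read_annotations_csv(path) -> list[dict]:
    """Read flattened annotations: one row per landmark.

    Columns: image_id, patient_id, side, protocol, sx, sy, label, x, y.
    """
    records: dict[str, dict] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = records.setdefault(
                row["image_id"],
                {
                    "image_id": row["image_id"],
                    "patient_id": row["patient_id"],
                    "side": row["side"],
                    "protocol": row["protocol"],
                    "spacing": [float(row["sx"]), float(row["sy"])],
                    "landmarks": {},
                },
            )
            rec["landmarks"][row["label"]] = [float(row["x"]), float(row["y"])]
    return list(records.values())


def resize_to_input(img: AnnotatedImage, target: tuple[int, int]) -> AnnotatedImage:
    """Resample to ``target = (W, H)`` pixels, bilinear, keeping physical geometry.

    Coordinates are multiplied by ``(W/W0, H/H0)`` and spacing by the inverse
    factors, so ``coordinate * spacing`` is invariant per axis. Aspect ratio is
    not preserved; anisotropy is absorbed into the per-axis spacing.
    """
    from skimage.transform import resize as sk_resize

    w_t, h_t = target
    if w_t <= 0 or h_t <= 0:
        raise ValueError(f"target dimensions must be positive, got {target}")
    h0, w0 = img.pixels.shape
    fx, fy = w_t / w0, h_t / h0
    pixels = sk_resize(
        img.pixels, (h_t, w_t), order=1, preserve_range=True, anti_aliasing=False
    ).astype(np.float32)
    return replace(
        img,
        pixels=pixels,
        spacing=(img.spacing[0] / fx, img.spacing[1] / fy),
        landmarks={k: (x * fx, y * fy) for k, (x, y) in img.landmarks.items()},
    )


@dataclass
class SplitPlan:
    """Patient-disjoint train/validation/test partition of image record ids."""

    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "train": self.train,
                "validation": self.validation,
                "test": self.test,
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(d["train"], d["validation"], d["test"], d["seed"])


def patient_wise_split(
    records,
    holdout_patients,
    train_fraction: float,
    seed: int,
) -> SplitPlan:
    """Split image records into train/validation/test without patient leakage.

    All records of ``holdout_patients`` go to the test set. The remaining
    records are shuffled with ``seed`` and split at
    ``round(train_fraction * n)``. ``records`` may be :class:`AnnotatedImage`
    objects or dicts with ``image_id`` and ``patient_id``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")

    def _fields(rec):
        if isinstance(rec, dict):
            return rec["image_id"], rec["patient_id"]
        return rec.image_id, rec.patient_id

    pairs = [_fields(r) for r in records]
    patients = {p for _, p in pairs}
    holdout = set(holdout_patients)
    missing = sorted(holdout - patients)
    if missing:
        raise ValueError(f"holdout patients absent from records: {missing}")

    test = [rid for rid, pid in pairs if pid in holdout]
    rest = [rid for rid, pid in pairs if pid not in holdout]
    rng = np.random.default_rng(seed)
    rest = [rest[i] for i in rng.permutation(len(rest))]
    n_train = round(train_fraction * len(rest))
    return SplitPlan(
        train=rest[:n_train], validation=rest[n_train:], test=test, seed=seed
    )
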