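"""Patellofemoral-instability indices from landmark coordinates.

Eight indices are computed from the thirteen protocol landmarks, four for
trochlear dysplasia (SA, TFA, TGD, LTI) and four for patellar height
(ISI, MISI, CDI, PTI). All constructions operate on physical points in mm
(pixel coordinates multiplied by per-axis spacing upstream), which makes
anisotropic spacing safe: angles and ratios are only meaningful after the
conversion, and TGD is reported directly in mm.

Constructions
-------------
SA   angle at T4 between rays T4->T3 and T4->T5 (degrees).
TFA  medial facet length d(T4,T5) over lateral facet length d(T4,T3).
TGD  (A + C)/2 - B with A, B, C the perpendicular distances of T3, T4, T5
     from the posterior condylar line through T1 and T2 (mm); may be <= 0
     for a flat or convex trochlea.
LTI  acute angle between line(T6,T7) and the posterior condylar line
     (T1, T2 taken from the paired trochlear-sulcus slice of the same knee).
ISI  patellar tendon length d(P4,P5) over patellar length d(P1,P4).
MISI d(P2,P5) over d(P1,P2).
CDI  d(P2,P6) over d(P1,P2).
PTI  cartilage overlap: distance along line(P1,P2) from the orthogonal
     projection of P3 to P2, over d(P1,P2); clamped at 0 when the projection
     falls distal to P2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

INDEX_NAMES = ("SA", "TFA", "TGD", "LTI", "ISI", "MISI", "CDI", "PTI")

#: landmark labels each index consumes
INDEX_INPUTS: dict[str, tuple[str, ...]] = {
    "SA": ("T3", "T4", "T5"),
    "TFA": ("T3", "T4", "T5"),
    "TGD": ("T1", "T2", "T3", "T4", "T5"),
    "LTI": ("T6", "T7", "T1", "T2"),
    "ISI": ("P1", "P4", "P5"),
    "MISI": ("P1", "P2", "P5"),
    "CDI": ("P1", "P2", "P6"),
    "PTI": ("P1", "P2", "P3"),
}

INDEX_UNITS = {
    "SA": "degrees",
    "TFA": "ratio",
    "TGD": "mm",
    "LTI": "degrees",
    "ISI": "ratio",
    "MISI": "ratio",
    "CDI": "ratio",
    "PTI": "ratio",
}


class GeometryError(ValueError):
    """Raised for degenerate constructions (coincident points, zero lengths)."""


@dataclass(frozen=True)
class IndexResult:
    """One measured index value with units and provenance."""

    name: str
    value: float
    units: str
    inputs_used: tuple[str, ...]
    construction_notes: str = ""


def _pt(p) -> np.ndarray:
    a = np.asarray(p, dtype=np.float64)
    if a.shape != (2,) or not np.all(np.isfinite(a)):
        raise GeometryError(f"invalid physical point {p!r}")
    return a


def _dist(p, q) -> float:
    return float(np.hypot(*(np.asarray(p, float) - np.asarray(q, float))))


def sulcus_angle(t3, t4, t5) -> float:
    """Angle (degrees) at vertex T4 between rays to T3 and T5, in (0, 180]."""
    t3, t4, t5 = _pt(t3), _pt(t4), _pt(t5)
    u, v = t3 - t4, t5 - t4
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0 or nv == 0:
        raise GeometryError("sulcus angle undefined: facet ray has zero length")
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def trochlear_facet_asymmetry(t3, t4, t5) -> float:
    """Medial facet length d(T4,T5) divided by lateral facet length d(T4,T3)."""
    medial = _dist(_pt(t4), _pt(t5))
    lateral = _dist(_pt(t4), _pt(t3))
    if medial == 0 or lateral == 0:
        raise GeometryError("facet asymmetry undefined: zero-length facet")
    return medial / lateral


def _line_distance(p, a, b) -> float:
    """Perpendicular distance of p from the line through a and b."""
    a, b, p = _pt(a), _pt(b), _pt(p)
    d = b - a
    n = float(np.hypot(*d))
    if n == 0:
        raise GeometryError("degenerate line: endpoints coincide")
    r = p - a
    return abs(float(d[0] * r[1] - d[1] * r[0])) / n


def trochlear_groove_depth(t1, t2, t3, t4, t5) -> float:
    """(A + C)/2 - B in mm, heights measured from the posterior condylar line."""
    a = _line_distance(t3, t1, t2)
    b = _line_distance(t4, t1, t2)
    c = _line_distance(t5, t1, t2)
    return (a + c) / 2.0 - b


def lateral_trochlear_inclination(t6, t7, t1, t2) -> float:
    """Acute angle (degrees) between line(T6,T7) and line(T1,T2), in [0, 90]."""
    u = _pt(t7) - _pt(t6)
    v = _pt(t2) - _pt(t1)
    nu, nv = float(np.hypot(*u)), float(np.hypot(*v))
    if nu == 0 or nv == 0:
        raise GeometryError("inclination undefined: degenerate line")
    c = abs(float(np.dot(u, v))) / (nu * nv)
    return math.degrees(math.acos(min(1.0, c)))


def insall_salvati(p1, p4, p5) -> float:
    """Tendon length d(P4,P5) over patellar length d(P1,P4)."""
    a = _dist(_pt(p1), _pt(p4))
    if a == 0:
        raise GeometryError("Insall-Salvati undefined: zero patellar length")
    return _dist(_pt(p4), _pt(p5)) / a


def modified_insall_salvati(p1, p2, p5) -> float:
    """d(P2,P5) over the articular-axis length proxy d(P1,P2)."""
    a = _dist(_pt(p1), _pt(p2))
    if a == 0:
        raise GeometryError("modified Insall-Salvati undefined: zero denominator")
    return _dist(_pt(p2), _pt(p5)) / a


def caton_deschamps(p1, p2, p6) -> float:
    """d(P2,P6) over d(P1,P2)."""
    a = _dist(_pt(p1), _pt(p2))
    if a == 0:
        raise GeometryError("Caton-Deschamps undefined: zero denominator")
    return _dist(_pt(p2), _pt(p6)) / a


def patellotrochlear(p1, p2, p3) -> float:
    """Cartilage overlap fraction along the P1->P2 axis, clamped at 0.

    A = d(P1,P2); B = signed distance from the orthogonal projection of P3
    onto line(P1,P2) to P2, positive towards P1. Returns max(B, 0) / A.
    """
    p1, p2, p3 = _pt(p1), _pt(p2), _pt(p3)
    axis = p2 - p1
    a = float(np.hypot(*axis))
    if a == 0:
        raise GeometryError("patellotrochlear undefined: degenerate axis")
    # position of P3's projection along the axis, from P1 (0) to P2 (a)
    s = float(np.dot(p3 - p1, axis)) / a
    return max(a - s, 0.0) / a


_CONSTRUCTORS = {
    "SA": sulcus_angle,
    "TFA": trochlear_facet_asymmetry,
    "TGD": trochlear_groove_depth,
    "LTI": lateral_trochlear_inclination,
    "ISI": insall_salvati,
    "MISI": modified_insall_salvati,
    "CDI": caton_deschamps,
    "PTI": patellotrochlear,
}

_NOTES = {
    "SA": "angle at T4 between rays to T3 and T5",
    "TFA": "d(T4,T5)/d(T4,T3), medial over lateral facet",
    "TGD": "(A+C)/2 - B, heights from line(T1,T2)",
    "LTI": "acute angle line(T6,T7) vs posterior condylar line(T1,T2)",
    "ISI": "d(P4,P5)/d(P1,P4)",
    "MISI": "d(P2,P5)/d(P1,P2)",
    "CDI": "d(P2,P6)/d(P1,P2)",
    "PTI": "projection overlap of P3 along P1->P2, clamped at 0",
}


@dataclass
class MeasurementReport:
    """Computed indices plus an explicit account of any skipped ones."""

    results: list[IndexResult] = field(default_factory=list)
    skipped: dict[str, list[str]] = field(default_factory=dict)

    def value(self, name: str) -> float:
        for r in self.results:
            if r.name == name:
                return r.value
        raise KeyError(name)

    def as_dict(self) -> dict[str, float]:
        return {r.name: r.value for r in self.results}


def to_physical(
    landmarks: Mapping[str, tuple[float, float]], spacing: tuple[float, float]
) -> dict[str, tuple[float, float]]:
    """Convert pixel coordinates to mm using per-axis spacing."""
    sx, sy = spacing
    return {k: (x * sx, y * sy) for k, (x, y) in landmarks.items()}


def measure_all(images) -> MeasurementReport:
    """Measure every index whose landmarks are present.

    ``images`` is an iterable of :class:`~kneemark.io_dataset.AnnotatedImage`
    (or objects exposing ``landmarks`` and ``spacing``), normally the up to
    three protocol slices of one knee. Each image's landmarks are converted
    to mm with its own spacing, then pooled. Indices whose landmarks are
    missing are reported in ``skipped`` rather than silently omitted.
    """
    if hasattr(images, "landmarks"):
        images = [images]
    physical: dict[str, tuple[float, float]] = {}
    for img in images:
        physical.update(to_physical(img.landmarks, img.spacing))

    report = MeasurementReport()
    for name in INDEX_NAMES:
        needed = INDEX_INPUTS[name]
        missing = [lbl for lbl in needed if lbl not in physical]
        if missing:
            report.skipped[name] = missing
            continue
        value = _CONSTRUCTORS[name](*(physical[lbl] for lbl in needed))
        report.results.append(
            IndexResult(
                name=name,
                value=float(value),
                units=INDEX_UNITS[name],
                inputs_used=needed,
                construction_notes=_NOTES[name],
            )
        )
    return report
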