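"""Synthetic knee phantoms with exactly known landmarks and index values.

The phantoms are stylised renderings -- soft-edged ellipses for condyles and
patella, Gaussian-profile ridge bands for facets, cartilage and tendon --
not anatomically realistic images. Each landmark coincides with a distinct
intensity feature (an extremum, band endpoint or corner) so the detection
task is well-posed, and every geometric construction parameter (groove depth,
facet asymmetry, inclination angle, tendon/patellar length ratios ...) is
chosen first and rendered second, so the ground-truth index values are known
in closed form before any measurement code runs.

Default canvas is 128 x 128 pixels at 0.8 mm isotropic spacing (desk-scale
training); 320 x 320 works the same way for full-scale runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import INDEX_NAMES
from .io_dataset import AnnotatedImage
from .landmarks import PATELLAR_HEIGHT, PROXIMAL_TROCHLEA, TROCHLEAR_SULCUS

_MARGIN = 4.0  # landmarks stay this many pixels inside the canvas


@dataclass
class PhantomSpec:
    """Geometry + appearance parameters for one phantom slice."""

    protocol: str
    params: dict
    canvas: tuple[int, int] = (128, 128)  # (H, W)
    spacing: tuple[float, float] = (0.8, 0.8)
    noise_level: float = 0.03
    seed: int = 0


# -- geometry ---------------------------------------------------------------

def _rot(points: dict, theta_deg: float, center) -> dict:
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    cx, cy = center
    return {
        k: (cx + c * (x - cx) - s * (y - cy), cy + s * (x - cx) + c * (y - cy))
        for k, (x, y) in points.items()
    }


def _axial_landmarks(p: dict) -> dict:
    cx, y_post = p["cx"], p["y_post"]
    return {
        "T1": (cx - p["condyle_sep"] / 2, y_post),
        "T2": (cx + p["condyle_sep"] / 2, y_post),
        "T3": (cx - p["facet_w_lat"], y_post - p["facet_h_lat"]),
        "T4": (cx + p["groove_jitter"], y_post - p["groove_h"]),
        "T5": (cx + p["facet_w_med"], y_post - p["facet_h_med"]),
    }


def _proximal_landmarks(p: dict) -> dict:
    a = math.radians(p["inclination_deg"])
    d = (math.cos(a), math.sin(a))
    mx, my = p["mid_x"], p["mid_y"]
    half = p["facet_len"] / 2
    return {
        "T6": (mx - half * d[0], my - half * d[1]),
        "T7": (mx + half * d[0], my + half * d[1]),
    }


def _sagittal_landmarks(p: dict) -> dict:
    phi = math.radians(p["tilt_deg"])
    u = (math.sin(phi), math.cos(phi))  # distal, along the patellar axis
    n = (u[1], -u[0])  # posterior normal
    a_len = p["patellar_len"]
    p1 = (p["p1_x"], p["p1_y"])
    p4 = (p1[0] + a_len * u[0], p1[1] + a_len * u[1])
    # distal articular margin: proximal to the apex and clearly posterior,
    # so P2 and P4 stay separable at heatmap scale
    p2 = (
        p1[0] + 0.82 * a_len * u[0] + 5.5 * n[0],
        p1[1] + 0.82 * a_len * u[1] + 5.5 * n[1],
    )
    psi = math.radians(p["tilt_deg"] + p["tendon_dev_deg"])
    u5 = (math.sin(psi), math.cos(psi))
    b_len = p["isi"] * a_len
    p5 = (p4[0] + b_len * u5[0], p4[1] + b_len * u5[1])

    l12 = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
    v12 = ((p2[0] - p1[0]) / l12, (p2[1] - p1[1]) / l12)
    m = (v12[1], -v12[0])
    s = (1.0 - p["pti"]) * l12
    p3 = (
        p1[0] + s * v12[0] + p["cartilage_off"] * m[0],
        p1[1] + s * v12[1] + p["cartilage_off"] * m[1],
    )
    delta = math.radians(p["tilt_deg"] - p["plateau_dev_deg"])
    w = (math.sin(delta), math.cos(delta))
    d6 = p["cdi"] * l12
    p6 = (p2[0] + d6 * w[0], p2[1] + d6 * w[1])
    return {"P1": p1, "P2": p2, "P3": p3, "P4": p4, "P5": p5, "P6": p6}


_LANDMARK_FNS = {
    TROCHLEAR_SULCUS: _axial_landmarks,
    PROXIMAL_TROCHLEA: _proximal_landmarks,
    PATELLAR_HEIGHT: _sagittal_landmarks,
}


def spec_landmarks(spec: PhantomSpec) -> dict:
    """Exact landmark coordinates implied by the spec (rotation applied)."""
    h, w = spec.canvas
    pts = _LANDMARK_FNS[spec.protocol](spec.params)
    return _rot(pts, spec.params.get("rotation_deg", 0.0), ((w - 1) / 2, (h - 1) / 2))


def ground_truth_indices(spec: PhantomSpec) -> dict[str, float]:
    """Closed-form index values from the construction parameters.

    Rigid rotation of the whole slice leaves every index unchanged, so the
    values are computed in the unrotated construction frame. Only the indices
    a single slice supports are returned.
    """
    p = spec.params
    sx, sy = spec.spacing
    if sx != sy:
        raise ValueError("phantom ground truth assumes isotropic spacing")
    out: dict[str, float] = {}
    if spec.protocol == TROCHLEAR_SULCUS:
        pts = _axial_landmarks(p)
        t3, t4, t5 = pts["T3"], pts["T4"], pts["T5"]
        r1 = (t3[0] - t4[0], t3[1] - t4[1])
        r2 = (t5[0] - t4[0], t5[1] - t4[1])
        cross = r1[0] * r2[1] - r1[1] * r2[0]
        dot = r1[0] * r2[0] + r1[1] * r2[1]
        out["SA"] = abs(math.degrees(math.atan2(cross, dot)))
        out["TFA"] = math.hypot(*r2) / math.hypot(*r1)
        out["TGD"] = ((p["facet_h_lat"] + p["facet_h_med"]) / 2 - p["groove_h"]) * sx
    elif spec.protocol == PROXIMAL_TROCHLEA:
        out["LTI"] = p["inclination_deg"]
    else:
        pts = _sagittal_landmarks(p)
        out["ISI"] = p["isi"]
        out["PTI"] = p["pti"]
        out["CDI"] = p["cdi"]
        p1, p2, p5 = pts["P1"], pts["P2"], pts["P5"]
        l12 = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
        out["MISI"] = math.hypot(p5[0] - p2[0], p5[1] - p2[1]) / l12
    return out


# -- rendering --------------------------------------------------------------

def _grid(shape):
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    return x, y


def _band(x, y, a, b, width, amp):
    """Gaussian-profile ridge along segment a-b; sharp ends give corner cues."""
    ax, ay = a
    dx, dy = b[0] - ax, b[1] - ay
    L2 = dx * dx + dy * dy
    t = np.clip(((x - ax) * dx + (y - ay) * dy) / L2, 0.0, 1.0)
    d2 = (x - (ax + t * dx)) ** 2 + (y - (ay + t * dy)) ** 2
    return amp * np.exp(-d2 / (2.0 * width**2))


def _ellipse(x, y, center, rx, ry, theta_deg, amp, edge=1.5):
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    xr = c * (x - center[0]) + s * (y - center[1])
    yr = -s * (x - center[0]) + c * (y - center[1])
    q = np.sqrt((xr / rx) ** 2 + (yr / ry) ** 2)
    return amp / (1.0 + np.exp((q - 1.0) * (rx + ry) / (2 * edge)))


def _bump(x, y, center, radius, amp):
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
    return amp * np.exp(-d2 / (2.0 * radius**2))


def _render(spec: PhantomSpec, pts: dict) -> np.ndarray:
    h, w = spec.canvas
    x, y = _grid((h, w))
    theta = spec.params.get("rotation_deg", 0.0)
    img = 0.06 + 0.05 * (y / h)  # faint gradient background

    if spec.protocol == TROCHLEAR_SULCUS:
        p = spec.params
        ry = p["condyle_ry"]
        for t in ("T1", "T2"):
            cx_, cy_ = pts[t]
            tr = math.radians(theta)
            # condyle ellipse whose (rotated) posterior pole is the landmark
            cen = (cx_ + ry * math.sin(tr), cy_ - ry * math.cos(tr))
            img = img + _ellipse(x, y, cen, p["condyle_rx"], ry, theta, 0.45)
        img = img + _band(x, y, pts["T3"], pts["T4"], 2.2, 0.65)
        img = img + _band(x, y, pts["T4"], pts["T5"], 2.2, 0.65)
        # guaranteed landmark-adjacent cues: corner/edge markers at each point
        img = img + _bump(x, y, pts["T3"], 2.0, 0.3)
        img = img + _bump(x, y, pts["T5"], 2.0, 0.3)
        img = img + _bump(x, y, pts["T4"], 2.0, -0.35)
        img = img + _bump(x, y, pts["T1"], 2.0, 0.35)
        img = img + _bump(x, y, pts["T2"], 2.0, -0.3)
    elif spec.protocol == PROXIMAL_TROCHLEA:
        p = spec.params
        mid = ((pts["T6"][0] + pts["T7"][0]) / 2, (pts["T6"][1] + pts["T7"][1]) / 2)
        img = img + _ellipse(
            x, y, (mid[0], mid[1] + 16), p["mass_rx"], p["mass_ry"], theta, 0.4
        )
        img = img + _band(x, y, pts["T6"], pts["T7"], 2.2, 0.65)
        img = img + _bump(x, y, pts["T6"], 2.0, 0.35)
        img = img + _bump(x, y, pts["T7"], 2.0, -0.3)
    else:
        p = spec.params
        p1, p4 = np.array(pts["P1"]), np.array(pts["P4"])
        center = (p1 + p4) / 2
        axis_deg = math.degrees(math.atan2(p4[1] - p1[1], p4[0] - p1[0]))
        img = img + _ellipse(
            x, y, tuple(center), p["patellar_len"] / 2, p["patellar_w"], axis_deg, 0.55
        )
        img = img + _band(x, y, pts["P4"], pts["P5"], 1.8, 0.5)  # patellar tendon
        # trochlear cartilage: band starting exactly at P3 running distally
        p3 = np.array(pts["P3"])
        v = p4 - p1
        v = v / np.hypot(*v)
        img = img + _band(x, y, tuple(p3), tuple(p3 + 26 * v), 1.8, 0.55)
        # tibial plateau edge with its anterior corner at P6
        p6 = np.array(pts["P6"])
        mpost = np.array([v[1], -v[0]])
        img = img + _band(x, y, tuple(p6), tuple(p6 + 26 * mpost), 2.0, 0.45)
        img = img + _band(x, y, tuple(p6), tuple(p6 + 18 * v), 2.0, 0.35)
        img = img + _bump(x, y, pts["P5"], 4.0, 0.25)  # tuberosity mass
        img = img + _bump(x, y, pts["P5"], 1.6, 0.4)  # insertion point cue
        img = img + _bump(x, y, pts["P2"], 1.8, 0.4)  # articular margin cue
        img = img + _bump(x, y, pts["P1"], 2.0, 0.35)  # proximal pole cue
        img = img + _bump(x, y, pts["P4"], 1.8, -0.35)  # apex cue
        img = img + _bump(x, y, pts["P3"], 2.0, 0.35)  # cartilage margin cue
        img = img + _bump(x, y, pts["P6"], 1.8, -0.3)  # plateau corner cue
    return img


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator | None = None):
    """Render one phantom; returns an :class:`AnnotatedImage`.

    Annotations are the exact generating coordinates. Deterministic for a
    given spec (``spec.seed`` drives the noise when no generator is passed).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    pts = spec_landmarks(spec)
    for label, (px, py) in pts.items():
        if not (_MARGIN <= px <= w - 1 - _MARGIN and _MARGIN <= py <= h - 1 - _MARGIN):
            raise ValueError(f"landmark {label} at ({px:.1f}, {py:.1f}) out of canvas")
    img = _render(spec, pts)
    if spec.noise_level > 0:
        img = img + rng.normal(0.0, spec.noise_level, size=img.shape)
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(img, sigma=0.6)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return AnnotatedImage(
        patient_id=spec.params.get("patient_id", "phantom"),
        knee_side=spec.params.get("side", "right"),
        protocol=spec.protocol,
        pixels=img,
        spacing=spec.spacing,
        landmarks=pts,
        image_id=spec.params.get("image_id", ""),
    )


# -- cohort sampling --------------------------------------------------------

#: default sampling ranges; phantoms span normal and dysplastic morphologies
#: (sulcus angles ~120-170 degrees, ISI 0.6-1.6, groove depths down to flat)
DEFAULT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    TROCHLEAR_SULCUS: {
        "cx": (58.0, 70.0),
        "y_post": (88.0, 100.0),
        "condyle_sep": (44.0, 56.0),
        "condyle_rx": (13.0, 17.0),
        "condyle_ry": (10.0, 14.0),
        "facet_w_lat": (18.0, 26.0),
        "facet_w_med": (14.0, 24.0),
        "facet_h_lat": (20.0, 30.0),
        "facet_h_med": (20.0, 30.0),
        "groove_frac": (0.35, 0.9),  # groove height as fraction of facet height
        "groove_jitter": (-3.0, 3.0),
        "rotation_deg": (-6.0, 6.0),
    },
    PROXIMAL_TROCHLEA: {
        "mid_x": (56.0, 72.0),
        "mid_y": (52.0, 70.0),
        "facet_len": (26.0, 36.0),
        "inclination_deg": (8.0, 32.0),
        "mass_rx": (22.0, 30.0),
        "mass_ry": (14.0, 20.0),
        "rotation_deg": (-6.0, 6.0),
    },
    PATELLAR_HEIGHT: {
        "p1_x": (42.0, 58.0),
        "p1_y": (10.0, 18.0),
        "patellar_len": (26.0, 36.0),
        "patellar_w": (7.0, 10.0),
        "tilt_deg": (-10.0, 10.0),
        "tendon_dev_deg": (-8.0, 8.0),
        "plateau_dev_deg": (15.0, 35.0),
        "cartilage_off": (4.0, 8.0),
        "isi": (0.6, 1.6),
        "cdi": (0.6, 1.4),
        "pti": (0.15, 0.9),
        "rotation_deg": (-6.0, 6.0),
    },
}


#: parameters that are angles, ratios or fractions -- never rescaled with canvas
_SCALE_FREE = {
    "rotation_deg", "inclination_deg", "tilt_deg", "tendon_dev_deg",
    "plateau_dev_deg", "groove_frac", "isi", "cdi", "pti",
}


def _sample_params(protocol: str, rng, ranges, scale: float = 1.0) -> dict:
    p = {}
    for k, (lo, hi) in ranges[protocol].items():
        v = float(rng.uniform(lo, hi))
        p[k] = v if k in _SCALE_FREE else v * scale
    if protocol == TROCHLEAR_SULCUS:
        p["groove_h"] = p["groove_frac"] * min(p["facet_h_lat"], p["facet_h_med"])
    return p


def _sample_spec(
    protocol, rng, ranges, canvas, spacing, noise_level, max_tries=100
) -> PhantomSpec:
    h, w = canvas
    scale = min(h, w) / 128.0  # default ranges are expressed on a 128 px canvas
    for _ in range(max_tries):
        spec = PhantomSpec(
            protocol=protocol,
            params=_sample_params(protocol, rng, ranges, scale),
            canvas=canvas,
            spacing=spacing,
            noise_level=noise_level,
        )
        pts = spec_landmarks(spec)
        if all(
            _MARGIN <= x <= w - 1 - _MARGIN and _MARGIN <= y <= h - 1 - _MARGIN
            for x, y in pts.values()
        ):
            return spec
    raise RuntimeError(f"no in-canvas {protocol} phantom found in {max_tries} tries")


def generate_cohort(
    n: int,
    seed: int,
    protocol: str | None = None,
    parameter_ranges: dict | None = None,
    canvas: tuple[int, int] = (128, 128),
    spacing: tuple[float, float] = (0.8, 0.8),
    noise_level: float = 0.03,
):
    """Sample ``n`` phantoms (or ``n`` knees when ``protocol`` is None).

    With a single protocol, ``n`` images of that protocol are produced and
    grouped into synthetic patients of 2-3 images so patient-wise splitting
    is exercised. With ``protocol=None`` each of ``n`` knees contributes all
    three protocol slices (sharing one in-plane rotation, as slices of one
    series are rotationally aligned), so all eight indices have ground truth.

    Returns ``(images, truth)`` where ``truth`` is a DataFrame with one row
    per image and the eight index columns (NaN where a slice does not carry
    the landmarks for an index).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = {k: dict(v) for k, v in DEFAULT_RANGES.items()}
    if parameter_ranges:
        for proto, upd in parameter_ranges.items():
            for key, (lo, hi) in upd.items():
                if lo > hi:
                    raise ValueError(f"range {proto}.{key} = {(lo, hi)} not well-ordered")
                ranges[proto][key] = (lo, hi)

    rng = np.random.default_rng(seed)
    images: list[AnnotatedImage] = []
    rows: list[dict] = []

    def _emit(spec: PhantomSpec, patient_id: str, side: str, image_id: str):
        spec.params["patient_id"] = patient_id
        spec.params["side"] = side
        spec.params["image_id"] = image_id
        img = generate_phantom(spec, rng)
        images.append(img)
        row = {"image_id": image_id, "patient_id": patient_id, "protocol": spec.protocol}
        truth = ground_truth_indices(spec)
        for name in INDEX_NAMES:
            row[name] = truth.get(name, np.nan)
        rows.append(row)

    if protocol is None:
        for i in range(n):
            pid = f"pat{i:04d}"
            side = "left" if i % 2 else "right"
            shared_rot = float(rng.uniform(*ranges[TROCHLEAR_SULCUS]["rotation_deg"]))
            for proto in (TROCHLEAR_SULCUS, PROXIMAL_TROCHLEA, PATELLAR_HEIGHT):
                spec = _sample_spec(proto, rng, ranges, canvas, spacing, noise_level)
                if proto in (TROCHLEAR_SULCUS, PROXIMAL_TROCHLEA):
                    spec.params["rotation_deg"] = shared_rot
                _emit(spec, pid, side, f"{pid}/{proto}")
    else:
        # group 2-3 consecutive images per synthetic patient
        pid_of: list[str] = []
        i, pat = 0, 0
        while len(pid_of) < n:
            k = 2 if pat % 2 == 0 else 3
            pid_of.extend([f"pat{pat:04d}"] * k)
            pat += 1
        pid_of = pid_of[:n]
        for i in range(n):
            spec = _sample_spec(protocol, rng, ranges, canvas, spacing, noise_level)
            side = "left" if i % 2 else "right"
            _emit(spec, pid_of[i], side, f"{pid_of[i]}/{protocol}/{i:04d}")

    return images, pd.DataFrame(rows)
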