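"""Evaluation statistics: SDR by radius, MAE +/- STD, ICC with grading.

Landmark accuracy is summarised by the successful detection rate

    SDR_R = #{i : ||t_i - p_i|| < R} / N * 100        (strict inequality)

at radii R in mm, and by the mean absolute error (mean Euclidean distance in
mm) with its sample standard deviation. Agreement between index values from
ground-truth and predicted landmarks is summarised by the two-way
random-effects, absolute-agreement, single-measurement intraclass
correlation coefficient ICC(2,1) with an F-based 95% confidence interval,
graded poor (< 0.5) / moderate (0.5-0.75) / good (0.75-0.9) /
excellent (> 0.9).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .indices import measure_all

DEFAULT_RADII_MM = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0)


def _distances(pairs) -> np.ndarray:
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no evaluation pairs")
    d = np.array(
        [np.hypot(t[0] - p[0], t[1] - p[1]) for t, p in pairs], dtype=np.float64
    )
    return d


def sdr(pairs, radii=DEFAULT_RADII_MM) -> dict[float, float]:
    """Successful detection rate (%) per radius; distances strictly < R count."""
    d = _distances(pairs)
    return {float(r): float((d < r).mean() * 100.0) for r in radii}


def mae(pairs) -> tuple[float, float]:
    """Mean Euclidean distance and its sample (n-1) standard deviation."""
    d = _distances(pairs)
    std = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), std


def icc(truth, pred) -> tuple[float, float, float]:
    """ICC(2,1), absolute agreement, with F-based 95% CI.

    ``truth`` and ``pred`` are paired scalar measurement series (the two
    "raters"); the statistic is symmetric in their order. Zero
    between-subject variance yields ICC 0 with a warning rather than NaN.
    """
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError("truth and pred must be 1-D series of equal length")
    n = truth.size
    if n < 5:
        raise ValueError(f"need >= 5 paired measurements for ICC, got {n}")
    if np.ptp(truth) == 0 and np.ptp(pred) == 0:
        warnings.warn("zero between-subject variance; ICC undefined, returning 0")
        return 0.0, 0.0, 0.0

    import pandas as pd
    import pingouin as pg

    data = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["truth", "pred"], n),
            "score": np.concatenate([truth, pred]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=data, targets="subject", raters="rater", ratings="score"
        )
    # two-way random effects, absolute agreement, single measurement:
    # labelled ICC2 (Shrout-Fleiss) or ICC(A,1) (McGraw-Wong) across versions
    table = table.set_index("Type")
    key = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    row = table.loc[key]
    value = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    if not np.isfinite(value):
        warnings.warn("ICC not finite (degenerate variance structure); returning 0")
        return 0.0, 0.0, 0.0
    value = float(min(max(value, -1.0), 1.0))
    if not np.isfinite(lo):
        lo = value
    if not np.isfinite(hi):
        hi = value
    return value, lo, hi


def grade_reliability(icc_value: float) -> str:
    """Map an ICC value to poor/moderate/good/excellent.

    Cut points 0.5, 0.75, 0.9; boundary values fall in the closed middle
    bands (0.5 -> moderate, 0.75 and 0.9 -> good), with excellent strictly
    above 0.9.
    """
    if not -1.0 <= icc_value <= 1.0:
        raise ValueError(f"ICC must be in [-1, 1], got {icc_value}")
    if icc_value < 0.5:
        return "poor"
    if icc_value < 0.75:
        return "moderate"
    if icc_value <= 0.9:
        return "good"
    return "excellent"


@dataclass
class LandmarkStats:
    label: str
    mae_mm: float
    std_mm: float
    sdr: dict[float, float]
    n: int


@dataclass
class IndexStats:
    name: str
    icc: float
    ci95: tuple[float, float]
    grade: str
    mae: float
    std: float
    n: int


@dataclass
class EvalReport:
    """Per-landmark detection accuracy and per-index measurement agreement."""

    landmarks: dict[str, LandmarkStats] = field(default_factory=dict)
    indices: dict[str, IndexStats] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "landmarks": {
                k: {
                    "mae_mm": v.mae_mm,
                    "std_mm": v.std_mm,
                    "sdr": {str(r): s for r, s in v.sdr.items()},
                    "n": v.n,
                }
                for k, v in self.landmarks.items()
            },
            "indices": {
                k: {
                    "icc": v.icc,
                    "ci95": list(v.ci95),
                    "grade": v.grade,
                    "mae": v.mae,
                    "std": v.std,
                    "n": v.n,
                }
                for k, v in self.indices.items()
            },
        }

    def sdr_table(self):
        """Per-landmark SDR as a DataFrame (radii as columns, in mm)."""
        import pandas as pd

        return pd.DataFrame(
            {lbl: st.sdr for lbl, st in self.landmarks.items()}
        ).T.sort_index()


def evaluate_run(
    truth_images,
    predictions: dict[str, dict],
    radii=DEFAULT_RADII_MM,
) -> EvalReport:
    """Assemble the full evaluation report for one test run.

    ``truth_images`` are annotated ground-truth images; ``predictions`` maps
    ``image_id`` to predicted landmark coordinate dicts in the same pixel
    frame. Distances are converted to mm with each image's spacing. Indices
    are computed per image from both coordinate sets and compared by
    ICC / MAE across the run.
    """
    truth_images = list(truth_images)
    truth_ids = {im.image_id for im in truth_images}
    unmatched = sorted(truth_ids.symmetric_difference(predictions))
    if unmatched:
        raise ValueError(f"unmatched image ids between truth and predictions: {unmatched}")

    per_landmark: dict[str, list] = {}
    index_pairs: dict[str, list] = {}
    for im in truth_images:
        pred = predictions[im.image_id]
        sx, sy = im.spacing
        for label, (tx, ty) in im.landmarks.items():
            if label not in pred:
                raise ValueError(f"{im.image_id}: prediction missing landmark {label}")
            px, py = pred[label]
            per_landmark.setdefault(label, []).append(
                ((tx * sx, ty * sy), (px * sx, py * sy))
            )
        t_rep = measure_all([im])
        p_img = type(im)(
            patient_id=im.patient_id,
            knee_side=im.knee_side,
            protocol=im.protocol,
            pixels=im.pixels,
            spacing=im.spacing,
            landmarks={k: tuple(v) for k, v in pred.items()},
            image_id=im.image_id,
        )
        p_rep = measure_all([p_img])
        p_vals = p_rep.as_dict()
        for r in t_rep.results:
            if r.name in p_vals:
                index_pairs.setdefault(r.name, []).append((r.value, p_vals[r.name]))

    report = EvalReport()
    for label in sorted(per_landmark):
        pairs = per_landmark[label]
        m, s = mae(pairs)
        report.landmarks[label] = LandmarkStats(
            label=label, mae_mm=m, std_mm=s, sdr=sdr(pairs, radii), n=len(pairs)
        )
    for name in sorted(index_pairs):
        pairs = index_pairs[name]
        tvals = [t for t, _ in pairs]
        pvals = [p for _, p in pairs]
        value, lo, hi = icc(tvals, pvals)
        m, s = mae([((t, 0.0), (p, 0.0)) for t, p in pairs])
        report.indices[name] = IndexStats(
            name=name,
            icc=value,
            ci95=(lo, hi),
            grade=grade_reliability(min(max(value, -1.0), 1.0)),
            mae=m,
            std=s,
            n=len(pairs),
        )
    return report
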