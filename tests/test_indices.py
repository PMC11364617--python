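import math

import numpy as np
import pytest

from kneemark.indices import (
    GeometryError,
    caton_deschamps,
    insall_salvati,
    lateral_trochlear_inclination,
    measure_all,
    modified_insall_salvati,
    patellotrochlear,
    sulcus_angle,
    trochlear_facet_asymmetry,
    trochlear_groove_depth,
)

import _oracles as oracle


class TestWorkedExamples:
    def test_sulcus_angle(self):
        assert sulcus_angle((0, 1), (0, 0), (1, 0)) == pytest.approx(90.0)
        assert sulcus_angle((-1, 0), (0, 0), (1, 0)) == pytest.approx(180.0)
        assert sulcus_angle((-4, 3), (0, 0), (4, 3)) == pytest.approx(
            math.degrees(math.acos(-7 / 25))
        )
        with pytest.raises(GeometryError):
            sulcus_angle((0, 0), (0, 0), (1, 0))

    def test_facet_asymmetry(self):
        assert trochlear_facet_asymmetry((0, 5), (0, 0), (5, 0)) == pytest.approx(1.0)
        assert trochlear_facet_asymmetry((6, 8), (0, 0), (-3, 4)) == pytest.approx(0.5)
        with pytest.raises(GeometryError):
            trochlear_facet_asymmetry((0, 0), (0, 0), (1, 1))

    def test_groove_depth(self):
        # horizontal condylar line: heights are just y-offsets
        assert trochlear_groove_depth(
            (0, 0), (10, 0), (1, 8), (5, 5), (9, 8)
        ) == pytest.approx(3.0)
        # flat trochlea
        assert trochlear_groove_depth(
            (0, 0), (10, 0), (1, 4), (5, 4), (9, 4)
        ) == pytest.approx(0.0)
        # point-line distance for a slanted line enters the formula
        d = oracle.point_line_distance((0, 5), (0, 0), (3, 4))
        assert d == pytest.approx(3.0)
        with pytest.raises(GeometryError):
            trochlear_groove_depth((1, 1), (1, 1), (0, 2), (1, 2), (2, 2))

    def test_lateral_trochlear_inclination(self):
        assert lateral_trochlear_inclination(
            (0, 0), (10, 0), (3, 5), (13, 5)
        ) == pytest.approx(0.0)
        assert lateral_trochlear_inclination(
            (0, 0), (10, 10), (0, 0), (1, 0)
        ) == pytest.approx(45.0)
        assert lateral_trochlear_inclination(
            (0, 0), (4, 3), (0, 0), (1, 0)
        ) == pytest.approx(math.degrees(math.atan2(3, 4)))

    def test_patellar_height_ratios(self):
        assert insall_salvati((0, 8), (0, 0), (0, -12)) == pytest.approx(1.5)
        assert insall_salvati((0, 8), (0, 0), (5, -12)) == pytest.approx(13 / 8)
        assert modified_insall_salvati((0, 8), (0, 0), (0, -10)) == pytest.approx(1.25)
        assert modified_insall_salvati((0, 8), (0, 0), (6, -8)) == pytest.approx(1.25)
        assert caton_deschamps((0, 8), (0, 0), (4, -3)) == pytest.approx(5 / 8)
        assert caton_deschamps((0, 8), (0, 0), (0, -9.6)) == pytest.approx(1.2)

    def test_patellotrochlear(self):
        assert patellotrochlear((0, 10), (0, 0), (3, 6)) == pytest.approx(0.6)
        assert patellotrochlear((0, 10), (0, 0), (4, 10)) == pytest.approx(1.0)
        assert patellotrochlear((0, 10), (0, 0), (4, -2)) == 0.0  # clamp past P2


def _random_points(rng, n):
    return [tuple(rng.uniform(-50, 50, 2)) for _ in range(n)]


class TestOracleEquivalence:
    """All constructions agree with independent brute-force geometry."""

    def test_thousand_random_configurations(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            t1, t2, t3, t4, t5, p1, p2, p3 = _random_points(rng, 8)
            assert sulcus_angle(t3, t4, t5) == pytest.approx(
                oracle.angle_at_vertex(t3, t4, t5), abs=1e-9
            )
            assert trochlear_facet_asymmetry(t3, t4, t5) == pytest.approx(
                oracle.dist(t4, t5) / oracle.dist(t4, t3), abs=1e-9
            )
            expected_tgd = (
                oracle.point_line_distance(t3, t1, t2)
                + oracle.point_line_distance(t5, t1, t2)
            ) / 2 - oracle.point_line_distance(t4, t1, t2)
            assert trochlear_groove_depth(t1, t2, t3, t4, t5) == pytest.approx(
                expected_tgd, abs=1e-9
            )
            assert lateral_trochlear_inclination(t3, t4, t1, t2) == pytest.approx(
                oracle.acute_angle_between_lines(t3, t4, t1, t2), abs=1e-9
            )
            assert insall_salvati(p1, p2, p3) == pytest.approx(
                oracle.dist(p2, p3) / oracle.dist(p1, p2), abs=1e-9
            )
            assert modified_insall_salvati(p1, p2, p3) == pytest.approx(
                oracle.dist(p2, p3) / oracle.dist(p1, p2), abs=1e-9
            )
            assert caton_deschamps(p1, p2, p3) == pytest.approx(
                oracle.dist(p2, p3) / oracle.dist(p1, p2), abs=1e-9
            )
            t = oracle.project_param(p3, p1, p2)
            expected_pti = max(1.0 - t, 0.0)
            assert patellotrochlear(p1, p2, p3) == pytest.approx(
                expected_pti, abs=1e-9
            )


class TestInvariances:
    def _rigid(self, pts, theta, shift, rng=None):
        c, s = math.cos(theta), math.sin(theta)
        return [
            (c * x - s * y + shift[0], s * x + c * y + shift[1]) for x, y in pts
        ]

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            pts = _random_points(rng, 5)
            theta = rng.uniform(0, 2 * math.pi)
            shift = rng.uniform(-20, 20, 2)
            moved = self._rigid(pts, theta, shift)
            assert sulcus_angle(*pts[2:5]) == pytest.approx(
                sulcus_angle(*moved[2:5]), abs=1e-8
            )
            assert trochlear_groove_depth(*pts) == pytest.approx(
                trochlear_groove_depth(*moved), abs=1e-8
            )
            assert patellotrochlear(*pts[:3]) == pytest.approx(
                patellotrochlear(*moved[:3]), abs=1e-8
            )

    def test_uniform_scaling(self):
        rng = np.random.default_rng(10)
        pts = _random_points(rng, 5)
        scaled = [(3.7 * x, 3.7 * y) for x, y in pts]
        assert trochlear_facet_asymmetry(*pts[2:5]) == pytest.approx(
            trochlear_facet_asymmetry(*scaled[2:5]), abs=1e-9
        )
        assert sulcus_angle(*pts[2:5]) == pytest.approx(
            sulcus_angle(*scaled[2:5]), abs=1e-9
        )
        assert trochlear_groove_depth(*scaled) == pytest.approx(
            3.7 * trochlear_groove_depth(*pts), abs=1e-8
        )


class TestMeasureAll:
    def test_full_knee_yields_eight_indices(self, small_knee_cohort):
        images, _ = small_knee_cohort
        report = measure_all(images[:3])
        assert {r.name for r in report.results} == {
            "SA", "TFA", "TGD", "LTI", "ISI", "MISI", "CDI", "PTI"
        }
        assert report.skipped == {}
        for r in report.results:
            assert r.units in ("degrees", "mm", "ratio")
            assert r.inputs_used

    def test_patellar_height_only_yields_four(self, small_knee_cohort):
        images, _ = small_knee_cohort
        sagittal = [im for im in images[:3] if im.protocol == "patellar_height"]
        report = measure_all(sagittal)
        assert {r.name for r in report.results} == {"ISI", "MISI", "CDI", "PTI"}
        assert set(report.skipped) == {"SA", "TFA", "TGD", "LTI"}
        assert "T4" in report.skipped["SA"]

    def test_anisotropic_spacing_converted_before_ratios(self):
        from kneemark.io_dataset import AnnotatedImage

        img = AnnotatedImage(
            patient_id="p", knee_side="left", protocol="patellar_height",
            pixels=np.zeros((64, 64)), spacing=(0.5, 1.0),
            landmarks={"P1": (10, 10), "P4": (10, 26), "P5": (10, 50)},
        )
        report = measure_all([img])
        # physical lengths: patella 16 px * 1.0 = 16 mm, tendon 24 px * 1.0 = 24 mm
        assert report.value("ISI") == pytest.approx(1.5)
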