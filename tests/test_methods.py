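import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cupversion.geometry import BeamGeometry, CupPose, EllipseParams, project_lateral, project_rim, project_silhouette
from cupversion.landmarks import (
    AcklandMeasures,
    HassanMeasures,
    LateralMeasures,
    LewinnekMeasures,
    LiawLandmarks,
    WidmerMeasures,
    extract_landmarks,
    extract_lateral_landmarks,
)
from cupversion.methods import (
    compute_version,
    version_ackland,
    version_hassan,
    version_lewinnek,
    version_liaw,
    version_widmer,
    version_widmer_arcsin,
    version_woo_morrey,
)

from conftest import random_poses


def _ellipse_landmarks(a, b):
    e = EllipseParams((0.0, 0.0), a, b, 0.0)
    return {
        "liaw": extract_landmarks(e, None, 0.1, "liaw"),
        "lewinnek": extract_landmarks(e, None, 0.1, "lewinnek"),
        "hassan": extract_landmarks(e, None, min(0.9 * a, max(b * 1.2, 0.2)), "hassan"),
        "ackland": extract_landmarks(e, None, 0.1, "ackland"),
    }


class TestLiaw:
    def test_beta_zero(self):
        lm = LiawLandmarks(A=np.array([-2.0, 0.0]), B=np.array([0.0, 0.0]), E=np.array([-1.0, 0.0]))
        assert version_liaw(lm).value_deg == pytest.approx(0.0)

    def test_beta_45_reads_90(self):
        lm = LiawLandmarks(A=np.array([-2.0, 0.0]), B=np.array([0.0, 0.0]), E=np.array([-1.0, 1.0]))
        assert version_liaw(lm).value_deg == pytest.approx(90.0)

    def test_half_ratio_reads_30(self):
        lm = _ellipse_landmarks(25.0, 12.5)["liaw"]
        assert version_liaw(lm).value_deg == pytest.approx(30.0, abs=1e-9)

    def test_beta_above_45_errors(self):
        lm = LiawLandmarks(A=np.array([-2.0, 0.0]), B=np.array([0.0, 0.0]), E=np.array([-1.0, 1.1]))
        with pytest.raises(ValueError, match="tan"):
            version_liaw(lm)


class TestLewinnek:
    def test_zero(self):
        m = LewinnekMeasures(short_ends=(np.zeros(2), np.zeros(2)),
                             long_ends=(np.zeros(2), np.array([50.0, 0.0])))
        assert version_lewinnek(m).value_deg == pytest.approx(0.0)

    def test_arcsin_half(self):
        m = LewinnekMeasures(short_ends=(np.zeros(2), np.array([0.0, 25.0])),
                             long_ends=(np.zeros(2), np.array([50.0, 0.0])))
        assert version_lewinnek(m).value_deg == pytest.approx(30.0)

    def test_d1_exceeding_d2_errors(self):
        m = LewinnekMeasures(short_ends=(np.zeros(2), np.array([0.0, 51.0])),
                             long_ends=(np.zeros(2), np.array([50.0, 0.0])))
        with pytest.raises(ValueError):
            version_lewinnek(m)


class TestWidmer:
    def test_printed_worked_value(self):
        # linear coefficients force 48.05 * 0.5 - 0.3 = 23.725 at S/TL = 0.5
        m = WidmerMeasures(short_ends=(np.zeros(2), np.array([10.0, 0.0])),
                           apex=np.array([-10.0, 0.0]))
        r = version_widmer(m)
        assert m.S / m.TL == pytest.approx(0.5)
        assert r.value_deg == pytest.approx(23.725, abs=1e-12)
        assert r.in_validity_range

    def test_out_of_range_flagged(self):
        m = WidmerMeasures(short_ends=(np.zeros(2), np.array([1.0, 0.0])),
                           apex=np.array([-9.0, 0.0]))
        r = version_widmer(m)
        assert m.S / m.TL == pytest.approx(0.1)
        assert not r.in_validity_range
        assert r.flags == "out_of_range"

    def test_arcsin_variant_disagrees_with_linear(self):
        m = WidmerMeasures(short_ends=(np.zeros(2), np.array([10.0, 0.0])),
                           apex=np.array([-10.0, 0.0]))
        assert version_widmer_arcsin(m).value_deg == pytest.approx(30.0)
        assert version_widmer(m).value_deg == pytest.approx(23.725)

    def test_s_not_below_tl_errors(self):
        m = WidmerMeasures.__new__(WidmerMeasures)
        object.__setattr__(m, "short_ends", (np.zeros(2), np.array([10.0, 0.0])))
        object.__setattr__(m, "apex", np.array([5.0, 0.0]))
        with pytest.raises(ValueError):
            version_widmer(m)

    def test_overestimates_truth_with_tl_convention(self, ap_beam):
        # positive bias across the clinical anteversion range
        for av in (12.0, 16.0, 20.0, 24.0, 28.0):
            pose = CupPose(av, 45.0, 25.0)
            e = project_rim(pose, ap_beam)
            sil = project_silhouette(pose, ap_beam, 200, head_radius_mm=14.0)
            r = version_widmer(extract_landmarks(e, sil, 14.0, "widmer"))
            assert r.value_deg > av


class TestHassan:
    def test_h_zero(self):
        m = HassanMeasures(long_ends=(np.zeros(2), np.array([50.0, 0.0])),
                           rim_point=np.array([30.0, 0.0]))
        assert version_hassan(m).value_deg == pytest.approx(0.0)

    def test_midpoint_chord(self):
        m = HassanMeasures(long_ends=(np.zeros(2), np.array([50.0, 0.0])),
                           rim_point=np.array([25.0, 12.5]))
        assert version_hassan(m).value_deg == pytest.approx(30.0)

    def test_inconsistent_landmarks_error(self):
        m = HassanMeasures(long_ends=(np.zeros(2), np.array([50.0, 0.0])),
                           rim_point=np.array([25.0, 30.0]))
        with pytest.raises(ValueError, match="arcsin"):
            version_hassan(m)

    def test_noise_free_pipeline_recovery(self, ap_beam):
        pose = CupPose(19.4, 45.0, 25.0)
        e = project_rim(pose, ap_beam)
        sil = project_silhouette(pose, ap_beam, 200, head_radius_mm=14.0)
        r = version_hassan(extract_landmarks(e, sil, 14.0, "hassan"))
        assert r.value_deg == pytest.approx(19.4, abs=1e-9)


class TestAckland:
    def test_y_zero(self):
        m = AcklandMeasures(A=np.zeros(2), C=np.array([50.0, 0.0]),
                            rim_point=np.array([20.0, 0.0]))
        assert version_ackland(m).value_deg == pytest.approx(0.0)

    def test_centre_tangent(self):
        m = AcklandMeasures(A=np.zeros(2), C=np.array([50.0, 0.0]),
                            rim_point=np.array([25.0, 12.5]))
        assert version_ackland(m).value_deg == pytest.approx(30.0)

    def test_chord_ratio_invariance(self):
        e = EllipseParams((0.0, 0.0), 25.0, 8.0, 0.0)
        v1 = compute_version(extract_landmarks(e, None, 1.0, "ackland", ackland_x_fraction=0.2))
        v2 = compute_version(extract_landmarks(e, None, 1.0, "ackland", ackland_x_fraction=0.8))
        assert v1.value_deg == pytest.approx(v2.value_deg, abs=1e-9)


class TestWooMorrey:
    def test_parallel_lines_read_zero(self):
        m = LateralMeasures(opening_line=(np.zeros(2), np.array([0.0, 10.0])),
                            reference_line=(np.array([5.0, 0.0]), np.array([5.0, 10.0])))
        assert version_woo_morrey(m).value_deg == pytest.approx(0.0)

    def test_retroversion_sign(self, lat_beam):
        lp = project_lateral(CupPose(3.0, 45.0, 25.0, tilt_deg=-25.0), lat_beam)
        r = version_woo_morrey(extract_lateral_landmarks(lp))
        assert r.value_deg < 0.0

    def test_overestimates_at_study_mean(self, lat_beam):
        lp = project_lateral(CupPose(19.4, 45.0, 25.0), lat_beam)
        r = version_woo_morrey(extract_lateral_landmarks(lp))
        assert r.value_deg > 19.4
        assert r.value_deg == pytest.approx(lp.angle_deg, abs=1e-9)

    def test_positive_bias_over_inclinations(self, lat_beam):
        for incl in (30.0, 37.0, 45.0, 50.0, 55.0):
            lp = project_lateral(CupPose(19.4, incl, 25.0), lat_beam)
            assert lp.angle_deg > 19.4


class TestAlgebraicEquivalence:
    @given(
        a=st.floats(20.0, 32.0),
        ratio=st.floats(0.1, 0.95),
    )
    @settings(max_examples=60, deadline=None)
    def test_four_ap_methods_identical(self, a, ratio):
        b = a * ratio
        lms = _ellipse_landmarks(a, b)
        vals = [compute_version(lms[m]).value_deg for m in ("liaw", "lewinnek", "hassan", "ackland")]
        expected = math.degrees(math.asin(ratio))
        for v in vals:
            assert v == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_true_anteversion(self, ap_beam, lat_beam):
        grids = {m: [] for m in ("liaw", "lewinnek", "widmer", "hassan", "ackland", "woo_morrey")}
        for av in np.linspace(5.5, 34.5, 15):
            pose = CupPose(float(av), 45.0, 25.0)
            e = project_rim(pose, ap_beam)
            sil = project_silhouette(pose, ap_beam, 200, head_radius_mm=14.0)
            for m in ("liaw", "lewinnek", "widmer", "hassan", "ackland"):
                grids[m].append(compute_version(extract_landmarks(e, sil, 14.0, m)).value_deg)
            grids["woo_morrey"].append(project_lateral(pose, lat_beam).angle_deg)
        for m, vals in grids.items():
            assert np.all(np.diff(vals) > 0), m
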