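import math

import numpy as np
import pytest

from cupversion.geometry import (
    BeamGeometry,
    CupPose,
    fit_ellipse_points,
    project_lateral,
    project_rim,
    project_silhouette,
    ray_trace_oracle,
)

from conftest import random_poses


class TestProjectRim:
    def test_anteversion_zero_degenerates_to_line(self, ap_beam):
        e = project_rim(CupPose(0.0, 45.0, 25.0), ap_beam)
        assert e.semi_minor_mm == pytest.approx(0.0, abs=1e-12)
        assert e.semi_major_mm == pytest.approx(25.0)

    def test_anteversion_ninety_is_circle(self, ap_beam):
        e = project_rim(CupPose(89.999999, 45.0, 25.0), ap_beam)
        assert e.semi_minor_mm / e.semi_major_mm == pytest.approx(1.0, abs=1e-6)

    def test_parallel_closed_form_ratio(self, ap_beam, pose_194):
        e = project_rim(pose_194, ap_beam)
        assert e.semi_major_mm == pytest.approx(25.0)
        assert e.semi_minor_mm == pytest.approx(25.0 * math.sin(math.radians(19.4)), abs=1e-12)

    @pytest.mark.parametrize("pose", random_poses(25, seed=3))
    def test_ratio_equals_sin_anteversion(self, pose, ap_beam):
        e = project_rim(pose, ap_beam)
        assert e.axis_ratio == pytest.approx(
            math.sin(math.radians(pose.anteversion_deg)), abs=1e-9
        )

    def test_orientation_matches_inclination(self, ap_beam):
        e = project_rim(CupPose(20.0, 40.0, 25.0, side="left"), ap_beam)
        assert e.orientation_deg == pytest.approx(40.0)
        e = project_rim(CupPose(20.0, 40.0, 25.0, side="right"), ap_beam)
        assert e.orientation_deg == pytest.approx(140.0)

    def test_rotation_equivariance(self, ap_beam):
        # rotating the pose about the beam axis rotates the ellipse by
        # the same angle and leaves the axis lengths unchanged
        e1 = project_rim(CupPose(22.0, 35.0, 26.0, side="left"), ap_beam)
        e2 = project_rim(CupPose(22.0, 47.0, 26.0, side="left"), ap_beam)
        assert (e2.orientation_deg - e1.orientation_deg) % 180.0 == pytest.approx(12.0)
        assert e2.semi_major_mm == pytest.approx(e1.semi_major_mm)
        assert e2.semi_minor_mm == pytest.approx(e1.semi_minor_mm)

    def test_side_symmetry_mirrors_x_only(self, ap_beam):
        pl = CupPose(20.0, 40.0, 25.0, centre_mm=(30.0, 10.0, 0.0), side="left")
        pr = CupPose(20.0, 40.0, 25.0, centre_mm=(-30.0, 10.0, 0.0), side="right")
        el, er = project_rim(pl, ap_beam), project_rim(pr, ap_beam)
        assert er.centre_film_mm[0] == pytest.approx(-el.centre_film_mm[0])
        assert er.centre_film_mm[1] == pytest.approx(el.centre_film_mm[1])
        assert er.semi_major_mm == pytest.approx(el.semi_major_mm)
        assert er.semi_minor_mm == pytest.approx(el.semi_minor_mm)
        assert er.orientation_deg == pytest.approx((180.0 - el.orientation_deg) % 180.0)

    def test_point_source_outside_cone_errors(self):
        beam = BeamGeometry(mode="point_source", film="ap")
        pose = CupPose(20.0, 45.0, 25.0, centre_mm=(400.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="cone"):
            project_rim(pose, beam)

    def test_wrong_film_errors(self, lat_beam, pose_194):
        with pytest.raises(ValueError):
            project_rim(pose_194, lat_beam)


class TestProjectSilhouette:
    def test_noise_free_rim_on_analytic_conic(self, ap_beam):
        pose = CupPose(30.0, 45.0, 25.0)
        e = project_rim(pose, ap_beam)
        sil = project_silhouette(pose, ap_beam, n_points=100)
        # implicit residual is dimensionless; 1e-9 mm-scale tolerance
        assert np.abs(e.implicit_residual(sil.rim_points)).max() < 1e-10

    def test_head_points_on_circle(self, ap_beam, pose_194):
        sil = project_silhouette(pose_194, ap_beam, head_radius_mm=14.0)
        d = np.linalg.norm(sil.head_points - np.asarray(pose_194.centre_mm[:2]), axis=1)
        assert np.allclose(d, 14.0, atol=1e-9)

    @pytest.mark.parametrize("pose", random_poses(10, seed=11))
    def test_dome_apex_at_radius_along_minor_axis(self, pose, ap_beam):
        e = project_rim(pose, ap_beam)
        sil = project_silhouette(pose, ap_beam)
        c = np.asarray(e.centre_film_mm)
        along = (sil.dome_points - c) @ e.minor_dir()
        apex = sil.dome_points[np.argmax(np.abs(along))]
        assert np.linalg.norm(apex - c) == pytest.approx(pose.radius_mm, abs=1e-9)
        # apex sits on the minor-axis line, up to the angular sampling step
        step = pose.radius_mm * math.pi / len(sil.dome_points)
        assert abs((apex - c) @ e.major_dir()) <= step

    def test_deterministic_for_seed(self, ap_beam, pose_194):
        s1 = project_silhouette(pose_194, ap_beam, rng_seed=5, noise_sd_mm=0.4)
        s2 = project_silhouette(pose_194, ap_beam, rng_seed=5, noise_sd_mm=0.4)
        assert np.array_equal(s1.rim_points, s2.rim_points)
        s3 = project_silhouette(pose_194, ap_beam, rng_seed=6, noise_sd_mm=0.4)
        assert not np.array_equal(s1.rim_points, s3.rim_points)

    def test_min_points(self, ap_beam, pose_194):
        with pytest.raises(ValueError):
            project_silhouette(pose_194, ap_beam, n_points=2)


class TestProjectLateral:
    def test_zero_anteversion_reads_zero(self, lat_beam):
        for incl in (30.0, 45.0, 55.0):
            lp = project_lateral(CupPose(1e-9, incl, 25.0), lat_beam)
            assert lp.angle_deg == pytest.approx(0.0, abs=1e-6)

    def test_overestimates_truth_at_study_mean(self, lat_beam):
        lp = project_lateral(CupPose(19.4, 45.0, 25.0), lat_beam)
        assert lp.angle_deg > 19.4

    def test_retroverted_reads_negative(self, lat_beam):
        lp = project_lateral(CupPose(5.0, 45.0, 25.0, tilt_deg=-30.0), lat_beam)
        assert lp.angle_deg < 0.0

    def test_side_invariance(self, lat_beam):
        r = project_lateral(CupPose(19.4, 45.0, 25.0, side="right"), lat_beam)
        l = project_lateral(CupPose(19.4, 45.0, 25.0, side="left"), lat_beam)
        assert r.angle_deg == pytest.approx(l.angle_deg, abs=1e-9)

    def test_degenerate_cephalad_angle_rejected(self):
        with pytest.raises(ValueError):
            BeamGeometry(film="crosstable_lateral", crosstable_cephalad_deg=0.0)
        with pytest.raises(ValueError):
            BeamGeometry(film="crosstable_lateral", crosstable_cephalad_deg=90.0)

    def test_wrong_film_errors(self, ap_beam, pose_194):
        with pytest.raises(ValueError):
            project_lateral(pose_194, ap_beam)


class TestRayTraceOracle:
    def test_axis_ratio_recovered(self, ap_beam):
        pose = CupPose(20.0, 45.0, 25.0)
        img = ray_trace_oracle(pose, ap_beam, pixel_mm=0.1)
        from cupversion.reference import measure_reference_from_image

        _, ell, _, _ = measure_reference_from_image(img)
        assert ell.axis_ratio == pytest.approx(math.sin(math.radians(20.0)), abs=0.005)

    def test_empty_pose_empty_image(self, ap_beam):
        img = ray_trace_oracle(None, ap_beam, pixel_mm=0.5)
        assert img.pixels.sum() == 0

    def test_parallel_vs_point_source_ratio(self):
        # at 1150 mm source-film distance magnification is near-uniform
        pose = CupPose(20.0, 45.0, 25.0)
        epar = project_rim(pose, BeamGeometry(film="ap"))
        eps = project_rim(pose, BeamGeometry(mode="point_source", film="ap"))
        assert abs(epar.axis_ratio - eps.axis_ratio) < 0.01

    def test_extent_too_small_errors(self, ap_beam, pose_194):
        with pytest.raises(ValueError, match="extent"):
            ray_trace_oracle(pose_194, ap_beam, 0.5, extent_mm=(-10, 10, -10, 10))

    def test_bad_pixel_size(self, ap_beam, pose_194):
        with pytest.raises(ValueError):
            ray_trace_oracle(pose_194, ap_beam, 0.0)


class TestBeamGeometry:
    def test_point_source_too_close_rejected(self):
        beam = BeamGeometry(mode="point_source", source_film_distance_mm=90.0)
        with pytest.raises(ValueError):
            beam.validate_for(CupPose(20.0, 45.0, 25.0))

    def test_fit_ellipse_roundtrip(self, ap_beam):
        e = project_rim(CupPose(24.0, 38.0, 27.0), ap_beam)
        refit = fit_ellipse_points(e.sample(50))
        assert refit.semi_major_mm == pytest.approx(e.semi_major_mm, abs=1e-6)
        assert refit.semi_minor_mm == pytest.approx(e.semi_minor_mm, abs=1e-6)
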