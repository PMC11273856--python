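"""Unit tests for Bennett scaling, fovea location, ROI thickness, circle fits
and directional curvature radii."""

import numpy as np
import pytest

from choromet.morphometry import (
    Calibration,
    FoveaLocation,
    bennett_scale,
    directional_radius,
    fit_circle_2d,
    locate_fovea,
    roi_mean_thickness,
)
from choromet.segmentation import SurfaceSet
from choromet.synthetic_data import EyeGeometryConfig, generate_eye


def flat_surfaces(nb=64, na=64, ilm=60.0, rpe=76.0, csi=92.0):
    ones = np.ones((nb, na))
    return SurfaceSet(ilm * ones, rpe * ones, csi * ones, ones.astype(bool))


@pytest.fixture()
def cal():
    # reduced-grid pitches, nominal eye (ratio 1)
    return Calibration(axial_um_per_px=4500 / 256, nominal_transverse_um_per_px=12000 / 64,
                       magnification_ratio=1.0)


class TestBennett:
    def test_known_values(self):
        assert bennett_scale(25.563) == pytest.approx(1.0489, abs=5e-5)
        assert bennett_scale(24.0) == pytest.approx(0.9798, abs=5e-5)

    def test_rejects_at_or_below_nodal_constant(self):
        with pytest.raises(ValueError):
            bennett_scale(1.82)

    def test_linearity_in_axial_length(self):
        base = bennett_scale(1.82 + 10.0)
        assert bennett_scale(1.82 + 20.0) == pytest.approx(2 * base)

    def test_calibration_scaling(self):
        c = Calibration(10.0, 20.0, 0.9)
        assert c.scaled_transverse_um_per_px == pytest.approx(18.0)


class TestLocateFovea:
    def test_exact_at_zero_noise_offset_pit(self):
        cfg = EyeGeometryConfig(fovea_position=(32, 30), undulation_um=0.0)
        truth = generate_eye(cfg, seed=0)
        fov = locate_fovea(truth.surfaces)
        assert (fov.bscan, fov.ascan) == (32, 30)

    def test_near_truth_at_default_noise(self, segmented_surfaces, eye_truth):
        fov = locate_fovea(segmented_surfaces)
        assert abs(fov.bscan - eye_truth.fovea[0]) <= 2
        assert abs(fov.ascan - eye_truth.fovea[1]) <= 2

    def test_flat_ilm_rejected(self):
        with pytest.raises(ValueError, match="no pit"):
            locate_fovea(flat_surfaces())


class TestRoiThickness:
    def test_uniform_choroid(self, cal):
        s = flat_surfaces(rpe=76.0, csi=76.0 + 280.0 / cal.axial_um_per_px)
        fov = FoveaLocation(32, 32, 60.0)
        for d in (1.0, 3.0):
            mean, n = roi_mean_thickness(s, cal, fov, d, "choroid")
            assert mean == pytest.approx(280.0, abs=cal.axial_um_per_px / 2)
            assert n > 0

    def test_linear_ramp_averages_to_fovea_value(self, cal):
        nb = na = 64
        ones = np.ones((nb, na))
        ramp = np.broadcast_to(np.arange(na) * 0.05, (nb, na))  # ramps along a
        s = SurfaceSet(60 * ones, 76 * ones, 76 + 10 + ramp, ones.astype(bool))
        fov = FoveaLocation(32, 32, 60.0)
        mean, _ = roi_mean_thickness(s, cal, fov, 3.0, "choroid")
        expected = (10 + ramp[32, 32]) * cal.axial_um_per_px
        assert mean == pytest.approx(expected, rel=1e-9)

    def test_quadratic_bowl_matches_brute_force(self, cal):
        nb = na = 64
        bb, aa = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
        bowl = 10 + 0.01 * ((bb - 32) ** 2 + (aa - 32) ** 2)
        ones = np.ones((nb, na))
        s = SurfaceSet(60 * ones, 76 * ones, 76 + bowl, ones.astype(bool))
        fov = FoveaLocation(32, 32, 60.0)
        mean, n = roi_mean_thickness(s, cal, fov, 3.0, "choroid")
        # independent brute-force average over the discrete ROI mask
        pitch = cal.scaled_transverse_um_per_px / 1000.0
        dist = np.sqrt(((bb - 32) * pitch) ** 2 + ((aa - 32) * pitch) ** 2)
        mask = dist < 1.5
        brute = np.mean(bowl[mask]) * cal.axial_um_per_px
        assert mean == pytest.approx(brute, abs=1e-9)
        assert n == int(mask.sum())

    def test_roi_count_shrinks_with_magnification_below_one(self):
        s = flat_surfaces(rpe=76.0, csi=92.0)
        fov = FoveaLocation(32, 32, 60.0)
        big = Calibration(17.58, 187.5, 1.0)
        small = Calibration(17.58, 187.5, 0.8)  # smaller eye: fewer px per mm...
        _, n_big = roi_mean_thickness(s, big, fov, 3.0, "choroid")
        _, n_small = roi_mean_thickness(s, small, fov, 3.0, "choroid")
        assert n_small > n_big  # ratio < 1 shrinks the px pitch, so more
        # A-scans fall inside a fixed physical diameter

    def test_empty_roi_rejected(self, cal):
        s = flat_surfaces()
        s.valid[:] = False
        with pytest.raises(ValueError):
            roi_mean_thickness(s, cal, FoveaLocation(32, 32, 60.0), 1.0, "choroid")


class TestCircleFit:
    def test_three_point_circle(self):
        center, r = fit_circle_2d(np.array([[0.0, 0.0], [2.0, 2.0], [4.0, 0.0]]))
        np.testing.assert_allclose(center, [2.0, 0.0], atol=1e-12)
        assert r == pytest.approx(2.0, abs=1e-12)

    def test_exact_points_on_radius_ten(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([3 + 10 * np.cos(t), -2 + 10 * np.sin(t)])
        _, r = fit_circle_2d(pts)
        assert r == pytest.approx(10.0, abs=1e-9)

    def test_noisy_arc_within_one_percent(self):
        """Monte-Carlo: arcs matching the curvature-fit use case (half-angle
        ~0.45 rad) with 10 um depth noise recover the radius within 1%."""
        r_gen = np.random.default_rng(5)
        radii = []
        t = np.linspace(-0.45, 0.45, 60)
        for _ in range(50):
            pts = np.column_stack(
                [10 * np.sin(t), 10 * (1 - np.cos(t)) + r_gen.normal(0, 0.01, t.size)]
            )
            radii.append(fit_circle_2d(pts)[1])
        assert np.mean(radii) == pytest.approx(10.0, rel=0.01)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError):
            fit_circle_2d(pts)


class TestDirectionalRadius:
    @pytest.fixture()
    def sphere_truth(self):
        cfg = EyeGeometryConfig(
            transverse_extent_mm=8.0, posterior_radius_mm=12.0, undulation_um=0.0
        )
        return cfg, generate_eye(cfg, seed=0)

    def test_sphere_cap_recovers_radius_all_angles(self, sphere_truth):
        cfg, truth = sphere_truth
        cal = Calibration(cfg.axial_pitch_mm * 1000, cfg.ascan_pitch_mm * 1000, 1.0)
        fov = FoveaLocation(*cfg.fovea_position, truth.surfaces.ilm_px[cfg.fovea_position])
        for angle in (0.0, 45.0, 90.0, 135.0):
            r = directional_radius(truth.surfaces, cal, fov, angle)
            assert r == pytest.approx(12.0, rel=0.01)

    def test_window_excludes_outliers(self, sphere_truth):
        """Corrupting the surface outside the inclusion window leaves the
        fitted radius unchanged."""
        cfg, truth = sphere_truth
        cal = Calibration(cfg.axial_pitch_mm * 1000, cfg.ascan_pitch_mm * 1000, 1.0)
        fov = FoveaLocation(*cfg.fovea_position, 0.0)
        r_before = directional_radius(truth.surfaces, cal, fov, 0.0)
        corrupted = SurfaceSet(
            truth.surfaces.ilm_px.copy(),
            truth.surfaces.midrpe_px.copy(),
            truth.surfaces.csi_px.copy(),
            truth.surfaces.valid.copy(),
        )
        # 0 degrees samples along a; the nasal (+a, left eye) window stops at
        # 3 mm = 24 px from the fovea on this 8 mm grid
        corrupted.midrpe_px[:, 58:] += 30.0
        corrupted.csi_px[:, 58:] += 30.0
        r_after = directional_radius(corrupted, cal, fov, 0.0)
        assert r_after == pytest.approx(r_before, rel=1e-9)

    def test_ellipsoid_matches_brute_force_fit(self):
        """On a non-spherical cap each directional radius equals an
        independent least-squares circle fit on the same sampled points."""
        from choromet.morphometry import _line_samples
        from scipy.optimize import least_squares

        nb = na = 64
        bb, aa = np.meshgrid(np.arange(nb, dtype=float), np.arange(na, dtype=float), indexing="ij")
        pitch_mm = 8.0 / 64
        ax_um = 4500 / 256
        x = (aa - 32) * pitch_mm
        y = (bb - 32) * pitch_mm
        z_mm = 1.3 + x**2 / (2 * 14.0) + y**2 / (2 * 20.0)  # paraboloid cap
        ones = np.ones((nb, na))
        s = SurfaceSet(z_mm * 1000 / ax_um - 20, z_mm * 1000 / ax_um, z_mm * 1000 / ax_um + 15,
                       ones.astype(bool))
        cal = Calibration(ax_um, pitch_mm * 1000, 1.0)
        fov = FoveaLocation(32, 32, 0.0)
        for angle in (0.0, 45.0, 90.0, 135.0):
            r = directional_radius(s, cal, fov, angle)
            pts = _line_samples(s, cal, fov, angle, "left")

            def resid(q):
                return np.hypot(pts[:, 0] - q[0], pts[:, 1] - q[1]) - q[2]

            brute = least_squares(resid, [0.0, 15.0, 15.0], xtol=1e-15, ftol=1e-15).x[2]
            assert r == pytest.approx(brute, abs=1e-6)

    def test_flat_surface_reports_infinite(self):
        s = flat_surfaces()
        cal = Calibration(17.58, 187.5, 1.0)
        r = directional_radius(s, cal, FoveaLocation(32, 32, 60.0), 90.0)
        assert np.isinf(r)

    def test_invalid_angle_rejected(self, cal):
        with pytest.raises(ValueError):
            directional_radius(flat_surfaces(), cal, FoveaLocation(32, 32, 60.0), 30.0)


class TestAsymmetricZeroWindow:
    def test_temporal_nasal_window_depends_on_orientation(self):
        """For the horizontal direction the nasal window is 3 mm and the
        temporal 5 mm; flipping eye orientation mirrors which side of the
        fovea is truncated."""
        from choromet.morphometry import _line_samples

        s = flat_surfaces()
        s.midrpe_px[:] += np.arange(64)[None, :] * 0.1  # break collinearity guard
        cal = Calibration(17.58, 187.5, 1.0)
        fov = FoveaLocation(32, 32, 60.0)
        left = _line_samples(s, cal, fov, 0.0, "left")
        right = _line_samples(s, cal, fov, 0.0, "right")
        # left eye: nasal = +a, so positive arc positions stop at 3 mm
        assert left[:, 0].max() < 3.0
        assert left[:, 0].min() > -5.0
        assert right[:, 0].max() < 5.0
        assert right[:, 0].min() > -3.0
        assert left[:, 0].max() < right[:, 0].max()
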