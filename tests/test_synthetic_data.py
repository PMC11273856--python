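"""Unit tests for the synthetic eye / RR-interval generators."""

import numpy as np
import pytest

from choromet.hrv import mean_hr, rmssd
from choromet.morphometry import fit_circle_2d
from choromet.synthetic_data import (
    EyeGeometryConfig,
    NoiseConfig,
    StressEffectConfig,
    apply_stress_effect,
    generate_eye,
    generate_rr_series,
    generate_stress_session_rr,
    render_volume,
)


class TestGenerateEye:
    def test_deterministic(self, eye_config):
        a = generate_eye(eye_config, seed=7)
        b = generate_eye(eye_config, seed=7)
        np.testing.assert_array_equal(a.surfaces.ilm_px, b.surfaces.ilm_px)
        np.testing.assert_array_equal(a.ct_map_um, b.ct_map_um)
        np.testing.assert_array_equal(a.vessel_map, b.vessel_map)

    def test_midrpe_lies_on_sphere_cap(self):
        """Cross-section of the mid-RPE through the fovea refits the
        configured posterior radius."""
        cfg = EyeGeometryConfig(
            transverse_extent_mm=8.0, posterior_radius_mm=12.0, undulation_um=0.0
        )
        truth = generate_eye(cfg, seed=0)
        b = cfg.fovea_position[0]
        z_mm = truth.surfaces.midrpe_px[b] * cfg.axial_pitch_mm
        x_mm = (np.arange(cfg.n_ascans) - cfg.fovea_position[1]) * cfg.ascan_pitch_mm
        _, radius = fit_circle_2d(np.column_stack([x_mm, z_mm]))
        assert radius == pytest.approx(12.0, rel=0.01)

    def test_uniform_choroid_thickness(self):
        cfg = EyeGeometryConfig(choroid_thickness_um=(280.0, 0.0), undulation_um=0.0)
        truth = generate_eye(cfg, seed=0)
        half_px_um = cfg.axial_pitch_mm * 1000 / 2
        assert np.all(np.abs(truth.ct_map_um - 280.0) <= half_px_um)

    def test_ct_map_consistent_with_surfaces(self, eye_truth, eye_config):
        recomputed = (
            eye_truth.surfaces.csi_px - eye_truth.surfaces.midrpe_px
        ) * eye_config.axial_pitch_mm * 1000
        assert np.max(np.abs(recomputed - eye_truth.ct_map_um)) <= (
            0.5 * eye_config.axial_pitch_mm * 1000
        )

    def test_pit_is_unique_ilm_depression_at_fovea(self, eye_config):
        """The foveal pit is the deepest detrended ILM point: locating it on
        the noise-free truth surfaces returns the configured fovea exactly."""
        from choromet.morphometry import locate_fovea

        truth = generate_eye(eye_config, seed=3)
        fov = locate_fovea(truth.surfaces)
        assert (fov.bscan, fov.ascan) == truth.fovea

    def test_rejects_oversized_pit(self):
        with pytest.raises(ValueError):
            EyeGeometryConfig(pit_radius_mm=7.0)

    def test_rejects_small_grid(self):
        with pytest.raises(ValueError):
            EyeGeometryConfig(n_bscans=4)


class TestRenderVolume:
    def test_deterministic(self, eye_truth):
        a = render_volume(eye_truth, NoiseConfig(seed=9))
        b = render_volume(eye_truth, NoiseConfig(seed=9))
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_noise_free_bands_match_reflectivities(self):
        """No attenuation, vanishing speckle: each column is piecewise
        constant at band reflectivity + background away from transitions."""
        cfg = EyeGeometryConfig(undulation_um=0.0, vessel_shadow=0.0)
        truth = generate_eye(cfg, seed=0)
        truth.texture_map = np.zeros_like(truth.texture_map)
        truth.disc_map = np.zeros_like(truth.disc_map)
        noise = NoiseConfig(speckle_shape=1e12, attenuation_coeff=0.0, background_level=0.02)
        vol = render_volume(truth, noise)
        b, a = cfg.fovea_position
        col = vol.intensities[b, :, a]
        s = truth.surfaces
        ilm, rpe, csi = s.ilm_px[b, a], s.midrpe_px[b, a], s.csi_px[b, a]
        assert col[int(ilm) - 10] == pytest.approx(0.05 + 0.02, abs=1e-3)  # vitreous
        assert col[int((ilm + rpe) / 2)] == pytest.approx(0.40 + 0.02, abs=1e-2)  # retina
        assert col[int((rpe + csi) / 2)] == pytest.approx(0.30 + 0.02, abs=1e-2)  # choroid
        assert col[int(csi) + 10] == pytest.approx(0.12 + 0.02, abs=1e-2)  # sclera

    def test_attenuation_dims_deeper_tissue(self):
        """Attenuation accrues with tissue depth: the same RPE band renders
        dimmer when a thicker retina puts it deeper below the ILM."""
        thin = EyeGeometryConfig(retina_thickness_um=(300.0, 0.0), undulation_um=0.0)
        thick = EyeGeometryConfig(retina_thickness_um=(420.0, 0.0), undulation_um=0.0)
        noise = NoiseConfig(speckle_shape=1e9, attenuation_coeff=1.0, seed=0)
        vals = []
        for cfg in (thin, thick):
            truth = generate_eye(cfg, seed=0)
            vol = render_volume(truth, noise)
            b, a = cfg.fovea_position
            rpe = int(round(truth.surfaces.midrpe_px[b, a]))
            vals.append(vol.intensities[b, rpe, a])
        assert vals[1] < vals[0]

    def test_rejects_out_of_range_surfaces(self, eye_truth):
        bad = apply_stress_effect(
            eye_truth, StressEffectConfig(delta_ct_um=0.0, rigid_shift_px=(-3.0, 0.0, 0.0))
        )
        bad.surfaces.ilm_px[:] = -1.0
        with pytest.raises(ValueError):
            render_volume(bad)


class TestStressEffect:
    def test_identity_leaves_surfaces_unchanged(self, eye_truth):
        out = apply_stress_effect(eye_truth, StressEffectConfig(delta_ct_um=0.0))
        np.testing.assert_allclose(out.surfaces.ilm_px, eye_truth.surfaces.ilm_px)
        np.testing.assert_allclose(out.surfaces.csi_px, eye_truth.surfaces.csi_px)

    def test_choroidal_thickening_magnitude(self, eye_truth, eye_config):
        out = apply_stress_effect(eye_truth, StressEffectConfig(delta_ct_um=3.3))
        delta = np.mean(out.ct_map_um - eye_truth.ct_map_um)
        assert delta == pytest.approx(3.3, abs=0.5 * eye_config.axial_pitch_mm * 1000)
        np.testing.assert_allclose(out.surfaces.ilm_px, eye_truth.surfaces.ilm_px)

    def test_pure_translation_shifts_indices(self, eye_truth):
        out = apply_stress_effect(
            eye_truth, StressEffectConfig(delta_ct_um=0.0, rigid_shift_px=(0.0, 2.0, 0.0))
        )
        np.testing.assert_allclose(
            out.surfaces.ilm_px[2:], eye_truth.surfaces.ilm_px[:-2], atol=1e-9
        )

    def test_rejects_excessive_rotation(self):
        with pytest.raises(ValueError):
            StressEffectConfig(rigid_rot_deg=5.0)

    def test_rejects_csi_leaving_grid(self, eye_truth):
        with pytest.raises(ValueError):
            apply_stress_effect(eye_truth, StressEffectConfig(delta_ct_um=50000.0))


class TestRRSeries:
    def test_zero_sd_degenerates_to_constant(self):
        s = generate_rr_series(800.0, 0.0, 50, seed=0)
        np.testing.assert_array_equal(s.rr_ms, 800.0)
        assert rmssd(s.rr_ms) == 0.0

    def test_deterministic(self):
        a = generate_rr_series(779.0, 34.0, 100, seed=4)
        b = generate_rr_series(779.0, 34.0, 100, seed=4)
        np.testing.assert_array_equal(a.rr_ms, b.rr_ms)

    def test_stationary_moments(self):
        s = generate_rr_series(779.0, 34.0, 20000, seed=1)
        assert np.mean(s.rr_ms) == pytest.approx(779.0, abs=2.0)
        assert np.std(s.rr_ms) == pytest.approx(34.0, rel=0.05)

    def test_autocorrelation_keeps_rmssd_below_sdrr(self):
        """At the default AR coefficient (0.7), RMSSD = sd*sqrt(2*0.3) < SDRR."""
        s = generate_rr_series(779.0, 34.0, 5000, seed=2)
        assert rmssd(s.rr_ms) < np.std(s.rr_ms, ddof=1)
        assert rmssd(s.rr_ms) == pytest.approx(34.0 * np.sqrt(0.6), rel=0.05)

    def test_mean_hr_difference_between_conditions(self):
        """779 ms vs 692 ms mean RR corresponds to a ~9.7 bpm HR rise."""
        base = generate_rr_series(779.0, 0.0, 100, seed=0)
        stress = generate_rr_series(692.0, 0.0, 100, seed=0)
        diff = mean_hr(stress.rr_ms) - mean_hr(base.rr_ms)
        assert diff == pytest.approx(60000 / 692 - 60000 / 779, abs=1e-9)
        assert diff == pytest.approx(9.7, abs=0.1)

    def test_rejects_events_beyond_duration(self):
        with pytest.raises(ValueError):
            generate_rr_series(800.0, 10.0, 10, events={"end": 1e9}, seed=0)

    def test_rejects_nonpositive_interval_risk(self):
        with pytest.raises(ValueError):
            generate_rr_series(100.0, 40.0, 10, seed=0)

    def test_stress_session_has_two_events(self):
        s = generate_stress_session_rr(seed=0)
        assert set(s.events) == {"baseline_end", "stress_end"}
        assert s.events["baseline_end"] < s.events["stress_end"] <= s.duration_ms
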