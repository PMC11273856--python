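"""Unit tests for boundary segmentation, layer masks and the Dice metric."""

import numpy as np
import pytest

from choromet.segmentation import (
    SurfaceSet,
    dice,
    layer_masks,
    load_surfaces_tsv,
    save_surfaces_tsv,
    segment_bscan,
    segment_volume,
)
from choromet.enhancement import enhance_bscan, enhance_volume
from choromet.synthetic_data import EyeGeometryConfig, NoiseConfig, generate_eye, render_volume


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = True
        b[4, 4] = True
        assert dice(a, b) == 0.0

    def test_shifted_block_overlap(self):
        a = np.zeros((4, 5), bool)
        b = np.zeros((4, 5), bool)
        a[1:3, 1:3] = True
        b[1:3, 2:4] = True  # overlap: 2 of 4 pixels each
        assert dice(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        assert dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestSegmentBscan:
    def test_noise_free_boundaries_within_one_pixel(self):
        """On a clean phantom (no speckle, no vessel shadows or disc) every
        boundary is localized within one pixel at every A-scan."""
        cfg = EyeGeometryConfig(undulation_um=0.0, vessel_shadow=0.0)
        truth = generate_eye(cfg, seed=1)
        truth.disc_map = np.zeros_like(truth.disc_map)
        vol = render_volume(truth, NoiseConfig(speckle_shape=1e9, attenuation_coeff=0.5))
        b = vol.n_bscans // 2
        img = enhance_bscan(vol.intensities[b])
        ilm, rpe, csi, valid = segment_bscan(img, vol.axial_mm_per_px * 1000)
        assert valid.all()
        s = truth.surfaces
        assert np.max(np.abs(ilm - s.ilm_px[b])) <= 1.0
        assert np.max(np.abs(rpe - s.midrpe_px[b])) <= 1.0
        assert np.max(np.abs(csi - s.csi_px[b])) <= 1.0

    def test_all_zero_image_flagged_invalid(self):
        ilm, rpe, csi, valid = segment_bscan(np.zeros((64, 16)), 17.58)
        assert not valid.any()

    def test_ordering_enforced(self, enhanced_volume):
        b = enhanced_volume.n_bscans // 2
        axial_um = enhanced_volume.axial_mm_per_px * 1000
        ilm, rpe, csi, _ = segment_bscan(enhanced_volume.intensities[b], axial_um)
        assert np.all(ilm <= rpe + 1e-9)
        assert np.all(rpe <= csi + 1e-9)


class TestSegmentVolume:
    def test_deterministic(self, enhanced_volume):
        a = segment_volume(enhanced_volume)
        b = segment_volume(enhanced_volume)
        np.testing.assert_array_equal(a.ilm_px, b.ilm_px)
        np.testing.assert_array_equal(a.csi_px, b.csi_px)

    def test_default_noise_dice_floor(self, eye_truth, segmented_surfaces, eye_config):
        """Retina and choroid Dice vs generator truth clear 0.95 on one
        default-noise volume (the 10-volume average runs with acceptance)."""
        rt_t, ct_t = layer_masks(eye_truth.surfaces, eye_config.depth_px)
        rt_m, ct_m = layer_masks(segmented_surfaces, eye_config.depth_px)
        assert dice(rt_t, rt_m) >= 0.95
        assert dice(ct_t, ct_m) >= 0.95

    def test_corrupted_bscan_interpolated_and_flagged(self, eye_volume):
        vol = eye_volume.with_intensities(eye_volume.intensities.copy())
        vol.intensities[10] = 0.0
        surf = segment_volume(enhance_volume(vol))
        assert 10 in surf.meta["interpolated_bscans"]
        assert surf.valid[10].all()
        # interpolated surfaces bridge the neighbors
        assert np.all(surf.ilm_px[10] <= np.maximum(surf.ilm_px[9], surf.ilm_px[11]) + 1e-9)
        assert not surf.meta["poor_quality"]

    def test_mostly_featureless_volume_flagged_poor(self):
        cfg = EyeGeometryConfig(n_bscans=8, n_ascans=16, depth_px=64)
        vol_arr = np.zeros((8, 64, 16))
        from choromet.volume import OCTVolume

        vol = OCTVolume(vol_arr, 12.0 / 16, 4.5 / 64)
        surf = segment_volume(vol)
        assert surf.meta["poor_quality"]


class TestSurfaceSet:
    def test_ordering_invariant_enforced(self):
        ones = np.ones((4, 4))
        with pytest.raises(ValueError):
            SurfaceSet(60 * ones, 50 * ones, 90 * ones, ones.astype(bool))

    def test_thickness_helpers(self):
        ones = np.ones((4, 4))
        s = SurfaceSet(60 * ones, 76 * ones, 92 * ones, ones.astype(bool))
        np.testing.assert_allclose(s.retina_thickness_px(), 16.0)
        np.testing.assert_allclose(s.choroid_thickness_px(), 16.0)

    def test_tsv_round_trip(self, tmp_path, segmented_surfaces):
        path = tmp_path / "surfaces.tsv"
        save_surfaces_tsv(segmented_surfaces, path)
        loaded = load_surfaces_tsv(path)
        np.testing.assert_allclose(loaded.ilm_px, segmented_surfaces.ilm_px)
        np.testing.assert_allclose(loaded.csi_px, segmented_surfaces.csi_px)
        np.testing.assert_array_equal(loaded.valid, segmented_surfaces.valid)

    def test_layer_masks_disjoint_and_consistent(self, segmented_surfaces, eye_config):
        retina, choroid = layer_masks(segmented_surfaces, eye_config.depth_px)
        assert not np.any(retina & choroid)
        # mask column heights equal the rounded boundary gaps
        nb, na = segmented_surfaces.shape
        b, a = nb // 2, na // 2
        col = retina[b, :, a]
        expected = np.ceil(segmented_surfaces.midrpe_px[b, a]) - np.ceil(
            segmented_surfaces.ilm_px[b, a]
        )
        assert col.sum() == expected
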