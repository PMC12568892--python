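"""Segmentation backends: thresholds, morphology, truth transport, merge."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from ctbodycomp import phantom as ph
from ctbodycomp.landmarks import LandmarkSet
from ctbodycomp.normalize import resample_standard
from ctbodycomp.segmentation import (AortaPrerequisiteError,
                                     UnsupportedTargetError, segment,
                                     threshold_calcium_backend,
                                     threshold_fat_backend,
                                     trabecular_roi_backend, truth_backend)
from conftest import small_spec, volume_from_array


def dice(a, b):
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * np.logical_and(a, b).sum() / denom


class TestDispatch:
    def test_truth_backend_reproduces_phantom_masks(self, noise_free_phantom,
                                                    noise_free_volume):
        _spec, _hu, truth = noise_free_phantom
        lm = segment(noise_free_volume, "truth",
                     ("vat", "sat", "muscle", "liver"), truth=truth)
        for name in ("vat", "sat", "muscle", "liver"):
            assert np.array_equal(lm.mask(name), truth.masks[name]), name

    def test_empty_targets_empty_map(self, noise_free_volume):
        lm = segment(noise_free_volume, "threshold", ())
        assert lm.labels.max() == 0
        assert lm.present_labels() == []

    def test_overlap_resolved_by_precedence_and_logged(self, noise_free_phantom,
                                                       noise_free_volume):
        # the full-vessel aorta mask overlaps plaque; plaque must win
        _spec, _hu, truth = noise_free_phantom
        lm = segment(noise_free_volume, "truth", ("aorta", "plaque"),
                     truth=truth)
        assert np.array_equal(lm.mask("plaque"), truth.masks["plaque"])
        assert not np.any(lm.mask("aorta") & truth.masks["plaque"])
        assert any("precedence" in w for w in lm.warnings)

    def test_unknown_backend_lists_registered(self, noise_free_volume):
        with pytest.raises(KeyError, match="threshold"):
            segment(noise_free_volume, "nope", ("vat",))

    def test_unknown_target_rejected(self, noise_free_volume):
        with pytest.raises(UnsupportedTargetError, match="valid"):
            segment(noise_free_volume, "threshold", ("gallbladder",))

    def test_threshold_backend_has_no_organ_model(self, noise_free_volume):
        with pytest.raises(UnsupportedTargetError, match="liver"):
            segment(noise_free_volume, "threshold", ("liver",))


class TestFatMuscle:
    def test_dice_against_truth_on_noise_free_phantom(self, noise_free_phantom,
                                                      noise_free_volume):
        _spec, _hu, truth = noise_free_phantom
        vat, sat, muscle, warn = threshold_fat_backend(noise_free_volume)
        assert dice(vat, truth.masks["vat"]) >= 0.95
        assert dice(sat, truth.masks["sat"]) >= 0.95
        assert dice(muscle, truth.masks["muscle"]) >= 0.95
        assert warn == []

    def test_vat_sat_partition_of_fat_range(self, noise_free_volume):
        raw = noise_free_volume.raw_hu()
        vat, sat, muscle, _ = threshold_fat_backend(noise_free_volume)
        assert not np.any(vat & sat)
        fat = (raw >= -190) & (raw <= -30)
        # VAT u SAT covers the fat range except voxels absorbed into muscle
        assert np.array_equal(vat | sat, fat & ~muscle & (vat | sat | fat))

    def test_no_fat_voxels_gives_empty_masks(self):
        hu = np.full((4, 20, 20), 50.0)
        vat, sat, _m, _w = threshold_fat_backend(volume_from_array(hu))
        assert vat.sum() == 0 and sat.sum() == 0

    def test_open_abdominal_wall_flags_slice_and_defaults_to_sat(self):
        spec = small_spec(noise_sd=0.0)
        hu, truth = ph.build_phantom(spec)
        # carve a wide anterior gap through the muscle ring on one slice
        s = 12
        gap = truth.masks["muscle"][s] & (np.arange(64)[None, :] >= 28) \
            & (np.arange(64)[None, :] < 36) & (np.arange(64)[:, None] < 32)
        hu[s][gap] = -100.0
        vol = volume_from_array(hu, spacing=(2.5, 2.5, 3.0))
        vat, sat, _m, warn = threshold_fat_backend(vol)
        assert any(f"slice {s}" in w for w in warn)
        assert vat[s].sum() == 0
        assert sat[s].sum() > 0


class TestCalcium:
    def test_exactly_plaque_voxels_on_phantom(self, noise_free_phantom,
                                              noise_free_volume):
        _spec, _hu, truth = noise_free_phantom
        mask, _comp, n = threshold_calcium_backend(noise_free_volume,
                                                   truth.masks["aorta"])
        assert np.array_equal(mask, truth.masks["plaque"])
        assert n == 2

    def test_blood_pool_not_detected(self):
        hu = np.full((4, 10, 10), 40.0)
        aorta = np.ones_like(hu, dtype=bool)
        mask, _c, n = threshold_calcium_backend(volume_from_array(hu), aorta)
        assert mask.sum() == 0 and n == 0

    def test_diagonal_touch_is_one_26_connected_component(self):
        hu = np.full((2, 4, 4), 0.0)
        hu[0, 0, 0] = 400.0
        hu[1, 1, 1] = 400.0   # touches only diagonally in 3-D
        aorta = np.ones_like(hu, dtype=bool)
        _m, _c, n = threshold_calcium_backend(volume_from_array(hu), aorta)
        assert n == 1

    def test_missing_aorta_prerequisite(self, noise_free_volume):
        with pytest.raises(AortaPrerequisiteError, match="aorta"):
            threshold_calcium_backend(noise_free_volume, None)

    def test_plaque_within_dilated_aorta_and_above_threshold(
            self, noise_free_phantom, noise_free_volume):
        _spec, _hu, truth = noise_free_phantom
        mask, _c, _n = threshold_calcium_backend(noise_free_volume,
                                                 truth.masks["aorta"])
        dilated = ndimage.binary_dilation(truth.masks["aorta"],
                                          structure=np.ones((3, 3, 3)))
        assert not np.any(mask & ~dilated)
        assert (noise_free_volume.raw_hu()[mask] >= 130).all()


class TestTrabecularRoi:
    def test_roi_median_near_trabecular_hu(self, phantom_volume,
                                           phantom_landmarks):
        roi, warn = trabecular_roi_backend(phantom_volume, phantom_landmarks,
                                           "L1")
        vals = phantom_volume.raw_hu()[roi]
        assert vals.size > 0 and warn == []
        assert abs(np.median(vals) - 150.0) <= 5.0

    def test_roi_excludes_cortical_shell(self, phantom_volume,
                                         phantom_landmarks):
        roi, _w = trabecular_roi_backend(phantom_volume, phantom_landmarks,
                                         "L1")
        assert (phantom_volume.raw_hu()[roi] < 400).all()

    def test_absent_level_raises(self, phantom_volume):
        with pytest.raises(KeyError, match="L3"):
            trabecular_roi_backend(phantom_volume, LandmarkSet(), "L3")

    def test_no_bone_at_slice_warns_empty(self):
        hu = np.full((4, 20, 20), -100.0)
        vol = volume_from_array(hu)
        roi, warn = trabecular_roi_backend(
            vol, LandmarkSet(positions={"L1": 2}), "L1")
        assert roi.sum() == 0 and len(warn) == 1


class TestTruthTransport:
    def test_identity_transport_unchanged(self, noise_free_phantom,
                                          noise_free_volume):
        _spec, _hu, truth = noise_free_phantom
        out = truth_backend(noise_free_volume, truth, ["liver", "vat"])
        assert np.array_equal(out["liver"], truth.masks["liver"])

    def test_resampled_transport_bounded_volume_change(self):
        spec = replace(small_spec(seed=2, noise_sd=0.0),
                       grid_shape=(64, 64, 48),
                       voxel_spacing_mm=(2.5, 2.5, 1.5),
                       vertebra_defs=tuple(
                           ph.VertebraDef(level=l, center_slice=8 + 12 * k,
                                          body_radius_mm=12.0)
                           for k, l in enumerate(("L3", "L4", "L5"))),
                       aorta=ph.AortaDef(center_xy_mm=(-5.0, 4.0),
                                         radius_mm=7.0, slice_range=(4, 40)),
                       hiatus_slice=4, bifurcation_slice=40)
        hu, truth = ph.build_phantom(spec)
        z = spec.z_positions_mm
        out, z_out = resample_standard(hu, z)
        vol = volume_from_array(out, spacing=(2.5, 2.5, 3.0))
        vol.provenance["z_positions_mm"] = [float(v) for v in z_out]
        got = truth_backend(vol, truth, ["liver", "muscle", "sat", "vat"])
        for name, m in got.items():
            v_in = truth.masks[name].sum() * (2.5 * 2.5 * 1.5) / 1000.0
            v_out = m.sum() * (2.5 * 2.5 * 3.0) / 1000.0
            assert abs(v_out - v_in) / v_in <= 0.05, name

    def test_reoriented_phantom_alignment_preserved(self, tmp_path):
        # write feet-first, normalize (which flips back), transport truth:
        # per-class Dice vs the native masks must be exactly 1
        from ctbodycomp.normalize import normalize_acquisition
        spec = small_spec(seed=3, noise_sd=0.0)
        hu, truth = ph.build_phantom(spec)
        plan = ph.AcquisitionPlan(series=[ph.SeriesPlan(patient_position="FFS")])
        files = ph.write_dicom_series(hu, spec, plan, str(tmp_path))
        vol = normalize_acquisition(files)
        got = truth_backend(vol, truth, ["liver", "muscle", "plaque"])
        for name, m in got.items():
            assert dice(m, truth.masks[name]) == 1.0, name

    def test_shape_mismatch_rejected(self, noise_free_phantom):
        _spec, hu, truth = noise_free_phantom
        small = volume_from_array(hu[:, :64, :64], spacing=(2.5, 2.5, 3.0))
        with pytest.raises(ValueError, match="shape"):
            truth_backend(small, truth, ["liver"])


class TestBackendAgreement:
    def test_backend_swap_bounds_biomarker_drift(self, noise_free_phantom,
                                                 noise_free_volume):
        """Truth vs threshold backends agree on the noise-free phantom:
        tissue volumes within 5%, Agatston exactly equal."""
        _spec, _hu, truth = noise_free_phantom
        from ctbodycomp.biomarkers import agatston_score
        vat, sat, muscle, _w = threshold_fat_backend(noise_free_volume)
        for name, m in (("vat", vat), ("sat", sat), ("muscle", muscle)):
            v_t = truth.masks[name].sum()
            assert abs(int(m.sum()) - int(v_t)) / v_t <= 0.05, name
        plaque, _c, _n = threshold_calcium_backend(noise_free_volume,
                                                   truth.masks["aorta"])
        s_thr, _ = agatston_score(plaque, noise_free_volume)
        s_tru, _ = agatston_score(truth.masks["plaque"], noise_free_volume)
        assert s_thr == s_tru
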