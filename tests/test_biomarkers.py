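"""Biomarker engine: Agatston weighting, areas, volumes, HU statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctbodycomp import phantom as ph
from ctbodycomp.biomarkers import (abdominal_and_total_agatston,
                                   agatston_score, cross_sectional_area,
                                   density_factor, hu_stats, measure_study,
                                   volume_ml, vsr)
from ctbodycomp.landmarks import LandmarkSet
from ctbodycomp.segmentation import LABEL_IDS, LabelMap, segment
from conftest import random_plaques, small_spec, volume_from_array


class TestDensityFactor:
    @pytest.mark.parametrize("peak,factor", [
        (0, 0), (129, 0), (129.9, 0),
        (130, 1), (150, 1), (199, 1), (199.5, 1),
        (200, 2), (250, 2), (299, 2),
        (300, 3), (399, 3),
        (400, 4), (1000, 4), (10000, 4),
    ])
    def test_printed_bins(self, peak, factor):
        assert density_factor(peak) == factor

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            density_factor(float("nan"))

    def test_monotone_non_decreasing(self):
        vals = [density_factor(h) for h in range(0, 1000)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))


def _label_map(mask, name="plaque"):
    labels = np.zeros(mask.shape, dtype=np.int16)
    labels[mask] = LABEL_IDS[name]
    return LabelMap(labels=labels,
                    dictionary={0: "background", LABEL_IDS[name]: name},
                    backend_id="test")


class TestAgatston:
    def test_empty_plaque_map_scores_zero(self):
        vol = volume_from_array(np.zeros((4, 8, 8)))
        score, stats = agatston_score(np.zeros((4, 8, 8), bool), vol)
        assert score == 0.0 and stats == []

    def test_single_slice_area_times_factor(self):
        # 20 voxels of 1 mm^2 at 420 HU on one slice: 20 x 4 = 80
        hu = np.zeros((3, 10, 10))
        mask = np.zeros((3, 10, 10), bool)
        mask[1, 2:4, 0:10] = True
        hu[mask] = 420.0
        vol = volume_from_array(hu, spacing=(1.0, 1.0, 3.0))
        score, stats = agatston_score(mask, vol)
        assert score == 80.0
        assert stats[0].area_mm2 == 20.0 and stats[0].density_factor == 4

    def test_per_slice_peak_governs_whole_slice_area(self):
        # two lesions on one slice: 300 HU peak weights both areas
        hu = np.zeros((1, 10, 10))
        mask = np.zeros((1, 10, 10), bool)
        mask[0, 1, 1:4] = True   # 3 px at 150
        mask[0, 5, 5:7] = True   # 2 px at 300
        hu[0, 1, 1:4] = 150.0
        hu[0, 5, 5:7] = 300.0
        vol = volume_from_array(hu, spacing=(1.0, 1.0, 3.0))
        score, stats = agatston_score(mask, vol)
        assert score == 5 * 3  # 5 mm^2, factor 3
        assert stats[0].peak_hu == 300.0

    def test_matches_voxel_loop_oracle_on_random_phantoms(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            spec = small_spec(seed=trial, noise_sd=0.0)
            spec_p = small_spec(seed=trial, noise_sd=0.0,
                                plaques=random_plaques(spec, rng,
                                                       int(rng.integers(1, 5))))
            hu, truth = ph.build_phantom(spec_p)
            vol = volume_from_array(hu, spacing=(2.5, 2.5, 3.0))
            score, _ = agatston_score(truth.masks["plaque"], vol)
            oracle = ph.agatston_voxel_loop(hu, truth.masks["plaque"], 6.25)
            assert score == oracle

    def test_shape_mismatch_rejected(self):
        vol = volume_from_array(np.zeros((4, 8, 8)))
        with pytest.raises(ValueError, match="shape"):
            agatston_score(np.zeros((4, 6, 6), bool), vol)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_in_plaque_voxels(self, seed):
        """Adding plaque voxels never decreases the score."""
        rng = np.random.default_rng(seed)
        hu = rng.uniform(0, 800, size=(3, 6, 6))
        vol = volume_from_array(hu, spacing=(1.0, 1.0, 3.0))
        base = rng.random(size=hu.shape) < 0.3
        grown = base | (rng.random(size=hu.shape) < 0.2)
        s_base, _ = agatston_score(base, vol)
        s_grown, _ = agatston_score(grown, vol)
        assert s_grown >= s_base


class TestCompartments:
    def _setup(self, plaque_slices, peak=420.0):
        hu = np.zeros((20, 8, 8))
        plaque = np.zeros((20, 8, 8), bool)
        aorta = np.zeros((20, 8, 8), bool)
        aorta[2:18, 3:5, 3:5] = True
        for s in plaque_slices:
            plaque[s, 3, 3] = True
            hu[s, 3, 3] = peak
        vol = volume_from_array(hu, spacing=(1.0, 1.0, 3.0))
        ls = LandmarkSet(positions={"aortic_hiatus": 6,
                                    "aortic_bifurcation": 14})
        return hu, plaque, aorta, vol, ls

    def test_plaque_inside_compartment_makes_scores_equal(self):
        _hu, plaque, aorta, vol, ls = self._setup([8, 10])
        abd, tot, flags = abdominal_and_total_agatston(plaque, vol, ls, aorta)
        assert abd == tot > 0 and flags == []

    def test_cranial_plaque_counts_only_toward_total(self):
        _hu, plaque, aorta, vol, ls = self._setup([3])
        abd, tot, _ = abdominal_and_total_agatston(plaque, vol, ls, aorta)
        assert abd == 0.0 and tot > 0

    def test_straddling_plaques_match_oracle_per_compartment(self):
        spec = small_spec(seed=0, noise_sd=0.0, plaques=())
        rng = np.random.default_rng(7)
        spec = small_spec(seed=0, noise_sd=0.0,
                          plaques=random_plaques(spec, rng, 4))
        hu, truth = ph.build_phantom(spec)
        vol = volume_from_array(hu, spacing=(2.5, 2.5, 3.0))
        ls = LandmarkSet(positions={k: v for k, v in truth.landmarks.items()})
        abd, tot, _ = abdominal_and_total_agatston(
            truth.masks["plaque"], vol, ls, truth.masks["aorta"])
        assert abd == truth.expected["abdominal_agatston"].value
        assert tot == truth.expected["total_agatston"].value

    def test_missing_landmarks_abdominal_absent_with_flag(self):
        _hu, plaque, aorta, vol, _ls = self._setup([8])
        abd, tot, flags = abdominal_and_total_agatston(
            plaque, vol, LandmarkSet(), aorta)
        assert abd is None and tot > 0 and "partial_anatomy" in flags

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_abdominal_never_exceeds_total(self, seed):
        rng = np.random.default_rng(seed)
        hu = rng.uniform(0, 600, size=(12, 6, 6))
        plaque = rng.random(size=hu.shape) < 0.2
        aorta = np.ones_like(plaque)
        vol = volume_from_array(hu, spacing=(1.0, 1.0, 3.0))
        lo, hi = sorted(rng.integers(0, 12, size=2).tolist())
        ls = LandmarkSet(positions={"aortic_hiatus": int(lo),
                                    "aortic_bifurcation": int(hi + 1)})
        abd, tot, _ = abdominal_and_total_agatston(plaque, vol, ls, aorta)
        assert abd <= tot


class TestGeometryMeasures:
    def test_area_arithmetic(self):
        mask = np.zeros((2, 20, 20), bool)
        mask[1, :20, :20] = True
        lm = _label_map(mask, "muscle")
        vol = volume_from_array(np.zeros((2, 20, 20)), spacing=(0.5, 0.5, 3.0))
        assert cross_sectional_area(lm, "muscle", 1, vol) == 1.0
        assert cross_sectional_area(lm, "muscle", 0, vol) == 0.0

    def test_area_slice_out_of_range(self):
        lm = _label_map(np.zeros((2, 4, 4), bool))
        vol = volume_from_array(np.zeros((2, 4, 4)))
        with pytest.raises(IndexError):
            cross_sectional_area(lm, "plaque", 5, vol)

    def test_volume_arithmetic_and_linearity(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.flat[:1000] = True
        lm = _label_map(mask, "liver")
        vol = volume_from_array(np.zeros((10, 10, 10)), spacing=(1.0, 1.0, 3.0))
        assert volume_ml(lm, "liver", vol) == 3.0
        half = mask.copy()
        half.flat[:500] = False
        assert volume_ml(_label_map(half, "liver"), "liver", vol) == 1.5

    def test_unknown_label_rejected(self):
        lm = _label_map(np.zeros((2, 4, 4), bool), "liver")
        vol = volume_from_array(np.zeros((2, 4, 4)))
        with pytest.raises(KeyError, match="spleen"):
            volume_ml(lm, "spleen", vol)

    def test_phantom_liver_within_five_percent_of_analytic(self,
                                                           default_phantom,
                                                           phantom_volume,
                                                           phantom_landmarks):
        spec, _hu, truth = default_phantom
        lm = segment(phantom_volume, "truth",
                     ("liver", "vat", "sat", "muscle"), truth=truth)
        got = volume_ml(lm, "liver", phantom_volume)
        od = next(o for o in spec.organ_defs if o.name == "liver")
        analytic = 4 / 3 * np.pi * np.prod(od.radii_mm) / 1000.0
        assert abs(got - analytic) / analytic <= 0.05

    def test_phantom_fat_ring_area_at_l3(self, default_phantom, phantom_volume,
                                         phantom_landmarks):
        spec, _hu, truth = default_phantom
        lm = segment(phantom_volume, "truth", ("sat",), truth=truth)
        s = phantom_landmarks.get("L3")
        got = cross_sectional_area(lm, "sat", s, phantom_volume)
        a, b = spec.body_ellipse_mm
        t = spec.fat_ring_thickness_mm
        analytic = (np.pi * a * b - np.pi * (a - t) * (b - t)) / 100.0
        assert abs(got - analytic) / analytic <= 0.05


class TestHuStats:
    def test_constant_region(self):
        hu = np.full((2, 4, 4), 55.0)
        vol = volume_from_array(hu)
        mean, med, sd = hu_stats(vol, np.ones_like(hu, bool))
        assert (mean, med, sd) == (55.0, 55.0, 0.0)

    def test_single_voxel(self):
        hu = np.zeros((2, 4, 4))
        hu[1, 2, 2] = -77.0
        mask = np.zeros_like(hu, bool)
        mask[1, 2, 2] = True
        mean, med, sd = hu_stats(volume_from_array(hu), mask)
        assert mean == med == -77.0 and sd == 0.0

    def test_empty_mask_absent_not_error(self):
        vol = volume_from_array(np.zeros((2, 4, 4)))
        assert hu_stats(vol, np.zeros((2, 4, 4), bool)) == (None, None, None)

    def test_noisy_phantom_liver_median_within_one_hu(self, default_phantom,
                                                      phantom_volume):
        _spec, _hu, truth = default_phantom
        _mean, med, _sd = hu_stats(phantom_volume, truth.masks["liver"])
        assert abs(med - 55.0) <= 1.0

    def test_invariant_to_intensity_offset(self):
        rng = np.random.default_rng(3)
        hu = rng.uniform(-200, 200, size=(3, 5, 5))
        mask = rng.random(size=hu.shape) < 0.5
        a = hu_stats(volume_from_array(hu), mask)
        shifted = volume_from_array(hu - 500.0)  # different offset record
        shifted.voxels = shifted.voxels  # raw differs; stats differ by 500
        b = hu_stats(shifted, mask)
        assert a[0] - b[0] == pytest.approx(500.0)


class TestVsr:
    def test_ratio(self):
        assert vsr(100.0, 200.0) == 0.5

    def test_zero_sat_absent(self):
        assert vsr(10.0, 0.0) is None

    def test_phantom_ratio_matches_truth(self, default_phantom, phantom_volume,
                                         phantom_landmarks):
        _spec, _hu, truth = default_phantom
        lm = segment(phantom_volume, "truth", ("vat", "sat"), truth=truth)
        s = phantom_landmarks.get("L3")
        r = vsr(cross_sectional_area(lm, "vat", s, phantom_volume),
                cross_sectional_area(lm, "sat", s, phantom_volume))
        assert r == pytest.approx(truth.expected["vsr_L3"].value, rel=0.05)


class TestMeasureStudy:
    def test_full_battery_on_phantom(self, default_phantom, phantom_volume,
                                     phantom_landmarks):
        _spec, _hu, truth = default_phantom
        lm = segment(phantom_volume, "truth",
                     ("vat", "sat", "muscle", "plaque", "trabecular", "aorta",
                      "liver", "spleen", "kidney_left", "kidney_right",
                      "pancreas"), truth=truth)
        ms = measure_study(phantom_volume, lm, phantom_landmarks)
        keys = {(m.name, m.level) for m in ms}
        assert ("vat_csa", "L3") in keys
        assert ("trabecular_density", "T10") in keys
        assert ("kidney_volume", "left") in keys
        assert ("total_agatston", "compartment") in keys
        by = {(m.name, m.level): m for m in ms}
        assert by[("total_agatston", "compartment")].value == \
            truth.expected["total_agatston"].value
        assert by[("abdominal_agatston", "compartment")].value == \
            truth.expected["abdominal_agatston"].value

    def test_missing_lumbar_levels_flagged(self, default_phantom,
                                           phantom_volume):
        _spec, _hu, truth = default_phantom
        lm = segment(phantom_volume, "truth", ("vat", "sat", "muscle"),
                     truth=truth)
        partial = LandmarkSet(positions={"T10": 6, "T11": 12})
        ms = measure_study(phantom_volume, lm, partial)
        l3 = [m for m in ms if m.level == "L3"]
        assert l3 and all("partial_anatomy" in m.flags for m in l3)
        assert all(m.value is None for m in l3)
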