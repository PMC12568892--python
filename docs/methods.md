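# Methods

This note records the measurement conventions, the phantom design, the
numerical choices, and the limitations of `ctbodycomp`.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate and orientation conventions

Volumes are numpy arrays indexed `[slice, row, col]`.  After
normalization, slice 0 is the most **superior** (cranial) slice — the
standard axial viewing order — with the patient's left on the image right
and anterior at the top.  DICOM patient coordinates (+x left, +y
posterior, +z cranial) therefore have physical z *decreasing* with slice
index; the per-slice z positions are kept in the volume's provenance and
every landmark or mask can be re-expressed on any grid through them.
Consequences used throughout: a landmark cranial to another has the
smaller slice index, vertebral landmarks satisfy
`index(T10) < index(T11) < … < index(L5)`, and the abdominal aortic
compartment is the inclusive slice interval
`[aortic_hiatus, aortic_bifurcation]`.

## Normalization

Fixed composition order: assemble → regularize → reorient → resample →
intensity offset, each step logged in provenance.

* **Assembly** applies RescaleSlope/Intercept and sorts slices by
  ascending z; duplicate z positions or inconsistent in-plane dimensions
  are hard errors (they indicate a mixed or corrupt series).
* **Regularization** resamples irregular z sampling onto the modal slice
  spacing with linear interpolation; already-uniform input passes through
  bit-identically.
* **Reorientation** uses the direction cosines to flip in-plane axes and
  z order into the canonical frame.  Missing orientation metadata
  degrades to identity with a provenance warning rather than failing the
  study.
* **Resampling** targets 3 mm slice thickness/spacing, chosen as the
  standard analysis grid: fine enough to limit partial-volume effects,
  coarse enough that thick and thin native acquisitions land on a common
  footing.  Only the out-of-plane axis is resampled; in-plane pixel
  spacing stays native and cross-sectional areas use native pixel area.
  (In-plane 3 mm resampling is deliberately not the default; areas would
  then quantize on a 9 mm² grid.)  Intensities interpolate linearly;
  label maps transported through the same transforms use
  nearest-neighbour so labels never mix.
* **Intensity offset**: the volume minimum is subtracted so air/background
  is exactly 0 and no stored value is negative.  The offset is *stored*
  (`raw = stored − offset`) rather than re-derived later, so cropping can
  never silently change the HU mapping.  All HU-threshold operations act
  on raw HU via this inverse mapping, which makes every density
  measurement invariant to the offset.

## Series selection

A series is eligible when it has ≥ 30 images, carries a primary axial
`ImageType` (no `SECONDARY`/`REFORMATTED`/`MPR` tokens), has slice
thickness < 7.5 mm, and its description contains none of the dual-energy
keywords {mono, monoenergetic, kev, material, iodine, vnc}
(case-insensitive).  The 30-image minimum is evaluated at series level,
before acquisition disambiguation.  Phase is inferred from
SeriesDescription keywords plus ContrastBolusAgent presence; an
unmatched description without contrast tags reads as non-contrast, with
contrast tags as unknown.  Selection order: phase priority (non-contrast
> portal venous > delayed > arterial > unknown), then thinnest slice,
then lowest series number (a deterministic tie-break).  Within the chosen
series, the acquisition number spanning the greatest z extent wins; exact
ties go to the lowest acquisition number.  When SliceThickness varies
across files the modal value is used (robust to isolated outlier tags).

## Agatston scoring

`score = Σ_slices area_slice × factor(peak_slice)` with plaque area in
mm² (pixel count × in-plane pixel area) and the density factor driven by
the **per-slice peak** attenuation: the factor applies to the whole
slice's plaque area, not per lesion.  On real-valued HU the bins are
half-open — [130, 200) → 1, [200, 300) → 2, [300, 400) → 3, [400, ∞) → 4
— which coincides with the printed integer bins (130–199, 200–299,
300–399, ≥ 400) on integer inputs and assigns the boundary value to the
higher factor in between.  No minimum-lesion-area filter is applied by
default.  Plaque components are labelled with 26-connectivity in 3-D
(8-connectivity in-slice); the choice is explicit because per-slice areas
depend on how touching lesions merge.  The total score covers every slice
where the aorta mask (or plaque) is visible; the abdominal score covers
the hiatus→bifurcation interval and is therefore never larger.  A
brute-force per-voxel oracle (`phantom.agatston_voxel_loop`) restates the
formula with explicit Python loops and an independent copy of the bins;
the test suite requires exact equality between engine and oracle on 100
randomized phantoms.

## Segmentation backends

The segmentation layer is a registry of backends returning named boolean
masks, merged into one label map with fixed precedence (plaque >
trabecular > organs > muscle > vat/sat; overlaps are logged).  The
shipped rules backend uses literature-standard HU windows, all
config-overridable:

* **Fat** −190…−30 HU inside the body (largest connected component above
  −500 HU).  Per slice, muscle-range voxels (−29…150 HU) are closed with
  a small disk; the component enclosing a large cavity is taken as the
  abdominal wall ring, and fat partitions into SAT (outside) and VAT
  (inside the cavity).  The closing absorbs small intramuscular fat
  pockets into the muscle mask — muscle area deliberately includes
  intramuscular adipose tissue — but a literal hole-fill of the ring is
  avoided, since that would count the entire visceral cavity as muscle.
  A slice with no closed ring (open abdominal wall) gets its fat
  labelled SAT and a per-slice warning; this fallback is a design choice,
  not a clinically validated rule.
* **Aortic calcium** ≥ 130 HU within the 1-voxel-dilated aorta mask.  The
  rules backend requires an externally supplied vessel mask (phantom
  truth or a plugged model); a vessel tracker is out of scope.
* **Trabecular ROI**: at a vertebral landmark slice, an ellipse centred
  on the dominant bone component's centroid at 60 % of its equivalent
  radius, eroded and stripped of cortical-range voxels (≥ 400 HU).
* **Organs**: no rules model is provided — organ HU ranges overlap
  muscle and each other, so thresholding cannot separate them honestly.
  Organ targets require the truth backend or a registered model backend.

## Landmarking

Providers map a normalized volume to named slice positions; ordering
invariants are enforced at the boundary, so no inconsistent landmark set
reaches measurement.  The rule-based fallback thresholds bone at 200 HU,
bridges intervertebral gaps with a z-only dilation to isolate the
vertebral column as one component, reads the per-slice bone-area profile
(area minima = disc spaces), and labels bodies counting cranially from
the most caudal detected body, which it assumes is L5.  Landmark = center
slice of the body; even-length bodies round caudally.  The L5 anchor
assumption and the 0.2×peak area threshold are declared limitations of
the fallback, not of the provider interface; a trained slice-score model
can be registered without changing consumers.  The aortic hiatus and
bifurcation are left to dedicated providers (the phantom truth provider
supplies them exactly).

## Measurement battery and usable ranges

Areas are pixel count × native pixel area (cm²) at the L1/L3 levels;
volumes are voxel count × voxel volume (mL); densities are medians of raw
HU (mean and SD available), trabecular density at T10/T12/L1/L3; VSR =
VAT/SAT area.  Missing landmarks yield null measurements flagged
`partial_anatomy`; empty masks yield nulls flagged `empty_mask` — absent
values are reported, never silently dropped.  Every biomarker has an
inclusive usable range (shipped in `ranges.yaml`); out-of-range values
are flagged `range_fail` but retained.  Bounds are inclusive because the
limits are defined as values beyond which no valid segmentation exists —
the bounds themselves are attainable.  The contrast check classifies the
aortic blood-pool mean as present (≥ 140 HU) or absent (≤ 90 HU), with an
indeterminate band between; the thresholds are package defaults
(config-overridable) chosen to separate unenhanced blood (~40 HU) from
arterial-phase enhancement with a wide guard band, and disagreement with
the DICOM contrast tags raises `contrast_mismatch`.

## The phantom

The generator emulates the *structure* the pipeline consumes, not
anatomy: an elliptical body with concentric subcutaneous-fat and
body-wall-muscle rings around a visceral-fat interior; ellipsoidal liver,
spleen, kidneys and pancreas analogs; an 8-body vertebral column
(trabecular core 150 HU inside a 700 HU cortical shell); and an aortic
cylinder (blood 40 HU) carrying spherical plaques of controlled radius
and uniform peak attenuation.  Tissue HU centers (fat −100, muscle +50,
liver +55, spleen +50, kidney +35, pancreas +40) are literature-standard
values chosen so threshold segmentation is unambiguous; noise is additive
Gaussian per tissue (default SD 5 HU, seeded, bit-reproducible), with
plaques left noise-free so peak attenuation is exactly controlled.  The
default study is a 400×320×180 mm field at 2.5×2.5×3 mm with two plaques
(420 HU in the abdominal compartment, 300 HU above the hiatus) so the
abdominal and total Agatston scores differ.  Paint order (background →
body → rings → organs → vertebrae → aorta → plaques) resolves overlaps
deterministically — later wins — and truth masks record exactly the
surviving voxels, so mutually exclusive tissues are disjoint by
construction and verified after painting.  Geometrically impossible
specs (overlapping exclusive organs, plaques outside the aorta, organs
outside the body) are rejected with diagnostics naming the labels.
DICOM emission stores `round(HU) + 1024` at 12 bits with slope 1 /
intercept −1024, bounding round-trip error by 0.5 HU; UIDs derive
deterministically from the plan's entropy string.

What the phantom does **not** emulate — and hence what passing tests do
not show about clinical data: partial-volume mixtures at tissue
boundaries, beam hardening and scatter, anatomical shape variation,
contrast-enhancement kinetics, motion, and texture.  Threshold-backend
Dice ≈ 1 on the phantom is a correctness check of the morphology logic,
not a clinical accuracy claim.

## Determinism and problem sizes

Fixed phantom seed + config ⇒ byte-identical report JSON and QA PNGs
(UIDs, noise, and field ordering are all derived deterministically).  The
test suite uses a 160×128×60 default phantom and a 64×64×24 compact
variant for property sweeps; these sizes were chosen so the full suite
exercises every stage, including 100 randomized oracle-equivalence
trials, in well under a minute on one CPU.

## Known limitations

* The rules backends are phantom-calibrated stand-ins for trained models:
  usable for pipeline validation, not for clinical measurement.
* The heuristic landmarker needs a visible L5 and regular disc gaps;
  transitional vertebrae or severe degeneration would mislabel levels.
* Multi-frame enhanced CT objects are not parsed (single-frame CT only),
  and PACS/DIMSE networking is out of scope — the toolkit starts from
  files on disk.
* The contrast detector is a two-threshold heuristic on the aortic blood
  pool; organ-enhancement-based detection is not implemented.
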