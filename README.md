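# ctbodycomp

Automated body-composition analysis for abdominal CT, built for
opportunistic screening research: every abdominal CT acquired for an
unrelated indication also carries quantitative information about muscle,
fat, bone, solid organs and vascular calcification.  `ctbodycomp`
implements the full measurement pipeline — DICOM series selection, volume
normalization, vertebral landmarking, tissue segmentation, biomarker
measurement, physiological range validation and standards-based reporting
— together with a **synthetic abdominal phantom generator** that provides
exact ground truth (masks, landmarks, analytic biomarker values), so the
whole chain is testable end to end without any clinical data.

It is aimed at imaging scientists building or validating body-composition
pipelines, and at anyone who needs a deterministic, fully-specified test
bench for DICOM-to-biomarker software.

## The pipeline

1. **Ingest & series selection** — catalogue a study's DICOM files; keep
   series with ≥ 30 images, a primary axial `ImageType`, slice thickness
   < 7.5 mm and no dual-energy derived output; choose the preferred series
   by contrast-phase priority (non-contrast > portal venous > delayed >
   arterial), then thinnest slice; within a series, keep the acquisition
   number with the greatest axial coverage.
2. **Normalization** — assemble HU with rescale slope/intercept, linearly
   regularize irregular slice sampling, reorient to head-first-supine,
   resample to the standard 3 mm slice grid, and subtract the volume
   minimum so air is exactly 0 (the offset is stored; raw HU is always
   recoverable).
3. **Anatomical landmarks** — slice positions of the T10–L5 vertebral-body
   centers plus the aortic hiatus and bifurcation, via a pluggable
   provider interface (a rule-based spine landmarker and a phantom-truth
   provider ship with the package).
4. **Segmentation** — pluggable backends producing label maps for VAT,
   SAT, muscle, aortic calcium, the vertebral trabecular ROI and solid
   organs.  Shipped: a threshold/morphology backend (fat −190…−30 HU,
   muscle −29…150 HU, calcium ≥ 130 HU inside the aorta) and a
   ground-truth backend for phantoms.
5. **Measurement, validation & reporting** — the full biomarker battery
   with per-biomarker usable ranges, a contrast-presence check, QA
   overlays + coronal MIP images, DICOM secondary-capture export and a
   deterministic JSON report.

The slice-wise aortic **Agatston score** is the package's central
measurement:

```
Agatston = Σ_slices  (plaque area_slice [mm²] × density factor_slice)

density factor = 1  if peak HU ∈ [130, 200)
                 2  if peak HU ∈ [200, 300)
                 3  if peak HU ∈ [300, 400)
                 4  if peak HU ≥ 400        (0 below 130 HU)
```

It is reported twice: over the abdominal aortic compartment (hiatus →
bifurcation) and over the entire visible aorta.

## Worked example

```bash
ctbodycomp phantom make --out study/ --seed 2     # synthetic DICOM study + truth
ctbodycomp run study/ --out results/ --backend truth
```

`results/report.json` then contains (abridged):

| biomarker | level | value | units |
|---|---|---|---|
| Muscle Cross-Sectional Area | L3 | 89.75 | cm² |
| Visceral Adipose Tissue Cross-Sectional Area | L3 | 344.19 | cm² |
| Subcutaneous Adipose Tissue Cross-Sectional Area | L3 | 150.25 | cm² |
| VSR | L3 | 2.29 | — |
| Vertebral Trabecular Bone Median Density | L1 | 151.0 | HU |
| Liver Volume / Median Density | — | 363.82 / 55.0 | mL / HU |
| Abdominal Agatston | compartment | 375.0 | — |
| Total Aortic Agatston | compartment | 656.25 | — |

All values fall inside their physiological usable ranges
(`any_tool_failed: false`); the contrast check reads the 45 HU aortic
blood pool as `absent`, consistent with the missing contrast tags.  The
Agatston values equal the phantom's analytic ground truth exactly: the
abdominal plaque (420 HU peak, factor 4) contributes 375 in-compartment,
the supra-diaphragmatic plaque (300 HU peak, factor 3) raises only the
total.  Swapping `--backend threshold` reproduces the same scores from HU
thresholds alone.

The same pipeline runs on real studies (`ctbodycomp run <dicom_dir>`);
organ segmentation then requires plugging a model backend — the
threshold backend covers fat, muscle, calcium and trabecular bone.

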