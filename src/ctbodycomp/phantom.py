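"""Synthetic abdominal CT phantom generator.

Builds voxelized abdominal phantoms with geometric organ analogs (liver,
spleen, kidneys, pancreas), a vertebral column (cortical shell + trabecular
core), concentric subcutaneous-fat and body-wall-muscle rings around a
visceral fat compartment, and an aorta carrying calcified plaques of
controlled size and peak attenuation.  Every phantom comes with exact
ground-truth masks, landmark slice indices, and analytically known biomarker
values, so each downstream pipeline stage can be tested without clinical
data.  Phantoms can be emitted as standards-conformant single-frame CT DICOM
series under a configurable acquisition plan (multi-series, multi-
acquisition, irregular z sampling, missing tags).

Array convention: volumes are indexed ``[slice, row, col]`` with slice 0 the
most superior (cranial) slice; DICOM patient coordinates have +x toward the
patient's left, +y posterior, +z cranial, so physical z decreases with slice
index.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = [
    "OrganDef",
    "VertebraDef",
    "PlaqueDef",
    "AortaDef",
    "PhantomSpec",
    "PhantomTruth",
    "ExpectedValue",
    "PhantomDefinitionError",
    "build_phantom",
    "default_spec",
    "agatston_voxel_loop",
    "SeriesPlan",
    "AcquisitionPlan",
    "write_dicom_series",
    "write_truth_sidecar",
    "load_truth_sidecar",
    "LANDMARK_NAMES",
]

LANDMARK_NAMES = (
    "T10", "T11", "T12", "L1", "L2", "L3", "L4", "L5",
    "aortic_hiatus", "aortic_bifurcation",
)

VERTEBRAL_LEVELS = ("T10", "T11", "T12", "L1", "L2", "L3", "L4", "L5")


class PhantomDefinitionError(ValueError):
    """Raised when a phantom spec is geometrically inconsistent."""


@dataclass(frozen=True)
class OrganDef:
    """A geometric organ analog.

    ``center_mm`` is (x, y, z) in patient coordinates (z = physical slice
    position); ``radii_mm`` are the semi-axes.  ``shape`` is ``ellipsoid``
    or ``cylinder`` (a cylinder has its axis along z with in-plane radii
    ``radii_mm[:2]`` and half-height ``radii_mm[2]``).
    """

    name: str
    shape: str
    center_mm: Tuple[float, float, float]
    radii_mm: Tuple[float, float, float]
    mean_hu: float
    noise_sd: Optional[float] = None  # None -> spec-level default


@dataclass(frozen=True)
class VertebraDef:
    level: str
    center_slice: int
    body_radius_mm: float = 17.0
    height_mm: float = 12.0
    cortical_hu: float = 700.0
    trabecular_hu: float = 150.0
    cortical_thickness_mm: float = 3.0


@dataclass(frozen=True)
class PlaqueDef:
    """A spherical calcified plaque of uniform attenuation ``peak_hu``."""

    center_mm: Tuple[float, float, float]
    radius_mm: float
    peak_hu: float


@dataclass(frozen=True)
class AortaDef:
    center_xy_mm: Tuple[float, float] = (-6.0, 24.0)
    radius_mm: float = 9.0
    slice_range: Tuple[int, int] = (2, 42)  # inclusive, cranial-first indices
    blood_hu: float = 40.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: Tuple[int, int, int] = (160, 128, 60)  # (nx, ny, nz)
    voxel_spacing_mm: Tuple[float, float, float] = (2.5, 2.5, 3.0)
    body_ellipse_mm: Tuple[float, float] = (170.0, 115.0)
    fat_ring_thickness_mm: float = 18.0
    muscle_ring_thickness_mm: float = 12.0
    organ_defs: Tuple[OrganDef, ...] = ()
    vertebra_defs: Tuple[VertebraDef, ...] = ()
    aorta: Optional[AortaDef] = None
    plaque_defs: Tuple[PlaqueDef, ...] = ()
    hiatus_slice: Optional[int] = None       # default: T12 center
    bifurcation_slice: Optional[int] = None  # default: L4 center
    background_hu: float = -1000.0
    visceral_fat_hu: float = -100.0
    sat_hu: float = -100.0
    muscle_hu: float = 50.0
    noise_sd: float = 5.0
    seed: int = 0

    @property
    def shape_zyx(self) -> Tuple[int, int, int]:
        nx, ny, nz = self.grid_shape
        return (nz, ny, nx)

    def slice_z_mm(self, index) -> np.ndarray:
        """Physical z position of a (cranial-first) slice index."""
        nz = self.grid_shape[2]
        dz = self.voxel_spacing_mm[2]
        return (nz - 1 - np.asarray(index, dtype=float)) * dz

    @property
    def z_positions_mm(self) -> np.ndarray:
        return self.slice_z_mm(np.arange(self.grid_shape[2]))


@dataclass(frozen=True)
class ExpectedValue:
    value: float
    units: str


@dataclass
class PhantomTruth:
    """Exact ground truth for a generated phantom."""

    masks: Dict[str, np.ndarray]
    landmarks: Dict[str, int]
    expected: Dict[str, ExpectedValue]
    spacing_mm: Tuple[float, float, float]
    z_positions_mm: np.ndarray


def default_spec(seed: int = 0, noise_sd: float = 5.0,
                 plaques: Optional[Sequence[PlaqueDef]] = None) -> PhantomSpec:
    """A realistic default abdomen: 400x320 mm field of view, 60 x 3 mm
    slices covering T10-L5, four solid-organ analogs, and (by default) one
    abdominal and one supra-diaphragmatic plaque so the abdominal and total
    Agatston scores differ."""
    vertebrae = tuple(
        VertebraDef(level=lev, center_slice=6 + 6 * k)
        for k, lev in enumerate(VERTEBRAL_LEVELS)
    )
    organs = (
        OrganDef("liver", "ellipsoid", (-60.0, -10.0, 135.0), (55.0, 45.0, 35.0), 55.0),
        OrganDef("spleen", "ellipsoid", (75.0, 5.0, 141.0), (30.0, 25.0, 25.0), 50.0),
        OrganDef("kidney_left", "ellipsoid", (55.0, 35.0, 87.0), (22.0, 20.0, 32.0), 35.0),
        OrganDef("kidney_right", "ellipsoid", (-55.0, 35.0, 87.0), (22.0, 20.0, 32.0), 35.0),
        OrganDef("pancreas", "ellipsoid", (5.0, 0.0, 99.0), (40.0, 14.0, 10.0), 40.0),
    )
    aorta = AortaDef()
    if plaques is None:
        az = aorta.center_xy_mm
        spec0 = PhantomSpec()
        plaques = (
            PlaqueDef((az[0], az[1], float(spec0.slice_z_mm(30))), 4.0, 420.0),
            PlaqueDef((az[0], az[1], float(spec0.slice_z_mm(10))), 4.0, 300.0),
        )
    return PhantomSpec(
        organ_defs=organs,
        vertebra_defs=vertebrae,
        aorta=aorta,
        plaque_defs=tuple(plaques),
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# geometry helpers

def _coord_grids(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_spacing_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    z = spec.z_positions_mm
    return x, y, z


def _shape_mask(spec: PhantomSpec, shape: str, center: Sequence[float],
                radii: Sequence[float]) -> np.ndarray:
    x, y, z = _coord_grids(spec)
    cx, cy, cz = center
    rx, ry, rz = radii
    xx = ((x - cx) / rx) ** 2
    yy = ((y - cy) / ry) ** 2
    zz = ((z - cz) / rz) ** 2
    if shape == "ellipsoid":
        return (zz[:, None, None] + yy[None, :, None] + xx[None, None, :]) <= 1.0
    if shape == "cylinder":
        inplane = (yy[None, :, None] + xx[None, None, :]) <= 1.0
        return (zz <= 1.0)[:, None, None] & inplane
    raise PhantomDefinitionError(f"unknown shape {shape!r}")


def _ellipse_norm(spec: PhantomSpec, a: float, b: float) -> np.ndarray:
    """Per-pixel normalized ellipse radius for semi-axes (a, b)."""
    x, y, _ = _coord_grids(spec)
    return np.sqrt((x[None, :] / a) ** 2 + (y[:, None] / b) ** 2)


# ---------------------------------------------------------------------------
# oracle

def _density_factor_printed(peak_hu: float) -> int:
    # Independent restatement of the Agatston weighting bins; deliberately
    # kept separate from biomarkers.density_factor so the two can be
    # cross-checked against each other.
    if peak_hu < 130:
        return 0
    if peak_hu < 200:
        return 1
    if peak_hu < 300:
        return 2
    if peak_hu < 400:
        return 3
    return 4


def agatston_voxel_loop(raw_hu: np.ndarray, plaque_mask: np.ndarray,
                        pixel_area_mm2: float,
                        slices: Optional[Sequence[int]] = None) -> float:
    """Brute-force per-voxel Agatston oracle.

    Walks every plaque voxel slice by slice in explicit Python loops,
    accumulating per-slice plaque area and peak attenuation, then sums
    area x density-factor over slices.  Used to pin down ground truth; the
    production implementation lives in :mod:`ctbodycomp.biomarkers`.
    """
    nz = raw_hu.shape[0]
    if slices is None:
        slices = range(nz)
    score = 0.0
    for s in slices:
        count = 0
        peak = None
        rows, cols = np.nonzero(plaque_mask[s])
        for r, c in zip(rows.tolist(), cols.tolist()):
            count += 1
            v = float(raw_hu[s, r, c])
            if peak is None or v > peak:
                peak = v
        if count == 0:
            continue
        score += count * pixel_area_mm2 * _density_factor_printed(peak)
    return score


# ---------------------------------------------------------------------------
# phantom construction

_EXCLUSIVE_GROUPS = ("liver", "spleen", "kidney_left", "kidney_right",
                     "pancreas", "aorta", "vertebra")


def build_phantom(spec: PhantomSpec) -> Tuple[np.ndarray, PhantomTruth]:
    """Render the phantom HU grid and its exact ground truth.

    Paint order (later overwrites earlier): background, body interior
    (visceral fat), subcutaneous fat ring, muscle ring, organs, vertebrae,
    aorta, plaques.  Truth masks record exactly the voxels that survive to
    the final grid for each tissue.
    """
    nx, ny, nz = spec.grid_shape
    if min(spec.grid_shape) <= 0:
        raise PhantomDefinitionError("grid_shape must be positive")
    if min(spec.voxel_spacing_mm) <= 0:
        raise PhantomDefinitionError("voxel_spacing must be positive")
    dx, dy, dz = spec.voxel_spacing_mm
    pixel_area = dx * dy
    voxel_ml = dx * dy * dz / 1000.0

    a, b = spec.body_ellipse_mm
    e = _ellipse_norm(spec, a, b)
    a_musc = a - spec.fat_ring_thickness_mm
    b_musc = b - spec.fat_ring_thickness_mm
    a_int = a_musc - spec.muscle_ring_thickness_mm
    b_int = b_musc - spec.muscle_ring_thickness_mm
    e_musc = _ellipse_norm(spec, a_musc, b_musc)
    e_int = _ellipse_norm(spec, a_int, b_int)

    body2d = e <= 1.0
    sat2d = body2d & (e_musc > 1.0)
    muscle2d = (e_musc <= 1.0) & (e_int > 1.0)
    interior2d = e_int <= 1.0

    rep = lambda m2: np.broadcast_to(m2, (nz, ny, nx)).copy()
    body = rep(body2d)
    masks: Dict[str, np.ndarray] = {}

    hu = np.full((nz, ny, nx), spec.background_hu, dtype=np.float64)
    rng = np.random.default_rng(spec.seed)

    def paint(mask: np.ndarray, mean: float, sd: Optional[float]):
        hu[mask] = mean
        sd = spec.noise_sd if sd is None else sd
        if sd > 0:
            hu[mask] += rng.normal(0.0, sd, size=int(mask.sum()))

    vat = rep(interior2d)
    sat = rep(sat2d)
    muscle = rep(muscle2d)
    paint(vat, spec.visceral_fat_hu, None)
    paint(sat, spec.sat_hu, None)
    paint(muscle, spec.muscle_hu, None)

    # organs (validated against body ellipse, pairwise disjoint)
    organ_masks: Dict[str, np.ndarray] = {}
    for od in spec.organ_defs:
        m = _shape_mask(spec, od.shape, od.center_mm, od.radii_mm)
        if np.any(m & ~body):
            raise PhantomDefinitionError(
                f"organ {od.name!r} extends outside the body ellipse")
        organ_masks[od.name] = m
        paint(m, od.mean_hu, od.noise_sd)
    names = list(organ_masks)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            if np.any(organ_masks[na] & organ_masks[nb]):
                raise PhantomDefinitionError(
                    f"mutually exclusive labels overlap: {na!r} and {nb!r}")

    # vertebrae: cortical shell + trabecular core, axis along z at (0, +55)
    trabecular = np.zeros((nz, ny, nx), dtype=bool)
    cortical = np.zeros((nz, ny, nx), dtype=bool)
    landmarks: Dict[str, int] = {}
    for vd in spec.vertebra_defs:
        # caudal-rounded center: the body spans [center - n//2, center + n - 1 - n//2]
        n = int(round(vd.height_mm / dz))
        n_lo = n // 2
        n_hi = n - 1 - n_lo
        lo = vd.center_slice - n_lo
        hi = vd.center_slice + n_hi
        if lo < 0 or hi >= nz:
            raise PhantomDefinitionError(
                f"vertebra {vd.level} [{lo},{hi}] outside grid depth {nz}")
        outer2d = _ellipse_norm(spec, vd.body_radius_mm, vd.body_radius_mm)
        ri = vd.body_radius_mm - vd.cortical_thickness_mm
        inner2d = _ellipse_norm(spec, ri, ri)
        x, y, _ = _coord_grids(spec)
        # vertebral bodies sit on the posterior midline
        cyl_out = np.sqrt((x[None, :] - 0.0) ** 2 + (y[:, None] - 55.0) ** 2) <= vd.body_radius_mm
        cyl_in = np.sqrt((x[None, :] - 0.0) ** 2 + (y[:, None] - 55.0) ** 2) <= ri
        for s in range(lo, hi + 1):
            cortical[s] |= cyl_out & ~cyl_in
            trabecular[s] |= cyl_in
        landmarks[vd.level] = vd.center_slice
    if spec.vertebra_defs:
        paint(cortical, spec.vertebra_defs[0].cortical_hu, None)
        paint(trabecular, spec.vertebra_defs[0].trabecular_hu, None)
        for nm, om in organ_masks.items():
            if np.any(om & (cortical | trabecular)):
                raise PhantomDefinitionError(
                    f"mutually exclusive labels overlap: {nm!r} and 'vertebra'")

    # aorta + plaques
    aorta = np.zeros((nz, ny, nx), dtype=bool)
    plaque = np.zeros((nz, ny, nx), dtype=bool)
    if spec.aorta is not None:
        ad = spec.aorta
        lo, hi = ad.slice_range
        if lo < 0 or hi >= nz or lo > hi:
            raise PhantomDefinitionError("aorta slice_range outside grid")
        x, y, _ = _coord_grids(spec)
        cyl = np.sqrt((x[None, :] - ad.center_xy_mm[0]) ** 2 +
                      (y[:, None] - ad.center_xy_mm[1]) ** 2) <= ad.radius_mm
        aorta[lo:hi + 1] = cyl
        for nm, om in organ_masks.items():
            if np.any(om & aorta):
                raise PhantomDefinitionError(
                    f"mutually exclusive labels overlap: {nm!r} and 'aorta'")
        if np.any(aorta & (cortical | trabecular)):
            raise PhantomDefinitionError(
                "mutually exclusive labels overlap: 'vertebra' and 'aorta'")
        paint(aorta, ad.blood_hu, None)
    for k, pd in enumerate(spec.plaque_defs):
        if pd.peak_hu < 0:
            raise PhantomDefinitionError("plaque peak_HU must be >= 0")
        m = _shape_mask(spec, "ellipsoid", pd.center_mm,
                        (pd.radius_mm,) * 3)
        if spec.aorta is None or np.any(m & ~aorta):
            raise PhantomDefinitionError(
                f"plaque {k} not contained in the aorta cylinder")
        hu[m] = pd.peak_hu  # plaques are noise-free: peak is controlled
        plaque |= m

    # finalize masks: later paints carve out earlier tissues
    painted_later = np.zeros((nz, ny, nx), dtype=bool)
    order: List[Tuple[str, np.ndarray]] = [("plaque", plaque), ("aorta", aorta)]
    order += [("trabecular", trabecular), ("cortical", cortical)]
    order += [(nm, organ_masks[nm]) for nm in reversed(list(organ_masks))]
    order += [("muscle", muscle), ("sat", sat), ("vat", vat)]
    for nm, m in order:
        final = m & ~painted_later
        painted_later |= m
        masks[nm] = final
    # the vessel mask keeps its lumen: plaque sits INSIDE the aorta, and the
    # calcium backend takes the full vessel as its search region
    masks["aorta"] = aorta
    masks["body"] = body

    # landmarks: aortic
    hiatus = spec.hiatus_slice
    bifurc = spec.bifurcation_slice
    if hiatus is None and "T12" in landmarks:
        hiatus = landmarks["T12"]
    if bifurc is None and "L4" in landmarks:
        bifurc = landmarks["L4"]
    if hiatus is not None:
        landmarks["aortic_hiatus"] = int(hiatus)
    if bifurc is not None:
        landmarks["aortic_bifurcation"] = int(bifurc)
    for nm, idx in landmarks.items():
        if not (0 <= idx < nz):
            raise PhantomDefinitionError(f"landmark {nm} slice {idx} outside grid")

    # expected analytic values
    expected: Dict[str, ExpectedValue] = {}
    for nm in list(organ_masks) + ["vat", "sat", "muscle",
                                   "plaque", "trabecular"]:
        expected[f"{nm}_volume_ml"] = ExpectedValue(
            float(masks[nm].sum()) * voxel_ml, "mL")
    aorta_slices = [s for s in range(nz) if masks["aorta"][s].any() or plaque[s].any()]
    expected["total_agatston"] = ExpectedValue(
        agatston_voxel_loop(hu, masks["plaque"], pixel_area, aorta_slices),
        "unitless")
    if hiatus is not None and bifurc is not None:
        expected["abdominal_agatston"] = ExpectedValue(
            agatston_voxel_loop(hu, masks["plaque"], pixel_area,
                                range(int(hiatus), int(bifurc) + 1)),
            "unitless")
    for level in ("L1", "L3"):
        if level in landmarks:
            s = landmarks[level]
            for nm in ("vat", "sat", "muscle"):
                expected[f"{nm}_csa_cm2_{level}"] = ExpectedValue(
                    float(masks[nm][s].sum()) * pixel_area / 100.0, "cm2")
            sat_a = expected[f"sat_csa_cm2_{level}"].value
            vat_a = expected[f"vat_csa_cm2_{level}"].value
            if sat_a > 0:
                expected[f"vsr_{level}"] = ExpectedValue(vat_a / sat_a, "unitless")
    if spec.vertebra_defs:
        expected["trabecular_hu"] = ExpectedValue(
            spec.vertebra_defs[0].trabecular_hu, "HU")

    truth = PhantomTruth(
        masks=masks,
        landmarks=landmarks,
        expected=expected,
        spacing_mm=spec.voxel_spacing_mm,
        z_positions_mm=spec.z_positions_mm,
    )
    _assert_exclusive(truth)
    return hu, truth


def _assert_exclusive(truth: PhantomTruth) -> None:
    names = [n for n in ("vat", "sat", "muscle", "plaque", "trabecular")
             if n in truth.masks]
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            if np.any(truth.masks[na] & truth.masks[nb]):  # pragma: no cover
                raise PhantomDefinitionError(
                    f"mutually exclusive labels overlap: {na!r} and {nb!r}")


# ---------------------------------------------------------------------------
# DICOM emission

@dataclass
class SeriesPlan:
    """One emitted DICOM series.

    ``slice_indices`` picks grid slices (default: all, cranial-first);
    ``acquisition_numbers`` is a single number or one per image;
    ``z_positions_mm`` overrides the per-image slice positions (irregular
    sampling); ``omit_keywords`` drops otherwise-default header fields;
    ``extra_tags`` sets arbitrary keyword -> value pairs.
    """

    description: str = "AXIAL ABDOMEN"
    slice_thickness_mm: Optional[float] = None  # default: grid dz
    series_number: int = 1
    image_type: Tuple[str, ...] = ("ORIGINAL", "PRIMARY", "AXIAL")
    slice_indices: Optional[Sequence[int]] = None
    acquisition_numbers: Union[int, Sequence[int]] = 1
    z_positions_mm: Optional[Sequence[float]] = None
    contrast_agent: Optional[str] = None
    contrast_route: Optional[str] = None
    patient_position: str = "HFS"
    omit_keywords: Tuple[str, ...] = ()
    extra_tags: Dict[str, object] = field(default_factory=dict)


@dataclass
class AcquisitionPlan:
    series: List[SeriesPlan]
    patient_id: str = "PHANTOM001"
    patient_name: str = "Phantom^Abdomen"
    study_description: str = "CT ABDOMEN"
    uid_entropy: str = "ctbodycomp-phantom"


_DEFAULT_HEADER = {
    "KVP": 120.0,
    "XRayTubeCurrent": 200,
    "Exposure": 150,
    "ScanOptions": "HELICAL",
    "FilterType": "BODY",
    "ProtocolName": "SYNTHETIC ABDOMEN",
    "BodyPartExamined": "ABDOMEN",
    "Manufacturer": "ctbodycomp",
    "ManufacturerModelName": "PhantomScanner",
    "SoftwareVersions": "1.0",
    "PatientWeight": 70.0,
    "ConvolutionKernel": "STANDARD",
    "ReconstructionDiameter": 400.0,
}


def write_dicom_series(hu_grid: np.ndarray, spec: PhantomSpec,
                       plan: AcquisitionPlan, out_dir: str) -> List[str]:
    """Emit the phantom as Explicit-VR-Little-Endian CT DICOM files.

    Stored values are ``round(HU) + 1024`` (12-bit unsigned) with
    RescaleSlope 1 / RescaleIntercept -1024, so the HU grid reconstructs to
    within 0.5 HU.  Returns the list of written file paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    nz = hu_grid.shape[0]
    dx, dy, _dz = spec.voxel_spacing_mm
    nx, ny = spec.grid_shape[0], spec.grid_shape[1]
    x0 = -(nx - 1) / 2.0 * dx
    y0 = -(ny - 1) / 2.0 * dy
    study_uid = generate_uid(entropy_srcs=[plan.uid_entropy, "study"])
    frame_uid = generate_uid(entropy_srcs=[plan.uid_entropy, "frame"])
    written: List[str] = []
    for sp in plan.series:
        indices = list(sp.slice_indices) if sp.slice_indices is not None \
            else list(range(nz))
        if len(indices) > nz or any(i < 0 or i >= nz for i in indices):
            raise ValueError(
                f"series {sp.series_number}: plan requests slices outside "
                f"grid depth {nz}")
        n = len(indices)
        if isinstance(sp.acquisition_numbers, int):
            acqs = [sp.acquisition_numbers] * n
        else:
            acqs = list(sp.acquisition_numbers)
            if len(acqs) != n:
                raise ValueError("acquisition_numbers length mismatch")
        if sp.z_positions_mm is not None:
            zs = [float(z) for z in sp.z_positions_mm]
            if len(zs) != n:
                raise ValueError("z_positions_mm length mismatch")
        else:
            zs = [float(spec.slice_z_mm(i)) for i in indices]
        series_uid = generate_uid(
            entropy_srcs=[plan.uid_entropy, "series", str(sp.series_number)])
        feet_first = sp.patient_position.upper().startswith("FF")
        thickness = sp.slice_thickness_mm if sp.slice_thickness_mm is not None \
            else spec.voxel_spacing_mm[2]
        for j, (idx, z, acq) in enumerate(zip(indices, zs, acqs)):
            ds = Dataset()
            ds.SOPClassUID = CTImageStorage
            ds.SOPInstanceUID = generate_uid(
                entropy_srcs=[plan.uid_entropy, "instance",
                              str(sp.series_number), str(j)])
            ds.Modality = "CT"
            ds.PatientName = plan.patient_name
            ds.PatientID = plan.patient_id
            ds.StudyInstanceUID = study_uid
            ds.StudyDescription = plan.study_description
            ds.SeriesInstanceUID = series_uid
            ds.SeriesNumber = sp.series_number
            ds.SeriesDescription = sp.description
            ds.FrameOfReferenceUID = frame_uid
            ds.InstanceNumber = j + 1
            ds.AcquisitionNumber = acq
            ds.ImageType = list(sp.image_type)
            ds.PatientPosition = sp.patient_position
            ds.SliceThickness = thickness
            ds.PixelSpacing = [dy, dx]
            ds.ImagePositionPatient = (
                [-x0, y0, z] if feet_first else [x0, y0, z])
            ds.ImageOrientationPatient = (
                [-1, 0, 0, 0, 1, 0] if feet_first else [1, 0, 0, 0, 1, 0])
            ds.SliceLocation = z
            for kw, val in _DEFAULT_HEADER.items():
                setattr(ds, kw, val)
            if sp.contrast_agent is not None:
                ds.ContrastBolusAgent = sp.contrast_agent
                ds.ContrastBolusRoute = sp.contrast_route or "IV"
            for kw, val in sp.extra_tags.items():
                setattr(ds, kw, val)
            for kw in sp.omit_keywords:
                if hasattr(ds, kw):
                    delattr(ds, kw)
            sl = hu_grid[idx]
            if feet_first:
                sl = sl[:, ::-1]
            stored = np.clip(np.round(sl) + 1024, 0, 4095).astype(np.uint16)
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.Rows, ds.Columns = stored.shape
            ds.BitsAllocated = 16
            ds.BitsStored = 12
            ds.HighBit = 11
            ds.PixelRepresentation = 0
            ds.RescaleIntercept = -1024.0
            ds.RescaleSlope = 1.0
            ds.PixelData = stored.tobytes()
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = CTImageStorage
            meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.file_meta = meta
            path = os.path.join(
                out_dir, f"series{sp.series_number:03d}_img{j:04d}.dcm")
            ds.save_as(path, enforce_file_format=True)
            written.append(path)
    return written


# ---------------------------------------------------------------------------
# truth sidecar (for the truth segmentation/landmark backends)

_SIDECAR_LABEL_IDS = {
    "vat": 1, "sat": 2, "muscle": 3, "plaque": 4, "trabecular": 5,
    "liver": 6, "spleen": 7, "kidney_left": 8, "kidney_right": 9,
    "pancreas": 10, "aorta": 11,
}


def write_truth_sidecar(truth: PhantomTruth, out_dir: str) -> str:
    """Persist truth as a NIfTI label volume + JSON table.

    Returns the JSON path.  Mutually exclusive tissue masks share one label
    volume; landmarks are stored both as native slice indices and physical z
    so they can be re-expressed on any resampled grid.
    """
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    shape = next(iter(truth.masks.values())).shape
    labels = np.zeros(shape, dtype=np.int16)
    # plaque painted last: it lies inside the (full-vessel) aorta mask
    paint_order = ("vat", "sat", "muscle", "liver", "spleen", "kidney_left",
                   "kidney_right", "pancreas", "aorta", "trabecular", "plaque")
    for nm in paint_order:
        if nm in truth.masks:
            labels[truth.masks[nm]] = _SIDECAR_LABEL_IDS[nm]
    dx, dy, dz = truth.spacing_mm
    aff = np.diag([dx, dy, -dz, 1.0])
    aff[2, 3] = float(truth.z_positions_mm[0])
    img = nib.Nifti1Image(np.transpose(labels, (2, 1, 0)), aff)
    nii_path = os.path.join(out_dir, "phantom_truth_labels.nii")
    nib.save(img, nii_path)
    doc = {
        "label_ids": _SIDECAR_LABEL_IDS,
        "spacing_mm": list(truth.spacing_mm),
        "z_positions_mm": [float(z) for z in truth.z_positions_mm],
        "landmarks": {k: int(v) for k, v in truth.landmarks.items()},
        "landmark_z_mm": {
            k: float(truth.z_positions_mm[v]) for k, v in truth.landmarks.items()},
        "expected": {k: {"value": ev.value, "units": ev.units}
                     for k, ev in truth.expected.items()},
        "labels_nifti": os.path.basename(nii_path),
    }
    json_path = os.path.join(out_dir, "phantom_truth.json")
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
    return json_path


def load_truth_sidecar(json_path: str) -> PhantomTruth:
    import nibabel as nib

    with open(json_path) as fh:
        doc = json.load(fh)
    nii = nib.load(os.path.join(os.path.dirname(json_path), doc["labels_nifti"]))
    labels = np.transpose(np.asarray(nii.dataobj), (2, 1, 0))
    masks = {nm: labels == lid for nm, lid in doc["label_ids"].items()}
    # restore the full-vessel aorta (its lumen plaque carries the plaque label)
    masks["aorta"] = masks["aorta"] | masks["plaque"]
    expected = {k: ExpectedValue(v["value"], v["units"])
                for k, v in doc["expected"].items()}
    return PhantomTruth(
        masks=masks,
        landmarks={k: int(v) for k, v in doc["landmarks"].items()},
        expected=expected,
        spacing_mm=tuple(doc["spacing_mm"]),
        z_positions_mm=np.asarray(doc["z_positions_mm"], dtype=float),
    )
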