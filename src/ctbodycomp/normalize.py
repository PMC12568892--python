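"""Canonical volume normalization.

Turns one selected DICOM acquisition into a canonical head-first-supine
volume: HU assembly (rescale slope/intercept, ascending-z sort), linear
regularization of irregular slice sampling onto the modal spacing,
reorientation so slice 0 is the most superior slice with the patient's
left on the image right, resampling to the standard 3 mm slice grid, and a
min-subtraction intensity offset so stored values are non-negative with
air at exactly 0.  Every transform is logged in the volume's provenance
and the raw HU scale is exactly recoverable from the stored offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pydicom

__all__ = [
    "NormalizedVolume",
    "assemble_volume",
    "regularize_slices",
    "reorient_hfs",
    "resample_standard",
    "apply_intensity_offset",
    "normalize_acquisition",
    "transport_slices",
    "map_z_to_slice",
    "STANDARD_DZ_MM",
]

STANDARD_DZ_MM = 3.0
_Z_TOL = 1e-3  # mm; slack for floating-point slice positions


@dataclass
class NormalizedVolume:
    """Canonical volume: offset intensities plus the inverse mapping.

    ``voxels`` holds ``raw_HU + intensity_offset`` (minimum exactly 0);
    ``raw_hu()`` inverts the offset.  ``provenance['z_positions_mm']`` is
    the physical z of each slice (descending: slice 0 superior).
    """

    voxels: np.ndarray                       # (nz, ny, nx), offset applied
    spacing_mm: Tuple[float, float, float]   # (dx, dy, dz)
    intensity_offset: float                  # offset = -min(raw HU)
    orientation_canonical: bool
    provenance: Dict[str, object] = field(default_factory=dict)

    def raw_hu(self) -> np.ndarray:
        return self.voxels - self.intensity_offset

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def z_positions_mm(self) -> np.ndarray:
        return np.asarray(self.provenance["z_positions_mm"], dtype=float)

    def pixel_area_mm2(self) -> float:
        return self.spacing_mm[0] * self.spacing_mm[1]

    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    def to_nifti(self, path: str) -> str:
        import nibabel as nib
        dx, dy, dz = self.spacing_mm
        aff = np.diag([dx, dy, -dz, 1.0])
        aff[2, 3] = float(self.z_positions_mm[0])
        img = nib.Nifti1Image(
            np.transpose(self.voxels.astype(np.float32), (2, 1, 0)), aff)
        nib.save(img, path)
        return path


def assemble_volume(files: Sequence[str]):
    """Stack one acquisition into a raw-HU volume sorted by ascending z.

    Returns ``(hu, meta)`` where ``meta`` carries the per-slice z
    positions, pixel spacing, orientation cosines and series UID.  Raises
    on inconsistent in-plane dimensions or duplicate z positions.
    """
    if not files:
        raise ValueError("no files to assemble")
    slices = []
    for path in files:
        ds = pydicom.dcmread(path)
        ipp = getattr(ds, "ImagePositionPatient", None)
        z = float(ipp[2]) if ipp is not None else float(
            getattr(ds, "SliceLocation", 0.0))
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        slices.append((z, hu, ds))
    shapes = {s[1].shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent in-plane dimensions: {sorted(shapes)}")
    zs = sorted(z for z, _h, _d in slices)
    for za, zb in zip(zs, zs[1:]):
        if abs(zb - za) < _Z_TOL:
            raise ValueError(f"duplicate z positions at {za:.3f} mm")
    slices.sort(key=lambda s: s[0])
    hu = np.stack([h for _z, h, _d in slices])
    first = slices[0][2]
    ps = getattr(first, "PixelSpacing", [1.0, 1.0])
    iop = getattr(first, "ImageOrientationPatient", None)
    meta = {
        "z_positions_mm": np.array([z for z, _h, _d in slices], dtype=float),
        "pixel_spacing_mm": (float(ps[1]), float(ps[0])),  # (dx, dy)
        "iop": [float(v) for v in iop] if iop is not None else None,
        "patient_position": str(getattr(first, "PatientPosition", "")) or None,
        "series_uid": str(getattr(first, "SeriesInstanceUID", "")),
        "slice_thickness_mm": (float(first.SliceThickness)
                               if getattr(first, "SliceThickness", None)
                               not in (None, "") else None),
    }
    return hu, meta


def _modal_spacing(z: np.ndarray) -> float:
    steps = np.round(np.diff(z), 3)
    vals, counts = np.unique(steps, return_counts=True)
    return float(vals[np.argmax(counts)])


def _interp_slices(hu: np.ndarray, z_in: np.ndarray,
                   z_out: np.ndarray) -> np.ndarray:
    """Linear interpolation of slices along z (z_in ascending)."""
    idx = np.searchsorted(z_in, z_out, side="left")
    idx = np.clip(idx, 1, len(z_in) - 1)
    lo = idx - 1
    hi = idx
    w = (z_out - z_in[lo]) / (z_in[hi] - z_in[lo])
    w = np.clip(w, 0.0, 1.0)[:, None, None]
    return (1.0 - w) * hu[lo] + w * hu[hi]


def regularize_slices(hu: np.ndarray, z_positions_mm: np.ndarray):
    """Resample irregularly spaced slices onto a uniform grid.

    The output spacing is the modal input spacing; inserted slices are the
    linear interpolation of their bracketing neighbours.  Already-uniform
    input is returned unchanged (same array object).
    """
    z = np.asarray(z_positions_mm, dtype=float)
    if hu.shape[0] < 2:
        raise ValueError("cannot regularize: fewer than 2 slices")
    dz = _modal_spacing(z)
    if dz <= 0:
        raise ValueError("z positions must be strictly increasing")
    n_out = int(np.floor((z[-1] - z[0]) / dz + _Z_TOL)) + 1
    z_out = z[0] + dz * np.arange(n_out)
    if len(z_out) == len(z) and np.allclose(z_out, z, atol=_Z_TOL):
        return hu, z, float(dz)
    return _interp_slices(hu, z, z_out), z_out, float(dz)


def reorient_hfs(hu: np.ndarray, meta: Dict[str, object],
                 z_positions_mm: np.ndarray):
    """Reorient to the canonical head-first-supine display order.

    Output slice 0 is the most superior slice (physical z descending with
    index) and in-plane axes follow the standard axial convention
    (patient left on image right, anterior at the top), inferred from the
    direction cosines.  Missing orientation metadata degrades to identity
    with a warning flag rather than failing the study.
    """
    transforms: List[Dict[str, object]] = []
    warnings: List[str] = []
    out = hu
    z = np.asarray(z_positions_mm, dtype=float)
    iop = meta.get("iop")
    if iop is None:
        warnings.append("missing orientation metadata; assuming canonical axes")
    else:
        row = np.asarray(iop[:3], dtype=float)   # direction of increasing column
        col = np.asarray(iop[3:], dtype=float)   # direction of increasing row
        if row[0] < 0:
            out = out[:, :, ::-1]
            transforms.append({"op": "flip", "axis": 2})
        if col[1] < 0:
            out = out[:, ::-1, :]
            transforms.append({"op": "flip", "axis": 1})
    if z[0] < z[-1]:  # ascending (inferior first) -> flip to superior-first
        out = out[::-1]
        z = z[::-1]
        transforms.append({"op": "flip", "axis": 0})
    return np.ascontiguousarray(out), z.copy(), transforms, warnings


def resample_standard(hu: np.ndarray, z_positions_mm: np.ndarray,
                      dz_target: float = STANDARD_DZ_MM):
    """Resample along z to the standard 3 mm slice thickness/spacing.

    In-plane sampling is left native; an input already on the target grid
    passes through untouched.  The z extent is preserved to within one
    slice.
    """
    z = np.asarray(z_positions_mm, dtype=float)
    if len(z) >= 2:
        dz_in = abs(_modal_spacing(z[::-1] if z[0] > z[-1] else z))
        if abs(dz_in - dz_target) < _Z_TOL:
            return hu, z
    descending = z[0] > z[-1]
    z_asc = z[::-1] if descending else z
    hu_asc = hu[::-1] if descending else hu
    n_out = int(np.floor((z_asc[-1] - z_asc[0]) / dz_target + _Z_TOL)) + 1
    z_out = z_asc[0] + dz_target * np.arange(n_out)
    out = _interp_slices(hu_asc, z_asc, z_out)
    if descending:
        out = out[::-1]
        z_out = z_out[::-1]
    return np.ascontiguousarray(out), z_out


def apply_intensity_offset(hu: np.ndarray) -> Tuple[np.ndarray, float]:
    """Shift intensities so the minimum is exactly 0.

    Returns ``(stored, offset)`` with ``stored = hu + offset`` and
    ``offset = -min(hu)``; raw HU is recovered as ``stored - offset``.
    Idempotent: a volume whose minimum is already 0 gets offset 0.
    """
    if not np.all(np.isfinite(hu)):
        raise ValueError("non-finite voxel values")
    offset = float(-hu.min())
    return hu + offset, offset


def normalize_acquisition(files: Sequence[str],
                          dz_target: float = STANDARD_DZ_MM) -> NormalizedVolume:
    """Full normalization chain for one acquisition.

    Fixed composition order: assemble -> regularize -> reorient ->
    resample -> intensity offset, each step logged in provenance.
    """
    hu, meta = assemble_volume(files)
    log: List[Dict[str, object]] = [
        {"op": "assemble", "n_slices": int(hu.shape[0])}]
    z = meta["z_positions_mm"]
    hu, z, dz_in = regularize_slices(hu, z)
    log.append({"op": "regularize", "dz_mm": dz_in, "n_slices": int(hu.shape[0])})
    hu, z, flips, warn = reorient_hfs(hu, meta, z)
    log.append({"op": "reorient", "transforms": flips})
    hu, z = resample_standard(hu, z, dz_target)
    log.append({"op": "resample", "dz_mm": dz_target, "n_slices": int(hu.shape[0])})
    stored, offset = apply_intensity_offset(hu)
    log.append({"op": "intensity_offset", "offset": offset})
    dx, dy = meta["pixel_spacing_mm"]
    return NormalizedVolume(
        voxels=stored,
        spacing_mm=(dx, dy, dz_target),
        intensity_offset=offset,
        orientation_canonical=True,
        provenance={
            "series_uid": meta["series_uid"],
            "z_positions_mm": [float(v) for v in z],
            "transforms": log,
            "warnings": warn,
        },
    )


def map_z_to_slice(z_mm: float, z_positions_mm: np.ndarray) -> int:
    """Nearest slice index for a physical z position."""
    z = np.asarray(z_positions_mm, dtype=float)
    return int(np.argmin(np.abs(z - float(z_mm))))


def transport_slices(mask: np.ndarray, src_z_mm: np.ndarray,
                     dst_z_mm: np.ndarray) -> np.ndarray:
    """Nearest-neighbour transport of a label/mask volume along z.

    Used to carry ground-truth label maps through the same geometric
    transforms as the intensity volume without mixing labels.
    """
    src = np.asarray(src_z_mm, dtype=float)
    idx = [int(np.argmin(np.abs(src - zd))) for zd in np.asarray(dst_z_mm)]
    return mask[idx]
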