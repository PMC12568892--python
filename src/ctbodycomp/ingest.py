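"""Study cataloguing and series selection.

Applies series-level inclusion criteria to a directory of DICOM files
(minimum image count, primary axial acquisition, slice-thickness ceiling,
no dual-energy derived output), disambiguates multi-acquisition series by
axial coverage, selects the preferred series by contrast-phase priority and
thinnest slice, and captures the scan/reconstruction header fields recorded
alongside the biomarkers.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pydicom
from pydicom.errors import InvalidDicomError

__all__ = [
    "SeriesMeta",
    "HeaderRecord",
    "StudyCatalog",
    "EmptyStudyError",
    "scan_study",
    "series_passes_inclusion",
    "select_acquisition",
    "select_preferred_series",
    "capture_header_fields",
    "PHASE_PRIORITY",
    "HEADER_FIELDS",
]

log = logging.getLogger(__name__)

MIN_IMAGES = 30
MAX_SLICE_THICKNESS_MM = 7.5

PHASE_PRIORITY = {
    "non_contrast": 0,
    "portal_venous": 1,
    "delayed": 2,
    "arterial": 3,
    "unknown": 4,
}

#: SeriesDescription keywords marking dual-energy derived series
#: (virtual monochromatic / material-basis reconstructions).
DUAL_ENERGY_KEYWORDS = ("mono", "monoenergetic", "kev", "material", "iodine", "vnc")

#: Captured header fields: record name -> (DICOM keyword, tag string).
HEADER_FIELDS: Dict[str, Tuple[str, str]] = {
    "kvp": ("KVP", "(0018,0060)"),
    "tube_current_ma": ("XRayTubeCurrent", "(0018,1151)"),
    "exposure_mas": ("Exposure", "(0018,1152)"),
    "scan_options": ("ScanOptions", "(0018,0022)"),
    "revolution_time_s": ("RevolutionTime", "(0018,9305)"),
    "spiral_pitch_factor": ("SpiralPitchFactor", "(0018,9311)"),
    "filter_type": ("FilterType", "(0018,1160)"),
    "protocol_name": ("ProtocolName", "(0018,1030)"),
    "body_part_examined": ("BodyPartExamined", "(0018,0015)"),
    "laterality": ("Laterality", "(0020,0060)"),
    "contrast_bolus_agent": ("ContrastBolusAgent", "(0018,0010)"),
    "contrast_bolus_route": ("ContrastBolusRoute", "(0018,1040)"),
    "manufacturer": ("Manufacturer", "(0008,0070)"),
    "manufacturer_model_name": ("ManufacturerModelName", "(0008,1090)"),
    "software_versions": ("SoftwareVersions", "(0018,1020)"),
    "patient_weight_kg": ("PatientWeight", "(0010,1030)"),
    "image_type": ("ImageType", "(0008,0008)"),
    "convolution_kernel": ("ConvolutionKernel", "(0018,1210)"),
    "reconstruction_diameter_mm": ("ReconstructionDiameter", "(0018,1100)"),
    "slice_thickness_mm": ("SliceThickness", "(0018,0050)"),
    "spacing_between_slices_mm": ("SpacingBetweenSlices", "(0018,0088)"),
}


class EmptyStudyError(ValueError):
    """No readable DICOM files in the study directory."""


@dataclass
class SeriesMeta:
    series_uid: str
    series_description: str
    image_count: int
    slice_thickness_mm: Optional[float]
    image_type: Tuple[str, ...]
    acquisition_groups: Dict[int, List[Tuple[str, float]]]
    phase: str
    modality: str
    series_number: Optional[int] = None
    contrast_agent: Optional[str] = None

    def files(self) -> List[str]:
        out: List[str] = []
        for grp in self.acquisition_groups.values():
            out.extend(p for p, _z in grp)
        return out


@dataclass
class HeaderRecord:
    """Captured header fields: name -> value-or-None, with source tags."""

    values: Dict[str, object] = field(default_factory=dict)

    @property
    def tags(self) -> Dict[str, str]:
        return {name: tag for name, (_kw, tag) in HEADER_FIELDS.items()}

    def get(self, name: str):
        return self.values.get(name)

    def to_dict(self) -> Dict[str, Dict[str, object]]:
        return {name: {"value": self.values.get(name), "tag": tag}
                for name, (_kw, tag) in HEADER_FIELDS.items()}


@dataclass
class StudyCatalog:
    series: List[SeriesMeta]
    warnings: List[str] = field(default_factory=list)


def _infer_phase(description: str, contrast_agent: Optional[str]) -> str:
    d = description.lower()
    if "arterial" in d:
        return "arterial"
    if "portal" in d or "pv" in d.split() or "venous" in d:
        return "portal_venous"
    if "delay" in d:
        return "delayed"
    if contrast_agent:
        return "unknown"
    return "non_contrast"


def _modal(values: Sequence[float]) -> Optional[float]:
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    return Counter(vals).most_common(1)[0][0]


def scan_study(directory: str) -> StudyCatalog:
    """Catalogue one study directory into per-series metadata.

    Files are grouped by SeriesInstanceUID; unreadable files are skipped
    with a logged warning.  Raises :class:`EmptyStudyError` when no file
    parses as DICOM.
    """
    per_series: Dict[str, List[Tuple[str, pydicom.Dataset]]] = {}
    warnings: List[str] = []
    paths = sorted(
        os.path.join(root, f)
        for root, _dirs, files in os.walk(directory) for f in files)
    for path in paths:
        try:
            ds = pydicom.dcmread(path, stop_before_pixels=True)
        except (InvalidDicomError, OSError, Exception) as exc:  # noqa: BLE001
            msg = f"skipping unreadable file {os.path.basename(path)}: {exc}"
            warnings.append(msg)
            log.warning(msg)
            continue
        uid = str(getattr(ds, "SeriesInstanceUID", "UNKNOWN"))
        per_series.setdefault(uid, []).append((path, ds))
    if not per_series:
        raise EmptyStudyError(f"empty study: no readable DICOM files in {directory}")

    series: List[SeriesMeta] = []
    for uid, items in sorted(per_series.items()):
        groups: Dict[int, List[Tuple[str, float]]] = {}
        thicknesses: List[Optional[float]] = []
        for path, ds in items:
            acq = getattr(ds, "AcquisitionNumber", None)
            acq = int(acq) if acq is not None else 0
            ipp = getattr(ds, "ImagePositionPatient", None)
            if ipp is not None:
                z = float(ipp[2])
            else:
                z = float(getattr(ds, "SliceLocation", 0.0))
            groups.setdefault(acq, []).append((path, z))
            st = getattr(ds, "SliceThickness", None)
            thicknesses.append(float(st) if st not in (None, "") else None)
        first = items[0][1]
        desc = str(getattr(first, "SeriesDescription", ""))
        agent = getattr(first, "ContrastBolusAgent", None)
        agent = str(agent) if agent not in (None, "") else None
        sn = getattr(first, "SeriesNumber", None)
        series.append(SeriesMeta(
            series_uid=uid,
            series_description=desc,
            image_count=len(items),
            slice_thickness_mm=_modal(thicknesses),
            image_type=tuple(str(t) for t in getattr(first, "ImageType", [])),
            acquisition_groups=groups,
            phase=_infer_phase(desc, agent),
            modality=str(getattr(first, "Modality", "")),
            series_number=int(sn) if sn is not None else None,
            contrast_agent=agent,
        ))
    return StudyCatalog(series=series, warnings=warnings)


def series_passes_inclusion(meta: SeriesMeta) -> Tuple[bool, List[str]]:
    """Series-level inclusion rules.

    A series passes iff it has at least 30 images, is a primary axial
    acquisition (no reformats / secondary captures per ImageType), has a
    slice thickness below 7.5 mm, and its description carries no
    dual-energy derived-output keywords.  Every failed rule is reported.
    """
    reasons: List[str] = []
    if meta.image_count < MIN_IMAGES:
        reasons.append(
            f"image count {meta.image_count} < {MIN_IMAGES}")
    tokens = {t.upper() for t in meta.image_type}
    if "PRIMARY" not in tokens or tokens & {"SECONDARY", "REFORMATTED", "MPR"}:
        reasons.append(
            f"ImageType {list(meta.image_type)} is not a primary axial "
            "acquisition (reformat or secondary capture)")
    if meta.slice_thickness_mm is None:
        reasons.append("missing SliceThickness")
    elif not meta.slice_thickness_mm < MAX_SLICE_THICKNESS_MM:
        reasons.append(
            f"slice thickness {meta.slice_thickness_mm} mm >= "
            f"{MAX_SLICE_THICKNESS_MM} mm")
    d = meta.series_description.lower()
    hits = [kw for kw in DUAL_ENERGY_KEYWORDS if kw in d]
    if hits:
        reasons.append(f"dual-energy derived series (keywords: {hits})")
    return (not reasons), reasons


def select_acquisition(meta: SeriesMeta) -> List[str]:
    """Pick one acquisition group within a series.

    Returns the files of the group with the greatest axial (z) coverage;
    exact ties go to the lowest acquisition number.  Files are returned in
    ascending-z order.
    """
    if not meta.acquisition_groups:
        raise ValueError("series has no acquisition groups")

    def extent(grp: List[Tuple[str, float]]) -> float:
        zs = [z for _p, z in grp]
        return max(zs) - min(zs)

    best = min(meta.acquisition_groups.items(),
               key=lambda kv: (-extent(kv[1]), kv[0]))
    return [p for p, _z in sorted(best[1], key=lambda pz: pz[1])]


def select_preferred_series(catalog: StudyCatalog) -> Optional[SeriesMeta]:
    """Choose the study's preferred series among those passing inclusion.

    Contrast-phase priority is non-contrast > portal venous > delayed >
    arterial (> unknown); within the winning phase the thinnest slice
    thickness wins, and remaining ties go to the lowest series number.
    Returns None when nothing passes.
    """
    passing = [m for m in catalog.series if series_passes_inclusion(m)[0]]
    if not passing:
        return None
    return min(passing, key=lambda m: (
        PHASE_PRIORITY.get(m.phase, len(PHASE_PRIORITY)),
        m.slice_thickness_mm if m.slice_thickness_mm is not None else float("inf"),
        m.series_number if m.series_number is not None else 1 << 30,
        m.series_uid,
    ))


def capture_header_fields(files: Sequence[str]) -> HeaderRecord:
    """Read the recorded header fields from the first file of an acquisition.

    Missing tags yield None, never an error; numeric fields are coerced to
    float, multi-valued fields to a string join.
    """
    if not files:
        raise ValueError("capture_header_fields requires at least one file")
    ds = pydicom.dcmread(files[0], stop_before_pixels=True)
    values: Dict[str, object] = {}
    numeric = {"kvp", "tube_current_ma", "exposure_mas", "revolution_time_s",
               "spiral_pitch_factor", "patient_weight_kg",
               "reconstruction_diameter_mm", "slice_thickness_mm",
               "spacing_between_slices_mm"}
    for name, (kw, _tag) in HEADER_FIELDS.items():
        raw = getattr(ds, kw, None)
        if raw in (None, ""):
            values[name] = None
        elif name in numeric:
            try:
                values[name] = float(raw)
            except (TypeError, ValueError):
                values[name] = None
        elif kw == "ImageType":
            values[name] = "\\".join(str(t) for t in raw)
        else:
            values[name] = str(raw)
    return HeaderRecord(values=values)
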