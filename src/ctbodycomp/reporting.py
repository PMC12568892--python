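"""Standards-based outputs and pipeline orchestration.

Assembles the structured biomarker report (measurements, captured header
fields, landmark summary, QA flags, provenance), renders quality-assurance
rasters (axial segmentation overlays and a coronal maximum-intensity
projection), exports them as DICOM secondary-capture objects tied to the
source study, and drives the whole ingest -> normalize -> landmark ->
segment -> measure -> validate -> report chain.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pydicom
from PIL import Image, ImageDraw
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid
from skimage.segmentation import find_boundaries

from . import __version__
from .biomarkers import Measurement, measure_study
from .ingest import (EmptyStudyError, capture_header_fields, scan_study,
                     select_acquisition, select_preferred_series,
                     series_passes_inclusion)
from .landmarks import (LandmarkSet, TruthLandmarkProvider, get_provider,
                        locate_landmarks)
from .normalize import NormalizedVolume, normalize_acquisition
from .phantom import load_truth_sidecar
from .segmentation import LabelMap, segment
from .validation import check_all, detect_contrast, load_range_limits, summarize_failures

__all__ = [
    "build_report",
    "render_qa_overlay",
    "render_coronal_mip",
    "coronal_mip",
    "label_boundaries",
    "write_dicom_sc",
    "run_pipeline",
    "PipelineResult",
    "OVERLAY_COLORS",
]

log = logging.getLogger(__name__)

#: Per-label contour colors (RGB) for QA overlays.
OVERLAY_COLORS: Dict[str, Tuple[int, int, int]] = {
    "vat": (255, 215, 0), "sat": (0, 200, 255), "muscle": (255, 0, 0),
    "plaque": (255, 255, 255), "trabecular": (200, 0, 255),
    "liver": (0, 255, 0), "spleen": (255, 128, 0),
    "kidney_left": (0, 128, 255), "kidney_right": (0, 0, 255),
    "pancreas": (255, 0, 128), "aorta": (255, 80, 80),
}

SOFT_TISSUE_WINDOW = (400.0, 40.0)   # (width, level)
BONE_WINDOW = (1500.0, 300.0)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _config_hash(config: Optional[dict]) -> str:
    payload = json.dumps(_json_safe(config or {}), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_report(*, selected_series_uid: Optional[str],
                 selection_audit: List[dict],
                 header: Optional[dict],
                 landmarks: Optional[LandmarkSet],
                 measurements: Sequence[Measurement],
                 contrast: Optional[dict],
                 failure_summary: dict,
                 provenance: Optional[dict],
                 config: Optional[dict] = None,
                 status: str = "complete",
                 status_detail: Optional[str] = None) -> dict:
    """Assemble the study report as a JSON-serializable mapping.

    Field order is fixed; all attempted measurements appear, absent ones
    with their reasons in flags.  Two runs over the same input and config
    yield byte-identical serialized JSON.
    """
    lm = None
    if landmarks is not None:
        lm = {
            "provider_id": landmarks.provider_id,
            "positions": dict(sorted(landmarks.positions.items())),
            "confidence": {k: landmarks.confidence.get(k)
                           for k in sorted(landmarks.positions)},
        }
    report = {
        "toolkit": {"name": "ctbodycomp", "version": __version__,
                    "config_hash": _config_hash(config)},
        "status": status,
        "status_detail": status_detail,
        "selected_series_uid": selected_series_uid,
        "selection_audit": selection_audit,
        "header": header,
        "landmarks": lm,
        "contrast": contrast,
        "measurements": [m.to_dict() for m in measurements],
        "failure_summary": failure_summary,
        "provenance": provenance,
    }
    return _json_safe(report)


def _window(raw: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    width, level = window
    lo = level - width / 2.0
    img = np.clip((raw - lo) / width, 0.0, 1.0)
    return (img * 255.0 + 0.5).astype(np.uint8)


def label_boundaries(mask: np.ndarray) -> np.ndarray:
    """Inner boundary pixels of a 2-D mask (the drawn contour set)."""
    return find_boundaries(mask, mode="inner")


def render_qa_overlay(volume: NormalizedVolume, label_map: LabelMap,
                      slice_index: int,
                      window: Tuple[float, float] = SOFT_TISSUE_WINDOW,
                      annotations: Sequence[str] = ()) -> Image.Image:
    """Axial QA overlay: windowed slice + colored label contours + legend."""
    nz = volume.shape[0]
    if not (0 <= slice_index < nz):
        raise IndexError(f"slice {slice_index} outside volume depth {nz}")
    gray = _window(volume.raw_hu()[slice_index], window)
    rgb = np.stack([gray] * 3, axis=-1)
    present = []
    for name in label_map.present_labels():
        m = label_map.mask(name)[slice_index]
        if not m.any():
            continue
        color = OVERLAY_COLORS.get(name, (255, 255, 0))
        rgb[label_boundaries(m)] = color
        present.append(name)
    img = Image.fromarray(rgb)
    draw = ImageDraw.Draw(img)
    y = 2
    for name in present:
        draw.text((2, y), name, fill=OVERLAY_COLORS.get(name, (255, 255, 0)))
        y += 10
    for text in annotations:
        draw.text((2, y), text, fill=(255, 255, 255))
        y += 10
    return img


def coronal_mip(volume: NormalizedVolume) -> np.ndarray:
    """Raw-HU maximum projection along the anterior-posterior axis."""
    return volume.raw_hu().max(axis=1)


def render_coronal_mip(volume: NormalizedVolume,
                       window: Tuple[float, float] = BONE_WINDOW) -> Image.Image:
    """Bone-windowed coronal MIP, aspect-corrected by voxel spacing."""
    mip = _window(coronal_mip(volume), window)
    img = Image.fromarray(mip)
    dx, _dy, dz = volume.spacing_mm
    scale = dz / dx
    if abs(scale - 1.0) > 1e-6:
        img = img.resize((img.width, max(1, int(round(img.height * scale)))),
                         Image.NEAREST)
    return img


def write_dicom_sc(images: Sequence[Image.Image], source_file: str,
                   out_dir: str, series_number: int = 900) -> List[str]:
    """Wrap QA rasters as DICOM secondary-capture objects.

    The SC series shares StudyInstanceUID and patient module with the
    source study (so PACS files them together) under a new series UID;
    pixel data round-trips exactly (8-bit RGB).
    """
    src = pydicom.dcmread(source_file, stop_before_pixels=True)
    study_uid = getattr(src, "StudyInstanceUID", None)
    if not study_uid:
        raise ValueError("source study lacks StudyInstanceUID")
    os.makedirs(out_dir, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=[str(study_uid), "ctbodycomp-sc",
                                            str(series_number)])
    paths: List[str] = []
    for i, img in enumerate(images):
        arr = np.asarray(img.convert("RGB"), dtype=np.uint8)
        ds = Dataset()
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = generate_uid(
            entropy_srcs=[str(series_uid), str(i)])
        ds.Modality = "OT"
        ds.ConversionType = "WSD"
        ds.StudyInstanceUID = study_uid
        for kw in ("PatientName", "PatientID", "StudyDescription",
                   "AccessionNumber", "StudyDate", "StudyTime"):
            if hasattr(src, kw):
                setattr(ds, kw, getattr(src, kw))
        ds.SeriesInstanceUID = series_uid
        ds.SeriesNumber = series_number
        ds.SeriesDescription = "ctbodycomp QA"
        ds.InstanceNumber = i + 1
        ds.SamplesPerPixel = 3
        ds.PhotometricInterpretation = "RGB"
        ds.PlanarConfiguration = 0
        ds.Rows, ds.Columns = arr.shape[:2]
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        ds.PixelData = arr.tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        path = os.path.join(out_dir, f"qa_sc_{i:03d}.dcm")
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineResult:
    status: int                       # 0 ok; 1 input/config error;
    report: dict                      # 3 no eligible series; 4 anatomy absent
    report_path: Optional[str] = None
    artifacts: List[str] = field(default_factory=list)


_DEFAULT_TARGETS = ("vat", "sat", "muscle", "plaque", "trabecular", "aorta",
                    "liver", "spleen", "kidney_left", "kidney_right",
                    "pancreas")


def run_pipeline(input_dir: str, out_dir: str,
                 config: Optional[dict] = None) -> PipelineResult:
    """End-to-end study processing.

    Config keys (all optional): ``backend`` (``threshold``/``truth``),
    ``landmark_provider`` (``truth``/``heuristic_spine``), ``truth_json``
    (phantom truth sidecar; auto-discovered inside ``input_dir``),
    ``range_overrides``, ``targets``, ``qa`` (bool), ``dicom_sc`` (bool).
    Gate failures produce a structured early-exit report rather than an
    exception; genuinely unreadable input or a bad config returns status 1.
    """
    config = dict(config or {})
    os.makedirs(out_dir, exist_ok=True)
    timings: Dict[str, float] = {}

    def _emit(status_int, status, detail, audit, **kw):
        report = build_report(
            selected_series_uid=kw.get("series_uid"),
            selection_audit=audit,
            header=kw.get("header"),
            landmarks=kw.get("landmarks"),
            measurements=kw.get("measurements", []),
            contrast=kw.get("contrast"),
            failure_summary=kw.get("summary", {"flag_counts": {},
                                               "flags_by_biomarker": {},
                                               "any_tool_failed": status_int != 0}),
            provenance=kw.get("provenance"),
            config=config, status=status, status_detail=detail)
        path = os.path.join(out_dir, "report.json")
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2)
            fh.write("\n")
        return PipelineResult(status_int, report, path,
                              kw.get("artifacts", []))

    try:
        limits = load_range_limits(config.get("range_overrides"))
    except (KeyError, ValueError) as exc:
        log.error("bad configuration: %s", exc)
        return PipelineResult(1, {"status": "error",
                                  "status_detail": f"bad config: {exc}"})

    t0 = time.perf_counter()
    try:
        catalog = scan_study(input_dir)
    except (EmptyStudyError, OSError) as exc:
        log.error("%s", exc)
        return PipelineResult(1, {"status": "error", "status_detail": str(exc)})
    timings["ingest"] = time.perf_counter() - t0

    audit = []
    for meta in catalog.series:
        ok, reasons = series_passes_inclusion(meta)
        audit.append({"series_uid": meta.series_uid,
                      "description": meta.series_description,
                      "phase": meta.phase,
                      "slice_thickness_mm": meta.slice_thickness_mm,
                      "image_count": meta.image_count,
                      "passes": ok, "rejection_reasons": reasons})
    selected = select_preferred_series(catalog)
    if selected is None:
        return _emit(3, "no_eligible_series",
                     "no series passed the inclusion rules", audit)
    files = select_acquisition(selected)
    header = capture_header_fields(files)

    t0 = time.perf_counter()
    volume = normalize_acquisition(files)
    timings["normalize"] = time.perf_counter() - t0

    truth = None
    truth_json = config.get("truth_json")
    if truth_json is None:
        cand = os.path.join(input_dir, "phantom_truth.json")
        truth_json = cand if os.path.exists(cand) else None
    if truth_json:
        truth = load_truth_sidecar(truth_json)

    t0 = time.perf_counter()
    provider_id = config.get("landmark_provider",
                             "truth" if truth is not None else "heuristic_spine")
    if provider_id == "truth":
        if truth is None:
            return PipelineResult(1, {
                "status": "error",
                "status_detail": "truth landmark provider requires a truth sidecar"})
        provider = TruthLandmarkProvider(truth)
    else:
        provider = get_provider(provider_id)
    landmark_set = locate_landmarks(volume, provider)
    timings["landmarks"] = time.perf_counter() - t0
    if not landmark_set.positions:
        return _emit(4, "anatomy_absent",
                     "no vertebral landmarks detected in the volume", audit,
                     series_uid=selected.series_uid, header=header.to_dict(),
                     provenance=volume.provenance)

    backend = config.get("backend", "truth" if truth is not None else "threshold")
    targets = tuple(config.get("targets", _DEFAULT_TARGETS))
    if backend == "threshold":
        targets = tuple(t for t in targets
                        if t in {"vat", "sat", "muscle", "plaque",
                                 "trabecular", "aorta"})
    aorta_mask = None
    if truth is not None and "aorta" in truth.masks:
        from .segmentation import truth_backend
        aorta_mask = truth_backend(volume, truth, ["aorta"])["aorta"]
    t0 = time.perf_counter()
    label_map = segment(volume, backend, targets, landmarks=landmark_set,
                        aorta_mask=aorta_mask, truth=truth)
    timings["segmentation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    measurements = measure_study(volume, label_map, landmark_set,
                                 aorta_mask=aorta_mask)
    measurements = check_all(measurements, limits)
    contrast = detect_contrast(
        volume, aorta_mask if aorta_mask is not None else label_map.mask("aorta"),
        header)
    summary = summarize_failures(measurements, contrast.get("flags", []))
    timings["measurement"] = time.perf_counter() - t0

    artifacts: List[str] = []
    if config.get("qa", True):
        t0 = time.perf_counter()
        level = landmark_set.get("L3")
        sl = level if level is not None else volume.shape[0] // 2
        overlay = render_qa_overlay(volume, label_map, sl)
        mip = render_coronal_mip(volume)
        p1 = os.path.join(out_dir, "qa_overlay_L3.png")
        p2 = os.path.join(out_dir, "qa_coronal_mip.png")
        overlay.save(p1)
        mip.save(p2)
        artifacts += [p1, p2]
        if config.get("dicom_sc", False):
            artifacts += write_dicom_sc([overlay, mip], files[0],
                                        os.path.join(out_dir, "sc"))
        timings["qa"] = time.perf_counter() - t0
    for stage, dt in timings.items():
        log.info("stage %-12s %.3f s", stage, dt)

    return _emit(0, "complete", None, audit,
                 series_uid=selected.series_uid, header=header.to_dict(),
                 landmarks=landmark_set, measurements=measurements,
                 contrast=contrast, summary=summary,
                 provenance=volume.provenance, artifacts=artifacts)
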