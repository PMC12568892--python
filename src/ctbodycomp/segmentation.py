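"""Pluggable tissue segmentation producing label maps.

Two backends ship with the toolkit: a rules-based threshold/morphology
backend (HU windows + per-slice morphology) covering adipose tissue
(VAT/SAT), body-wall muscle, aortic calcium, and the vertebral trabecular
ROI; and a ground-truth backend that transports phantom masks through the
same geometric transforms as the intensity volume.  Deep-learning models
can be registered as additional backends without changing consumers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .landmarks import LandmarkSet
from .normalize import NormalizedVolume, transport_slices
from .phantom import PhantomTruth

__all__ = [
    "LabelMap",
    "LABEL_IDS",
    "AortaPrerequisiteError",
    "UnsupportedTargetError",
    "segment",
    "threshold_fat_backend",
    "threshold_calcium_backend",
    "trabecular_roi_backend",
    "truth_backend",
    "register_backend",
    "registered_backends",
    "FAT_HU_RANGE",
    "MUSCLE_HU_RANGE",
    "CALCIUM_HU_MIN",
    "CORTICAL_HU_MIN",
]

log = logging.getLogger(__name__)

#: Literature-standard HU windows (config-overridable at call sites).
FAT_HU_RANGE = (-190.0, -30.0)
MUSCLE_HU_RANGE = (-29.0, 150.0)
BODY_HU_MIN = -500.0
CALCIUM_HU_MIN = 130.0
CORTICAL_HU_MIN = 400.0
TRABECULAR_BONE_HU_MIN = 200.0

LABEL_IDS: Dict[str, int] = {
    "background": 0, "vat": 1, "sat": 2, "muscle": 3, "plaque": 4,
    "trabecular": 5, "liver": 6, "spleen": 7, "kidney_left": 8,
    "kidney_right": 9, "pancreas": 10, "aorta": 11,
}

#: Merge precedence, painted low-to-high (later overwrites earlier).
_PAINT_ORDER = ("vat", "sat", "muscle", "liver", "spleen", "kidney_left",
                "kidney_right", "pancreas", "aorta", "trabecular", "plaque")

#: 26-connectivity in 3-D (8-connectivity in-slice): per-slice Agatston
#: areas depend on how lesions merge, so the choice is explicit.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class AortaPrerequisiteError(ValueError):
    """Calcium segmentation needs an aorta mask (truth or plugged model)."""


class UnsupportedTargetError(ValueError):
    pass


@dataclass
class LabelMap:
    labels: np.ndarray                 # int16, aligned to the source volume
    dictionary: Dict[int, str]
    backend_id: str
    warnings: List[str] = field(default_factory=list)

    def mask(self, name: str) -> np.ndarray:
        ids = [i for i, n in self.dictionary.items() if n == name]
        if not ids:
            return np.zeros(self.labels.shape, dtype=bool)
        return np.isin(self.labels, ids)

    def present_labels(self) -> List[str]:
        vals = np.unique(self.labels)
        return [self.dictionary[int(v)] for v in vals if int(v) != 0]


# ---------------------------------------------------------------------------
# rules backends

def _body_mask(raw: np.ndarray) -> np.ndarray:
    """Largest connected component above the air threshold."""
    cand = raw > BODY_HU_MIN
    lbl, n = ndimage.label(cand)
    if n == 0:
        return cand
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, range(1, n + 1))
    return lbl == (int(np.argmax(sizes)) + 1)


def threshold_fat_backend(volume: NormalizedVolume,
                          fat_range: Tuple[float, float] = FAT_HU_RANGE,
                          muscle_range: Tuple[float, float] = MUSCLE_HU_RANGE):
    """Threshold/morphology segmentation of VAT, SAT and body-wall muscle.

    Fat voxels are those in ``fat_range`` inside the body (largest
    component above -500 HU).  Per slice, muscle-range voxels are
    morphologically closed; the component enclosing a large cavity is the
    abdominal wall ring, which partitions fat into SAT (outside) and VAT
    (inside the cavity).  The closing also absorbs small intramuscular fat
    pockets into the muscle mask, so muscle area includes intramuscular
    adipose tissue.  Slices where no closed ring is found get their fat
    labelled SAT and are flagged.

    Returns ``(vat, sat, muscle, warnings)``.
    """
    raw = volume.raw_hu()
    body = _body_mask(raw)
    fat = (raw >= fat_range[0]) & (raw <= fat_range[1]) & body
    vat = np.zeros(raw.shape, dtype=bool)
    sat = np.zeros(raw.shape, dtype=bool)
    muscle = np.zeros(raw.shape, dtype=bool)
    warnings: List[str] = []
    selem = disk(2)
    for s in range(raw.shape[0]):
        m = (raw[s] >= muscle_range[0]) & (raw[s] <= muscle_range[1]) & body[s]
        ring = np.zeros(m.shape, dtype=bool)
        cavity = np.zeros(m.shape, dtype=bool)
        lbl, n = ndimage.label(m)
        for c in range(1, n + 1):
            comp = ndimage.binary_closing(lbl == c, structure=selem)
            filled = ndimage.binary_fill_holes(comp)
            hole = filled & ~comp
            if hole.sum() > 0.5 * comp.sum():
                ring |= comp
                cavity |= hole
        if not ring.any() and fat[s].any():
            warnings.append(
                f"slice {s}: no closed muscle ring; fat labelled SAT")
            sat[s] = fat[s]
            continue
        muscle[s] = ring
        vat[s] = fat[s] & cavity
        sat[s] = fat[s] & ~cavity & ~ring
    return vat, sat, muscle, warnings


def threshold_calcium_backend(volume: NormalizedVolume,
                              aorta_mask: Optional[np.ndarray],
                              hu_min: float = CALCIUM_HU_MIN):
    """Aortic calcified plaque: raw HU >= 130 within the dilated aorta.

    The aorta mask (from the truth backend or a plugged vessel model) is
    dilated by one voxel so mural plaque at the vessel boundary is kept;
    components are labelled with 26-connectivity.  Returns ``(mask,
    component_labels, n_components)``.
    """
    if aorta_mask is None:
        raise AortaPrerequisiteError(
            "aorta prerequisite: calcium segmentation requires an aorta mask")
    if aorta_mask.shape != volume.shape:
        raise ValueError("aorta mask shape mismatch")
    raw = volume.raw_hu()
    region = ndimage.binary_dilation(aorta_mask, structure=_STRUCT_26)
    plaque = (raw >= hu_min) & region
    comp, n = ndimage.label(plaque, structure=_STRUCT_26)
    return plaque, comp, int(n)


def trabecular_roi_backend(volume: NormalizedVolume, landmarks: LandmarkSet,
                           level: str,
                           cortical_min: float = CORTICAL_HU_MIN):
    """Elliptical trabecular ROI at a vertebral landmark slice.

    At the landmark slice the dominant bone component (raw HU >= 200) is
    located; an ellipse centred on its centroid, scaled to 60% of the
    component's equivalent radius, is eroded and stripped of
    cortical-range voxels (raw HU >= 400) so only trabecular bone remains.
    Returns a volume-shaped mask (empty with a warning when no bone is
    found at the slice).
    """
    idx = landmarks.get(level)
    if idx is None:
        raise KeyError(f"landmark {level} absent")
    raw = volume.raw_hu()
    sl = raw[idx]
    bone = sl >= TRABECULAR_BONE_HU_MIN
    out = np.zeros(raw.shape, dtype=bool)
    lbl, n = ndimage.label(bone)
    if n == 0:
        log.warning("no bone component at %s slice %d", level, idx)
        return out, [f"no bone component at {level} slice {idx}"]
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, range(1, n + 1))
    comp = lbl == (int(np.argmax(sizes)) + 1)
    cy, cx = ndimage.center_of_mass(comp)
    r_eq = np.sqrt(comp.sum() / np.pi)
    yy, xx = np.mgrid[0:sl.shape[0], 0:sl.shape[1]]
    r = 0.6 * r_eq
    roi = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r
    roi &= sl < cortical_min
    roi = ndimage.binary_erosion(roi)
    out[idx] = roi
    return out, []


def truth_backend(volume: NormalizedVolume, truth: PhantomTruth,
                  targets: Sequence[str]) -> Dict[str, np.ndarray]:
    """Ground-truth masks transported onto the normalized grid.

    Transport is nearest-neighbour along z (label-preserving), matching
    the geometric transforms applied to the intensity volume.  Raises on
    in-plane shape mismatch.
    """
    out: Dict[str, np.ndarray] = {}
    dst_z = volume.z_positions_mm
    for name in targets:
        if name not in truth.masks:
            raise KeyError(f"truth has no mask for {name!r}")
        m = transport_slices(truth.masks[name], truth.z_positions_mm, dst_z)
        if m.shape != volume.shape:
            raise ValueError(
                f"mask {name!r} shape {m.shape} does not match volume "
                f"{volume.shape} after transport")
        out[name] = m
    return out


# ---------------------------------------------------------------------------
# dispatch

_TRABECULAR_LEVELS = ("T10", "T12", "L1", "L3")


def _run_threshold(volume, targets, landmarks, aorta_mask, warnings):
    masks: Dict[str, np.ndarray] = {}
    fat_targets = {"vat", "sat", "muscle"} & set(targets)
    if fat_targets:
        vat, sat, muscle, w = threshold_fat_backend(volume)
        warnings.extend(w)
        produced = {"vat": vat, "sat": sat, "muscle": muscle}
        masks.update({k: produced[k] for k in fat_targets})
    if "plaque" in targets:
        plaque, _comp, _n = threshold_calcium_backend(volume, aorta_mask)
        masks["plaque"] = plaque
    if "aorta" in targets and aorta_mask is not None:
        masks["aorta"] = aorta_mask
    if "trabecular" in targets:
        if landmarks is None:
            raise ValueError("trabecular target requires landmarks")
        combined = np.zeros(volume.shape, dtype=bool)
        for lev in _TRABECULAR_LEVELS:
            if landmarks.get(lev) is None:
                continue
            roi, w = trabecular_roi_backend(volume, landmarks, lev)
            warnings.extend(w)
            combined |= roi
        masks["trabecular"] = combined
    unsupported = (set(targets) - set(masks)
                   - {"aorta"})  # aorta without a mask handled above
    organy = unsupported & {"liver", "spleen", "kidney_left", "kidney_right",
                            "pancreas"}
    if organy:
        raise UnsupportedTargetError(
            f"threshold backend has no organ model for {sorted(organy)}; "
            "use the 'truth' backend or register a model backend")
    return masks


def segment(volume: NormalizedVolume, backend_id: str,
            targets: Sequence[str], *,
            landmarks: Optional[LandmarkSet] = None,
            aorta_mask: Optional[np.ndarray] = None,
            truth: Optional[PhantomTruth] = None) -> LabelMap:
    """Dispatch to a registered backend and merge per-target masks.

    Overlapping claims are resolved by a documented precedence (plaque >
    trabecular > organs > muscle > vat/sat) and logged.  Unknown targets
    or backends raise with the list of valid choices.
    """
    unknown = set(targets) - set(LABEL_IDS)
    if unknown:
        raise UnsupportedTargetError(
            f"unknown targets {sorted(unknown)}; valid: {sorted(LABEL_IDS)}")
    warnings: List[str] = []
    if backend_id == "truth":
        if truth is None:
            raise ValueError("truth backend requires phantom truth")
        masks = truth_backend(volume, truth, targets)
    elif backend_id == "threshold":
        masks = _run_threshold(volume, targets, landmarks, aorta_mask, warnings)
    elif backend_id in _BACKENDS:
        masks = _BACKENDS[backend_id](volume, targets, landmarks=landmarks,
                                      aorta_mask=aorta_mask, truth=truth)
    else:
        raise KeyError(
            f"unknown backend {backend_id!r}; registered: "
            f"{registered_backends()}")

    labels = np.zeros(volume.shape, dtype=np.int16)
    overlap = 0
    for name in _PAINT_ORDER:
        if name not in masks:
            continue
        m = masks[name]
        overlap += int((m & (labels != 0)).sum())
        labels[m] = LABEL_IDS[name]
    if overlap:
        msg = f"{overlap} voxels claimed by multiple targets; resolved by precedence"
        warnings.append(msg)
        log.info(msg)
    dictionary = {LABEL_IDS[n]: n for n in masks}
    dictionary[0] = "background"
    return LabelMap(labels=labels, dictionary=dictionary,
                    backend_id=backend_id, warnings=warnings)


_BACKENDS: Dict[str, object] = {}


def register_backend(backend_id: str, fn) -> None:
    """Register an external segmentation backend (e.g. a model adapter).

    The callable receives ``(volume, targets, *, landmarks, aorta_mask,
    truth)`` and returns a dict of boolean masks keyed by target name.
    """
    _BACKENDS[backend_id] = fn


def registered_backends() -> List[str]:
    return sorted({"truth", "threshold", *_BACKENDS})
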