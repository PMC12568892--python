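"""Slice-level anatomical landmarks.

Provides vertebral-body center landmarks (T10-T12, L1-L5) and the aortic
hiatus / bifurcation through a pluggable provider interface.  A trained
slice-score regression model can be plugged in as a provider; shipped here
are a rule-based spine landmarker (bone thresholding + disc-gap detection)
and a ground-truth provider backed by the synthetic phantom.

Canonical slice order is superior-first: a landmark cranial to another has
the smaller slice index.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .normalize import NormalizedVolume, map_z_to_slice
from .phantom import PhantomTruth, VERTEBRAL_LEVELS

__all__ = [
    "LandmarkSet",
    "InconsistentLandmarksError",
    "MissingLandmarkError",
    "locate_landmarks",
    "heuristic_spine_landmarker",
    "TruthLandmarkProvider",
    "abdominal_aorta_extent",
    "register_provider",
    "get_provider",
    "write_landmarks_csv",
    "read_landmarks_csv",
    "LANDMARK_ORDER",
]

log = logging.getLogger(__name__)

#: Cranial-to-caudal landmark order used by the validation invariants.
LANDMARK_ORDER = ("T10", "T11", "T12", "L1", "L2", "L3", "L4", "L5")

BONE_HU = 200.0


class InconsistentLandmarksError(ValueError):
    """Provider output violates the cranial-to-caudal ordering."""


class MissingLandmarkError(KeyError):
    """A required landmark is absent."""


@dataclass
class LandmarkSet:
    positions: Dict[str, int] = field(default_factory=dict)
    provider_id: str = ""
    confidence: Dict[str, Optional[float]] = field(default_factory=dict)

    def get(self, name: str) -> Optional[int]:
        return self.positions.get(name)

    def validate(self, nz: Optional[int] = None) -> None:
        present = [(n, self.positions[n]) for n in LANDMARK_ORDER
                   if n in self.positions]
        for (na, ia), (nb, ib) in zip(present, present[1:]):
            if not ia < ib:
                raise InconsistentLandmarksError(
                    f"inconsistent landmarks: {na} (slice {ia}) must be "
                    f"cranial to {nb} (slice {ib})")
        hi = self.positions.get("aortic_hiatus")
        bi = self.positions.get("aortic_bifurcation")
        if hi is not None and bi is not None and not hi < bi:
            raise InconsistentLandmarksError(
                f"inconsistent landmarks: aortic_hiatus (slice {hi}) must "
                f"be cranial to aortic_bifurcation (slice {bi})")
        if nz is not None:
            for n, i in self.positions.items():
                if not (0 <= i < nz):
                    raise InconsistentLandmarksError(
                        f"landmark {n} slice {i} outside [0, {nz})")


Provider = Callable[[NormalizedVolume], LandmarkSet]
_PROVIDERS: Dict[str, Provider] = {}


def register_provider(provider_id: str, fn: Provider) -> None:
    _PROVIDERS[provider_id] = fn


def get_provider(provider_id: str) -> Provider:
    try:
        return _PROVIDERS[provider_id]
    except KeyError:
        raise KeyError(
            f"unknown landmark provider {provider_id!r}; registered: "
            f"{sorted(_PROVIDERS)}") from None


def locate_landmarks(volume: NormalizedVolume, provider: Provider) -> LandmarkSet:
    """Run a provider and enforce the LandmarkSet invariants.

    Missing landmarks are allowed (recorded as absent); ordering
    violations raise :class:`InconsistentLandmarksError` naming the pair.
    """
    ls = provider(volume)
    ls.validate(nz=volume.shape[0])
    return ls


def heuristic_spine_landmarker(volume: NormalizedVolume) -> LandmarkSet:
    """Rule-based vertebral landmarker.

    Thresholds bone (raw HU >= 200), keeps the dominant posterior-central
    column component, reads the per-slice bone-area profile, treats area
    minima as intervertebral disc gaps, and labels vertebral bodies
    counting cranially from the most caudal detected body (assumed L5).
    Landmark = center slice of each body, ties rounding caudally.  The
    aortic landmarks are left to dedicated providers.
    """
    raw = volume.raw_hu()
    bone = raw >= BONE_HU
    if bone.any():
        # bridge intervertebral gaps with a z-only dilation so the column is
        # one component, then keep it and discard off-column bone/calcium
        struct = np.zeros((7, 3, 3), dtype=bool)
        struct[:, 1, 1] = True
        column = ndimage.binary_dilation(bone, structure=struct)
        lbl, n = ndimage.label(column)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, range(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            bone &= lbl == keep
    area = bone.reshape(bone.shape[0], -1).sum(axis=1).astype(float)
    ls = LandmarkSet(provider_id="heuristic_spine")
    if area.max() <= 0:
        log.warning("no bone-range voxels; all landmarks absent")
        return ls
    # disc gaps: slices whose bone area drops well below the profile peak
    in_body = area > 0.2 * area.max()
    runs: List[Tuple[int, int]] = []
    start = None
    for i, v in enumerate(in_body):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(in_body) - 1))
    if len(runs) < 2:
        log.warning("fewer than 2 vertebral bodies detected; landmarks absent")
        return ls
    runs = runs[-len(VERTEBRAL_LEVELS):]  # at most 8 most-caudal bodies
    levels = VERTEBRAL_LEVELS[-len(runs):]  # most caudal body -> L5
    for lev, (s, e) in zip(levels, runs):
        ls.positions[lev] = (s + e + 1) // 2  # caudal-rounded center
        ls.confidence[lev] = None
    return ls


@dataclass
class TruthLandmarkProvider:
    """Ground-truth provider for phantom studies.

    Re-expresses the phantom's landmark z positions on the normalized
    volume's slice grid, so truth stays exact under reorientation and
    resampling.
    """

    truth: PhantomTruth
    provider_id: str = "truth"

    def __call__(self, volume: NormalizedVolume) -> LandmarkSet:
        dst_z = volume.z_positions_mm
        ls = LandmarkSet(provider_id=self.provider_id)
        for name, idx in self.truth.landmarks.items():
            z = float(self.truth.z_positions_mm[idx])
            ls.positions[name] = map_z_to_slice(z, dst_z)
            ls.confidence[name] = 1.0
        return ls


def abdominal_aorta_extent(landmarks: LandmarkSet) -> Tuple[int, int]:
    """Inclusive slice interval of the abdominal aortic compartment,
    from the diaphragmatic (aortic) hiatus to the aortic bifurcation."""
    hi = landmarks.get("aortic_hiatus")
    bi = landmarks.get("aortic_bifurcation")
    if hi is None or bi is None:
        missing = [n for n, v in (("aortic_hiatus", hi),
                                  ("aortic_bifurcation", bi)) if v is None]
        raise MissingLandmarkError(
            f"abdominal compartment undefined: missing {missing}")
    return int(hi), int(bi)


def write_landmarks_csv(ls: LandmarkSet, path: str) -> str:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "slice", "confidence"])
        for name in list(LANDMARK_ORDER) + ["aortic_hiatus", "aortic_bifurcation"]:
            if name in ls.positions:
                w.writerow([name, ls.positions[name],
                            ls.confidence.get(name, "")])
    return path


def read_landmarks_csv(path: str, provider_id: str = "csv") -> LandmarkSet:
    ls = LandmarkSet(provider_id=provider_id)
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ls.positions[row["name"]] = int(row["slice"])
            conf = row.get("confidence") or ""
            ls.confidence[row["name"]] = float(conf) if conf else None
    return ls


register_provider("heuristic_spine", heuristic_spine_landmarker)
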