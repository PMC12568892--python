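"""Body-composition biomarker measurement.

Computes the toolkit's measurement battery from a label map: slice-wise
aortic Agatston scores (abdominal compartment and entire visible aorta),
cross-sectional areas at vertebral landmark levels, organ volumes, HU
statistics (median density as the primary attenuation metric), and the
visceral-to-subcutaneous area ratio (VSR).

The Agatston score is the slice-wise weighted sum of segmented calcium:
``sum over slices of plaque_area_slice x density_factor_slice``, where the
density factor is 1 for a per-slice peak attenuation of 130-199 HU, 2 for
200-299, 3 for 300-399, and 4 at or above 400; below the 130 HU
calcification threshold a slice contributes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .landmarks import LandmarkSet, MissingLandmarkError, abdominal_aorta_extent
from .normalize import NormalizedVolume
from .segmentation import LabelMap

__all__ = [
    "PlaqueSliceStat",
    "Measurement",
    "density_factor",
    "agatston_score",
    "abdominal_and_total_agatston",
    "cross_sectional_area",
    "volume_ml",
    "hu_stats",
    "vsr",
    "measure_study",
    "TABLE_NAMES",
]

CALCIFICATION_THRESHOLD_HU = 130.0

#: Canonical biomarker keys -> report display names.
TABLE_NAMES: Dict[str, str] = {
    "muscle_csa": "Muscle Cross-Sectional Area",
    "muscle_density": "Muscle Median Density (attenuation)",
    "abdominal_agatston": "Abdominal Agatston",
    "total_agatston": "Total Aortic Agatston",
    "trabecular_density": "Vertebral Trabecular Bone Median Density (attenuation)",
    "vat_csa": "Visceral Adipose Tissue Cross-Sectional Area",
    "sat_csa": "Subcutaneous Adipose Tissue Cross-Sectional Area",
    "total_fat_csa": "Total Adipose Tissue Cross-Sectional Area",
    "vsr": "Visceral to Subcutaneous Cross Sectional Area Ratio (VSR)",
    "vat_density": "Visceral Adipose Tissue Median Density",
    "sat_density": "Subcutaneous Adipose Tissue Median Density",
    "liver_density": "Liver Median Density (attenuation)",
    "liver_volume": "Liver Volume",
    "spleen_density": "Spleen Median Density (attenuation)",
    "spleen_volume": "Spleen Volume",
    "kidney_density": "Kidney Median Density (attenuation)",
    "kidney_volume": "Kidney Volume",
    "pancreas_density": "Pancreas Median Density (attenuation)",
    "pancreas_volume": "Pancreas Volume",
}


@dataclass(frozen=True)
class PlaqueSliceStat:
    slice_index: int
    area_mm2: float
    peak_hu: float
    density_factor: int


@dataclass
class Measurement:
    name: str                       # canonical biomarker key
    value: Optional[float]
    units: str                      # cm2 | HU | mL | unitless
    level: str                      # landmark name, "volume", or "compartment"
    flags: List[str] = field(default_factory=list)

    @property
    def display_name(self) -> str:
        return TABLE_NAMES.get(self.name, self.name)

    def to_dict(self) -> Dict[str, object]:
        return {"biomarker_name": self.display_name, "key": self.name,
                "level": self.level, "value": self.value,
                "units": self.units, "flags": list(self.flags)}


def density_factor(peak_hu: float) -> int:
    """Agatston density factor for a slice's peak plaque attenuation.

    Integer weight: 0 below the 130 HU calcification threshold, then 1
    (130-199 HU), 2 (200-299), 3 (300-399), 4 (>= 400).  Real-valued
    inputs use the half-open bins [130, 200), [200, 300), [300, 400),
    [400, inf).
    """
    if not np.isfinite(peak_hu):
        raise ValueError("peak_hu must be finite")
    if peak_hu < 130.0:
        return 0
    if peak_hu < 200.0:
        return 1
    if peak_hu < 300.0:
        return 2
    if peak_hu < 400.0:
        return 3
    return 4


def agatston_score(plaque_mask: np.ndarray, volume: NormalizedVolume,
                   slices: Optional[Iterable[int]] = None,
                   ) -> Tuple[float, List[PlaqueSliceStat]]:
    """Slice-wise weighted Agatston sum over a plaque mask.

    Per slice: plaque area (pixel count x in-plane pixel area, mm^2)
    multiplied by the density factor of that slice's peak raw HU; slices
    without plaque contribute 0.  Returns the score and the per-slice
    statistics that produced it.
    """
    if plaque_mask.shape != volume.shape:
        raise ValueError(
            f"plaque mask shape {plaque_mask.shape} does not match volume "
            f"{volume.shape}")
    raw = volume.raw_hu()
    pixel_area = volume.pixel_area_mm2()
    if slices is None:
        slices = range(plaque_mask.shape[0])
    score = 0.0
    stats: List[PlaqueSliceStat] = []
    for s in slices:
        m = plaque_mask[s]
        count = int(m.sum())
        if count == 0:
            continue
        peak = float(raw[s][m].max())
        f = density_factor(peak)
        area = count * pixel_area
        score += area * f
        stats.append(PlaqueSliceStat(int(s), area, peak, f))
    return score, stats


def abdominal_and_total_agatston(plaque_mask: np.ndarray,
                                 volume: NormalizedVolume,
                                 landmarks: LandmarkSet,
                                 aorta_mask: Optional[np.ndarray] = None):
    """Agatston over the abdominal compartment and the entire visible aorta.

    The total score covers every slice where the aorta (or plaque) is
    visible; the abdominal score covers the hiatus-to-bifurcation
    interval.  Missing aortic landmarks leave the abdominal score absent
    with a ``partial_anatomy`` flag.  Returns ``(abdominal, total,
    flags)`` with ``abdominal <= total`` whenever both are defined.
    """
    if aorta_mask is not None:
        visible = np.flatnonzero(
            aorta_mask.reshape(aorta_mask.shape[0], -1).any(axis=1)
            | plaque_mask.reshape(plaque_mask.shape[0], -1).any(axis=1))
        total, _ = agatston_score(plaque_mask, volume, visible.tolist())
    else:
        total, _ = agatston_score(plaque_mask, volume)
    flags: List[str] = []
    try:
        lo, hi = abdominal_aorta_extent(landmarks)
    except MissingLandmarkError:
        return None, total, ["partial_anatomy"]
    nz = plaque_mask.shape[0]
    abdominal, _ = agatston_score(
        plaque_mask, volume, range(max(lo, 0), min(hi, nz - 1) + 1))
    return abdominal, total, flags


def cross_sectional_area(label_map: LabelMap, name: str, slice_index: int,
                         volume: NormalizedVolume) -> float:
    """Cross-sectional area of a label at one slice, in cm^2."""
    nz = label_map.labels.shape[0]
    if not (0 <= slice_index < nz):
        raise IndexError(f"slice {slice_index} outside volume depth {nz}")
    count = int(label_map.mask(name)[slice_index].sum())
    return count * volume.pixel_area_mm2() / 100.0


def volume_ml(label_map: LabelMap, name: str,
              volume: NormalizedVolume) -> float:
    """Volume of a label in mL (voxel count x voxel volume)."""
    if name not in label_map.dictionary.values():
        raise KeyError(
            f"unknown label {name!r}; present: {sorted(set(label_map.dictionary.values()))}")
    count = int(label_map.mask(name).sum())
    return count * volume.voxel_volume_mm3() / 1000.0


def hu_stats(volume: NormalizedVolume, mask: np.ndarray):
    """(mean, median, sd) of raw HU over a mask; (None,)*3 when empty.

    Statistics are computed on the offset-inverted (raw HU) scale, so
    they are invariant to the stored intensity offset.
    """
    vals = volume.raw_hu()[mask]
    if vals.size == 0:
        return None, None, None
    return float(vals.mean()), float(np.median(vals)), float(vals.std())


def vsr(vat_area: float, sat_area: float) -> Optional[float]:
    """Visceral-to-subcutaneous cross-sectional area ratio (unitless)."""
    if sat_area <= 0:
        return None
    return vat_area / sat_area


# ---------------------------------------------------------------------------
# full measurement battery

_FAT_MUSCLE_LEVELS = ("L1", "L3")
_TRABECULAR_LEVELS = ("T10", "T12", "L1", "L3")
_ORGANS = ("liver", "spleen", "pancreas")


def _slice_median(volume, label_map, name, s) -> Tuple[Optional[float], Optional[float]]:
    m = label_map.mask(name)[s]
    vals = volume.raw_hu()[s][m]
    if vals.size == 0:
        return None, None
    return float(np.median(vals)), float(vals.size)


def measure_study(volume: NormalizedVolume, label_map: LabelMap,
                  landmarks: LandmarkSet,
                  aorta_mask: Optional[np.ndarray] = None,
                  ) -> List[Measurement]:
    """Compute the full biomarker battery.

    Level-based measurements missing their landmark are emitted with a
    null value and a ``partial_anatomy`` flag; empty masks yield null
    values with an ``empty_mask`` flag rather than an error.  Slice-level
    segmentation warnings propagate as ``slice_warning``.
    """
    out: List[Measurement] = []
    present = set(label_map.dictionary.values())
    slice_warn = any(w.startswith("slice") for w in label_map.warnings)

    def add(name, value, units, level, flags=()):
        m = Measurement(name, value, units, level, list(flags))
        if value is None and "partial_anatomy" not in m.flags \
                and "empty_mask" not in m.flags:
            m.flags.append("empty_mask")
        out.append(m)

    # fat / muscle at L1, L3
    for level in _FAT_MUSCLE_LEVELS:
        s = landmarks.get(level)
        if s is None:
            for key, units in (("muscle_csa", "cm2"), ("muscle_density", "HU"),
                               ("vat_csa", "cm2"), ("sat_csa", "cm2"),
                               ("total_fat_csa", "cm2"), ("vsr", "unitless"),
                               ("vat_density", "HU"), ("sat_density", "HU")):
                add(key, None, units, level, ["partial_anatomy"])
            continue
        flags = ["slice_warning"] if slice_warn else []
        areas = {}
        for tissue, key in (("muscle", "muscle_csa"), ("vat", "vat_csa"),
                            ("sat", "sat_csa")):
            if tissue in present:
                a = cross_sectional_area(label_map, tissue, s, volume)
                areas[tissue] = a
                add(key, a, "cm2", level, flags)
                med, n = _slice_median(volume, label_map, tissue, s)
                dkey = {"muscle": "muscle_density", "vat": "vat_density",
                        "sat": "sat_density"}[tissue]
                add(dkey, med, "HU", level, flags)
        if "vat" in areas and "sat" in areas:
            add("total_fat_csa", areas["vat"] + areas["sat"], "cm2", level, flags)
            r = vsr(areas["vat"], areas["sat"])
            add("vsr", r, "unitless", level,
                flags + (["empty_mask"] if r is None else []))

    # trabecular bone medians
    if "trabecular" in present:
        for level in _TRABECULAR_LEVELS:
            s = landmarks.get(level)
            if s is None:
                add("trabecular_density", None, "HU", level, ["partial_anatomy"])
                continue
            med, _n = _slice_median(volume, label_map, "trabecular", s)
            add("trabecular_density", med, "HU", level)

    # organ volumes + densities
    organ_names = list(_ORGANS) + ["kidney_left", "kidney_right"]
    for organ in organ_names:
        if organ not in present:
            continue
        if organ.startswith("kidney"):
            key_base, level = "kidney", organ.split("_")[1]
        else:
            key_base, level = organ, "volume"
        v = volume_ml(label_map, organ, volume)
        add(f"{key_base}_volume", v if v > 0 else None, "mL", level,
            [] if v > 0 else ["empty_mask"])
        _mean, med, _sd = hu_stats(volume, label_map.mask(organ))
        add(f"{key_base}_density", med, "HU", level)

    # Agatston scores
    if "plaque" in present:
        plaque = label_map.mask("plaque")
        if aorta_mask is None and "aorta" in present:
            aorta_mask = label_map.mask("aorta")
        abdominal, total, aflags = abdominal_and_total_agatston(
            plaque, volume, landmarks, aorta_mask)
        add("total_agatston", total, "unitless", "compartment")
        add("abdominal_agatston", abdominal, "unitless", "compartment", aflags)
    return out
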