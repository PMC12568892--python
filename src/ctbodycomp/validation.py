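"""Quality assurance: physiological range checks and contrast detection.

Every biomarker has a usable range — values outside it indicate that no
valid segmentation could have produced them.  Out-of-range measurements
are flagged (``range_fail``) but never censored, so downstream consumers
see both the value and its status.  A simple enhancement check on the
aortic blood pool classifies intravenous contrast as present/absent and
is cross-checked against the DICOM contrast tags.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import yaml

from .biomarkers import Measurement
from .ingest import HeaderRecord
from .normalize import NormalizedVolume

__all__ = [
    "RangeLimit",
    "load_range_limits",
    "check_measurement",
    "check_all",
    "detect_contrast",
    "summarize_failures",
    "CONTRAST_PRESENT_HU",
    "CONTRAST_ABSENT_HU",
]

#: Aortic blood-pool mean HU thresholds for the contrast check
#: (config-overridable defaults).
CONTRAST_PRESENT_HU = 140.0
CONTRAST_ABSENT_HU = 90.0


@dataclass(frozen=True)
class RangeLimit:
    biomarker_name: str
    low: float
    high: float
    units: str

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(
                f"range for {self.biomarker_name!r}: low {self.low} must be "
                f"< high {self.high}")


def load_range_limits(overrides: Optional[Mapping[str, Mapping[str, float]]] = None,
                      ) -> Dict[str, RangeLimit]:
    """Load the default usable ranges, optionally overridden by name.

    Overrides may replace ``low`` and/or ``high`` for a known biomarker;
    unknown names or inverted bounds are rejected.
    """
    text = resources.files("ctbodycomp").joinpath("ranges.yaml").read_text()
    raw = yaml.safe_load(text)
    limits = {name: RangeLimit(name, float(v["low"]), float(v["high"]),
                               str(v["units"]))
              for name, v in raw.items()}
    if overrides:
        for name, ov in overrides.items():
            if name not in limits:
                raise KeyError(
                    f"unknown biomarker {name!r} in range override; valid "
                    f"names: {sorted(limits)}")
            base = limits[name]
            limits[name] = RangeLimit(
                name,
                float(ov.get("low", base.low)),
                float(ov.get("high", base.high)),
                str(ov.get("units", base.units)),
            )
    return limits


def check_measurement(m: Measurement,
                      limits: Mapping[str, RangeLimit]) -> Measurement:
    """Flag a measurement outside its usable range (inclusive bounds).

    The value is never mutated; the check is idempotent.  A biomarker
    without a defined limit passes with a ``limit_missing`` note.
    """
    limit = limits.get(m.name)
    if limit is None:
        if "limit_missing" not in m.flags:
            m.flags.append("limit_missing")
        return m
    if m.value is None:
        return m
    if not (limit.low <= m.value <= limit.high):
        if "range_fail" not in m.flags:
            m.flags.append("range_fail")
    return m


def check_all(measurements: Iterable[Measurement],
              limits: Mapping[str, RangeLimit]) -> List[Measurement]:
    return [check_measurement(m, limits) for m in measurements]


def detect_contrast(volume: NormalizedVolume,
                    aorta_mask: Optional[np.ndarray],
                    header: Optional[HeaderRecord] = None,
                    present_hu: float = CONTRAST_PRESENT_HU,
                    absent_hu: float = CONTRAST_ABSENT_HU) -> Dict[str, object]:
    """Classify intravenous contrast from aortic blood-pool enhancement.

    Mean raw HU over the aorta mask >= ``present_hu`` reads as contrast
    present, <= ``absent_hu`` as absent, in between (or with no usable
    mask) as indeterminate.  When DICOM contrast tags disagree with the
    image-based call, a ``contrast_mismatch`` flag is raised.
    """
    result: Dict[str, object] = {"status": "indeterminate",
                                 "mean_aorta_hu": None, "flags": []}
    if aorta_mask is not None and aorta_mask.any():
        mean = float(volume.raw_hu()[aorta_mask].mean())
        result["mean_aorta_hu"] = mean
        if mean >= present_hu:
            result["status"] = "present"
        elif mean <= absent_hu:
            result["status"] = "absent"
    if header is not None and result["status"] != "indeterminate":
        tagged = header.get("contrast_bolus_agent") is not None
        if tagged != (result["status"] == "present"):
            result["flags"].append("contrast_mismatch")
    return result


def summarize_failures(measurements: Iterable[Measurement],
                       extra_flags: Iterable[str] = ()) -> Dict[str, object]:
    """Aggregate flags across the report.

    Returns per-flag counts, the affected biomarkers per flag, and an
    ``any_tool_failed`` boolean (true when any range_fail or missing
    measurement is present).
    """
    counts: Dict[str, int] = {}
    by_biomarker: Dict[str, Dict[str, int]] = {}
    for m in measurements:
        for f in m.flags:
            counts[f] = counts.get(f, 0) + 1
            by_biomarker.setdefault(f, {})
            by_biomarker[f][m.name] = by_biomarker[f].get(m.name, 0) + 1
    for f in extra_flags:
        counts[f] = counts.get(f, 0) + 1
    failure_flags = {"range_fail", "partial_anatomy", "empty_mask",
                     "contrast_mismatch"}
    return {
        "flag_counts": counts,
        "flags_by_biomarker": by_biomarker,
        "any_tool_failed": any(f in failure_flags for f in counts),
    }
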