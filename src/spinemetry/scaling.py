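"""Cross-modality scaling: the common scaling factor (CSF).

X-ray measurements live in pixels; ultrasound measurements in
millimeters.  A single global conversion constant, the common scaling
factor in cm/px, links the two.  It is derived once from matched
anatomical landmarks of a reference volunteer: for each axis the
per-pair ratios (ultrasound cm) / (X-ray px) are averaged
arithmetically, and the horizontal and vertical axis ratios are then
combined by their geometric mean,

    CSF = sqrt(r_H * r_V)   [cm/px].

The geometric mean integrates the horizontal and vertical adjustments
into one isotropic factor; when both axes agree (r_H == r_V == r) the
CSF is exactly r.  The study pipeline applies one CSF uniformly across
all volunteers, regions and metrics; the reproduction default is
``DEFAULT_CSF_CM_PER_PX`` = 0.518 cm/px, shipped as a configuration
constant because the reference volunteer's landmark values are not part
of the public record.  Lengths convert as px * CSF (cm) and areas as
px^2 * CSF^2 (cm^2); reporting re-expresses them in mm and mm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from io import StringIO
from pathlib import Path
from typing import Iterable

import pandas as pd

from .annotation import Region
from .errors import InsufficientLandmarksError
from .geometry import BaseMeasurementSet

__all__ = [
    "Axis",
    "MatchedLandmark",
    "ScalingFactor",
    "DEFAULT_CSF_CM_PER_PX",
    "derive_csf",
    "to_physical_length",
    "to_physical_area",
    "PhysicalBaseSet",
    "convert_base_set",
    "read_matched_landmarks_csv",
]

#: The study's configured conversion constant, cm per X-ray pixel.
DEFAULT_CSF_CM_PER_PX = 0.518


class Axis(str, Enum):
    HORIZONTAL = "HORIZONTAL"
    VERTICAL = "VERTICAL"


@dataclass(frozen=True)
class MatchedLandmark:
    """One anatomical distance measured in both modalities along one axis."""

    ultrasound_mm: float
    xray_px: float
    axis: Axis

    def __post_init__(self):
        if self.ultrasound_mm <= 0 or self.xray_px <= 0:
            raise ValueError("matched-landmark distances must be > 0")

    @property
    def ratio_cm_per_px(self) -> float:
        return (self.ultrasound_mm / 10.0) / self.xray_px


@dataclass(frozen=True)
class ScalingFactor:
    """A validated cm-per-pixel conversion constant."""

    csf_cm_per_px: float

    def __post_init__(self):
        if not (math.isfinite(self.csf_cm_per_px) and self.csf_cm_per_px > 0):
            raise ValueError("scaling factor must be finite and > 0")


def derive_csf(pairs: Iterable[MatchedLandmark]) -> ScalingFactor:
    """Derive the CSF from matched landmark pairs (>= 1 per axis required)."""
    by_axis: dict[Axis, list[float]] = {Axis.HORIZONTAL: [], Axis.VERTICAL: []}
    for pair in pairs:
        by_axis[pair.axis].append(pair.ratio_cm_per_px)
    missing = [axis.value for axis, ratios in by_axis.items() if not ratios]
    if missing:
        raise InsufficientLandmarksError(
            f"need at least one matched landmark per axis; missing {', '.join(missing)}"
        )
    r_h = sum(by_axis[Axis.HORIZONTAL]) / len(by_axis[Axis.HORIZONTAL])
    r_v = sum(by_axis[Axis.VERTICAL]) / len(by_axis[Axis.VERTICAL])
    return ScalingFactor(csf_cm_per_px=math.sqrt(r_h * r_v))


def to_physical_length(length_px: float, csf: ScalingFactor) -> float:
    """Convert a pixel length to centimeters."""
    if length_px <= 0:
        raise ValueError("length must be > 0")
    return length_px * csf.csf_cm_per_px


def to_physical_area(area_px2: float, csf: ScalingFactor) -> float:
    """Convert a pixel area to square centimeters."""
    if area_px2 <= 0:
        raise ValueError("area must be > 0")
    return area_px2 * csf.csf_cm_per_px**2


@dataclass(frozen=True)
class PhysicalBaseSet:
    """The five baseline metrics in physical units (cm / cm^2).

    ``*_mm`` accessors re-express values in mm / mm^2 for table output.
    """

    volunteer_id: str
    region: Region
    area_cm2: float
    height_cm: float
    width_cm: float
    pdh_cm: float
    adh_cm: float

    @property
    def area_mm2(self) -> float:
        return self.area_cm2 * 100.0

    @property
    def height_mm(self) -> float:
        return self.height_cm * 10.0

    @property
    def width_mm(self) -> float:
        return self.width_cm * 10.0

    @property
    def pdh_mm(self) -> float:
        return self.pdh_cm * 10.0

    @property
    def adh_mm(self) -> float:
        return self.adh_cm * 10.0


def convert_base_set(base: BaseMeasurementSet, csf: ScalingFactor) -> PhysicalBaseSet:
    """Convert a pixel-space baseline set into physical units via the CSF."""
    return PhysicalBaseSet(
        volunteer_id=base.volunteer_id,
        region=base.region,
        area_cm2=to_physical_area(base.area_px2, csf),
        height_cm=to_physical_length(base.height_px, csf),
        width_cm=to_physical_length(base.width_px, csf),
        pdh_cm=to_physical_length(base.pdh_px, csf),
        adh_cm=to_physical_length(base.adh_px, csf),
    )


def read_matched_landmarks_csv(source: str | Path | StringIO) -> list[MatchedLandmark]:
    """Read matched landmarks from CSV columns: axis, ultrasound_mm, xray_px."""
    frame = pd.read_csv(source)
    required = {"axis", "ultrasound_mm", "xray_px"}
    if not required.issubset(frame.columns):
        raise ValueError(f"matched-landmark CSV needs columns {sorted(required)}")
    return [
        MatchedLandmark(
            ultrasound_mm=float(row.ultrasound_mm),
            xray_px=float(row.xray_px),
            axis=Axis(str(row.axis).upper()),
        )
        for row in frame.itertuples()
    ]
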