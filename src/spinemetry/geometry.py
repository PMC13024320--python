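"""Pixel-space geometric measurements from annotation coordinates.

The five X-ray baseline metrics per lumbar region are:

* ``area_px2``   -- enclosed area of the IVF boundary polygon, by the
  shoelace formula |sum_i (x_i * y_{i+1} - x_{i+1} * y_i)| / 2;
* ``width_px``/``height_px`` -- axis-aligned bounding-box extents of the
  IVF polygon (the measurement convention for foramen width and height);
* ``pdh_px``/``adh_px`` -- Euclidean distances between the posterior
  (resp. anterior) disc tip landmark pairs.

Ultrasound interspinous distances are pixel distances scaled by the
per-image ``ultrasound_mm_per_px`` calibration into millimeters.

All results are convention-invariant: the shoelace value is taken in
absolute value so tracing direction does not matter, and every quantity
is unchanged under translation of the image origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .annotation import AnnotationDocument, Label, Modality, Phase, PolygonAnnotation, Point2D, Region
from .errors import DegenerateGeometryError, IncompleteAnnotationError

__all__ = [
    "BaseMeasurementSet",
    "UltrasoundMeasurement",
    "polygon_area",
    "point_distance",
    "polygon_extents",
    "measure_xray_base",
    "measure_ultrasound",
]

# Relative tolerance below which a shoelace area or an extent is treated
# as degenerate.  Double precision leaves ~1e-16 relative error per term;
# 1e-12 of the bounding-box scale is far above rounding noise for the
# < 1e3-vertex polygons produced by manual annotation.
_DEGENERATE_REL = 1e-12


@dataclass(frozen=True)
class BaseMeasurementSet:
    """The five X-ray baseline metrics for one volunteer x region, in pixels."""

    volunteer_id: str
    region: Region
    area_px2: float
    height_px: float
    width_px: float
    pdh_px: float
    adh_px: float


@dataclass(frozen=True)
class UltrasoundMeasurement:
    """One calibrated interspinous distance at a phase x load condition."""

    volunteer_id: str
    region: Region
    phase: Phase
    load_kg: float
    distance_mm: float


def polygon_area(poly: PolygonAnnotation) -> float:
    """Enclosed area of a simple polygon in px^2 (shoelace formula).

    Independent of tracing direction and of which vertex starts the ring.
    Raises :class:`DegenerateGeometryError` for collinear/zero-area input.
    """
    coords = poly.coords()
    acc = 0.0
    n = len(coords)
    for i in range(n):
        x0, y0 = coords[i]
        x1, y1 = coords[(i + 1) % n]
        acc += x0 * y1 - x1 * y0
    area = abs(acc) / 2.0
    width, height = _raw_extents(coords)
    scale = max(width * height, 1.0)
    if area <= _DEGENERATE_REL * scale:
        raise DegenerateGeometryError(
            f"polygon {poly.label.value}/{poly.region.value} has zero area"
        )
    return area


def point_distance(p: Point2D, q: Point2D) -> float:
    """Euclidean distance between two landmark points, in pixels."""
    if p == q:
        raise DegenerateGeometryError("landmark points coincide")
    return math.hypot(p.x - q.x, p.y - q.y)


def _raw_extents(coords: list[tuple[float, float]]) -> tuple[float, float]:
    xs = [c[0] for c in coords]
    ys = [c[1] for c in coords]
    return max(xs) - min(xs), max(ys) - min(ys)


def polygon_extents(poly: PolygonAnnotation) -> tuple[float, float]:
    """(width_px, height_px): axis-aligned bounding-box extents of the polygon."""
    width, height = _raw_extents(poly.coords())
    scale = max(abs(v) for xy in poly.coords() for v in xy)
    tol = _DEGENERATE_REL * max(scale, 1.0)
    if width <= tol or height <= tol:
        raise DegenerateGeometryError(
            f"polygon {poly.label.value}/{poly.region.value} collapses onto an axis"
        )
    return width, height


def measure_xray_base(doc: AnnotationDocument, region: Region) -> BaseMeasurementSet:
    """Extract the five baseline metrics for one region of an X-ray document."""
    if doc.meta.modality is not Modality.XRAY:
        raise IncompleteAnnotationError("baseline measurement requires an X-ray document")
    poly = doc.find_polygon(Label.IVF, region)
    if poly is None:
        raise IncompleteAnnotationError(
            f"missing IVF polygon for region {region.value} "
            f"(volunteer {doc.meta.volunteer_id})"
        )
    missing = [
        label.value
        for label in (Label.PDH, Label.ADH)
        if doc.find_landmarks(label, region) is None
    ]
    if missing:
        raise IncompleteAnnotationError(
            f"missing {'/'.join(missing)} landmarks for region {region.value} "
            f"(volunteer {doc.meta.volunteer_id})"
        )
    pdh = doc.find_landmarks(Label.PDH, region)
    adh = doc.find_landmarks(Label.ADH, region)
    assert pdh is not None and adh is not None
    width, height = polygon_extents(poly)
    return BaseMeasurementSet(
        volunteer_id=doc.meta.volunteer_id,
        region=region,
        area_px2=polygon_area(poly),
        height_px=height,
        width_px=width,
        pdh_px=point_distance(pdh.p, pdh.q),
        adh_px=point_distance(adh.p, adh.q),
    )


def measure_ultrasound(doc: AnnotationDocument, region: Region) -> UltrasoundMeasurement:
    """Calibrated interspinous distance (mm) for one region of an ultrasound document."""
    if doc.meta.modality is not Modality.ULTRASOUND:
        raise IncompleteAnnotationError("interspinous measurement requires an ultrasound document")
    pair = doc.find_landmarks(Label.INTERSPINOUS, region)
    if pair is None:
        raise IncompleteAnnotationError(
            f"missing INTERSPINOUS landmarks for region {region.value} "
            f"(volunteer {doc.meta.volunteer_id}, phase {doc.meta.phase.value}, "
            f"load {doc.meta.load_kg} kg)"
        )
    mm_per_px = doc.meta.ultrasound_mm_per_px
    assert mm_per_px is not None and doc.meta.load_kg is not None
    return UltrasoundMeasurement(
        volunteer_id=doc.meta.volunteer_id,
        region=region,
        phase=doc.meta.phase,
        load_kg=doc.meta.load_kg,
        distance_mm=point_distance(pair.p, pair.q) * mm_per_px,
    )
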