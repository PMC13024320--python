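"""Annotation-document I/O: schema, validation, round-trip serialization.

A document describes one image: provenance metadata plus the labeled
geometry drawn on it.  X-ray documents carry the intervertebral-foramen
(IVF) boundary polygon and the posterior/anterior disc-height landmark
pairs; ultrasound documents carry the interspinous landmark pair.  The
on-disk format is a single UTF-8 JSON object::

    {
      "meta": {
        "volunteer_id": "V01",
        "modality": "XRAY" | "ULTRASOUND",
        "phase": "PRE" | "DURING",
        "load_kg": 1.8 | 3.6 | 5.4 | 11.3 | null,
        "ultrasound_mm_per_px": <float> | null
      },
      "polygons":  [{"label": "IVF", "region": "L3L4", "vertices": [[x, y], ...]}],
      "landmarks": [{"label": "PDH", "region": "L3L4", "p": [x, y], "q": [x, y]}]
    }

Coordinates are 0-based pixel positions with y increasing downward
(raster convention).  X-ray images are acquired pre-procedure only, so
X-ray metadata always has ``phase = PRE`` and no load.  Traction loads
may be given in kg {1.8, 3.6, 5.4, 11.3} or as their lb equivalents
{4, 8, 12, 25}; lb values are normalized to kg on input.

A duplicated closing vertex (first == last) is dropped on input, since
both open and closed polygon dialects exist among annotation tools.
"""

from __future__ import annotations

import json
import math
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pydantic
from pydantic import BaseModel, ConfigDict, model_serializer, model_validator
from shapely.geometry import LineString

from .errors import AnnotationParseError, AnnotationValidationError, CohortConflictError

__all__ = [
    "Modality",
    "Phase",
    "Region",
    "Label",
    "LOADS_KG",
    "LB_TO_KG",
    "normalize_load",
    "Point2D",
    "PolygonAnnotation",
    "LandmarkPair",
    "ImageMeta",
    "AnnotationDocument",
    "parse_annotation_document",
    "write_annotation_document",
    "load_annotation_document",
    "save_annotation_document",
    "CohortIndex",
    "collect_cohort",
]


class Modality(str, Enum):
    XRAY = "XRAY"
    ULTRASOUND = "ULTRASOUND"


class Phase(str, Enum):
    PRE = "PRE"
    DURING = "DURING"


class Region(str, Enum):
    L3L4 = "L3L4"
    L4L5 = "L4L5"
    L5S1 = "L5S1"

    @property
    def display(self) -> str:
        return {"L3L4": "L3-L4", "L4L5": "L4-L5", "L5S1": "L5-S1"}[self.value]


class Label(str, Enum):
    IVF = "IVF"
    PDH = "PDH"
    ADH = "ADH"
    INTERSPINOUS = "INTERSPINOUS"


#: Graded traction loads of the study protocol, in kg.
LOADS_KG: tuple[float, ...] = (1.8, 3.6, 5.4, 11.3)

#: Accepted lb aliases, normalized to kg on input.
LB_TO_KG: dict[float, float] = {4.0: 1.8, 8.0: 3.6, 12.0: 5.4, 25.0: 11.3}

_XRAY_LABELS = {Label.IVF, Label.PDH, Label.ADH}
_US_LABELS = {Label.INTERSPINOUS}


def normalize_load(value: float) -> float:
    """Map a load given in kg or lb onto the canonical kg grid."""
    for lb, kg in LB_TO_KG.items():
        if math.isclose(value, lb, abs_tol=1e-6):
            return kg
    for kg in LOADS_KG:
        if math.isclose(value, kg, abs_tol=1e-6):
            return kg
    raise ValueError(
        f"load {value!r} is not one of {LOADS_KG} kg (or lb aliases {sorted(LB_TO_KG)})"
    )


class Point2D(BaseModel):
    """Image-plane coordinate in pixels (x rightward, y downward)."""

    model_config = ConfigDict(frozen=True)

    x: float
    y: float

    @model_validator(mode="before")
    @classmethod
    def _coerce_pair(cls, data):
        if isinstance(data, (list, tuple)):
            if len(data) != 2:
                raise ValueError("a point must be a [x, y] pair")
            return {"x": data[0], "y": data[1]}
        return data

    @model_validator(mode="after")
    def _finite(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("coordinates must be finite")
        return self

    @model_serializer
    def _as_pair(self) -> list[float]:
        return [self.x, self.y]

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


class PolygonAnnotation(BaseModel):
    """A closed region traced on the image, stored as an open vertex ring."""

    model_config = ConfigDict(frozen=True)

    label: Label
    region: Region
    vertices: tuple[Point2D, ...]

    @pydantic.field_validator("vertices", mode="after")
    @classmethod
    def _check_vertices(cls, verts: tuple[Point2D, ...]) -> tuple[Point2D, ...]:
        verts = list(verts)
        if len(verts) >= 4 and verts[0] == verts[-1]:
            verts = verts[:-1]  # drop duplicated closing vertex
        if len(verts) < 3:
            raise ValueError("a polygon needs at least 3 distinct vertices")
        n = len(verts)
        for i in range(n):
            if verts[i] == verts[(i + 1) % n]:
                raise ValueError(f"consecutive vertices {i} and {(i + 1) % n} coincide")
        return tuple(verts)

    @model_validator(mode="after")
    def _check_label(self):
        if self.label is not Label.IVF:
            raise ValueError(f"polygon label must be IVF, got {self.label.value}")
        return self

    def coords(self) -> list[tuple[float, float]]:
        return [v.as_tuple() for v in self.vertices]

    def is_simple(self) -> bool:
        """True iff the closed boundary does not self-intersect."""
        ring = self.coords()
        return LineString(ring + ring[:1]).is_simple


class LandmarkPair(BaseModel):
    """Two anatomical tip points whose separation is the measurement."""

    model_config = ConfigDict(frozen=True)

    label: Label
    region: Region
    p: Point2D
    q: Point2D

    @model_validator(mode="after")
    def _check(self):
        if self.label is Label.IVF:
            raise ValueError("IVF is a polygon label, not a landmark label")
        if self.p == self.q:
            raise ValueError("landmark points must be distinct")
        return self


class ImageMeta(BaseModel):
    """Provenance of one image: who, which modality, which condition."""

    model_config = ConfigDict(frozen=True)

    volunteer_id: str
    modality: Modality
    phase: Phase = Phase.PRE
    load_kg: float | None = None
    ultrasound_mm_per_px: float | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.modality is Modality.XRAY:
            if self.phase is not Phase.PRE:
                raise ValueError("X-ray imaging is pre-procedure only")
            if self.load_kg is not None:
                raise ValueError("X-ray documents carry no traction load")
            if self.ultrasound_mm_per_px is not None:
                raise ValueError("ultrasound_mm_per_px is an ultrasound-only field")
        else:
            if self.load_kg is None:
                raise ValueError("ultrasound documents require a traction load")
            object.__setattr__(self, "load_kg", normalize_load(self.load_kg))
            if self.ultrasound_mm_per_px is None or self.ultrasound_mm_per_px <= 0:
                raise ValueError("ultrasound_mm_per_px must be present and > 0")
        return self


class AnnotationDocument(BaseModel):
    """One image's metadata plus all geometry annotated on it."""

    model_config = ConfigDict(frozen=True)

    meta: ImageMeta
    polygons: tuple[PolygonAnnotation, ...] = ()
    landmarks: tuple[LandmarkPair, ...] = ()

    @model_validator(mode="after")
    def _check(self):
        allowed = _XRAY_LABELS if self.meta.modality is Modality.XRAY else _US_LABELS
        seen: set[tuple[Label, Region]] = set()
        for i, poly in enumerate(self.polygons):
            if poly.label not in allowed:
                raise ValueError(
                    f"polygons[{i}]: label {poly.label.value} not allowed for "
                    f"{self.meta.modality.value} documents"
                )
            key = (poly.label, poly.region)
            if key in seen:
                raise ValueError(f"polygons[{i}]: duplicate {poly.label.value}/{poly.region.value}")
            seen.add(key)
        for i, lm in enumerate(self.landmarks):
            if lm.label not in allowed:
                raise ValueError(
                    f"landmarks[{i}]: label {lm.label.value} not allowed for "
                    f"{self.meta.modality.value} documents"
                )
            key = (lm.label, lm.region)
            if key in seen:
                raise ValueError(f"landmarks[{i}]: duplicate {lm.label.value}/{lm.region.value}")
            seen.add(key)
        return self

    def find_polygon(self, label: Label, region: Region) -> PolygonAnnotation | None:
        for poly in self.polygons:
            if poly.label is label and poly.region is region:
                return poly
        return None

    def find_landmarks(self, label: Label, region: Region) -> LandmarkPair | None:
        for lm in self.landmarks:
            if lm.label is label and lm.region is region:
                return lm
        return None


def _loc_to_path(loc: tuple) -> str:
    parts: list[str] = []
    for item in loc:
        if isinstance(item, int):
            parts.append(f"[{item}]")
        else:
            if parts:
                parts.append(".")
            parts.append(str(item))
    return "".join(parts)


def parse_annotation_document(text: str) -> AnnotationDocument:
    """Parse and fully validate one serialized annotation document.

    Raises :class:`AnnotationParseError` for malformed JSON (naming the
    byte offset) and :class:`AnnotationValidationError` for schema or
    invariant violations (naming the offending path).  Polygons are
    additionally checked for simplicity: a self-intersecting boundary
    has no well-defined enclosed area.
    """
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(str(exc), offset=exc.pos) from exc
    try:
        doc = AnnotationDocument.model_validate(data)
    except pydantic.ValidationError as exc:
        err = exc.errors()[0]
        raise AnnotationValidationError(err["msg"], path=_loc_to_path(err["loc"])) from exc
    for i, poly in enumerate(doc.polygons):
        if not poly.is_simple():
            raise AnnotationValidationError(
                "polygon boundary self-intersects", path=f"polygons[{i}].vertices"
            )
    return doc


def write_annotation_document(doc: AnnotationDocument) -> str:
    """Serialize a document to canonical JSON (sorted keys, 2-space indent).

    The output is deterministic so re-serialization is byte-identical, and
    ``parse_annotation_document(write_annotation_document(doc)) == doc``.
    """
    payload = doc.model_dump(mode="json")
    return json.dumps(payload, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def load_annotation_document(path: str | Path) -> AnnotationDocument:
    return parse_annotation_document(Path(path).read_text(encoding="utf-8"))


def save_annotation_document(doc: AnnotationDocument, path: str | Path) -> None:
    Path(path).write_text(write_annotation_document(doc), encoding="utf-8")


#: Index key: (volunteer_id, modality, phase, load_kg).  A document spans
#: all lumbar regions of its image, so region is resolved within a document.
CohortKey = tuple[str, Modality, Phase, float | None]


class CohortIndex(Mapping[CohortKey, AnnotationDocument]):
    """Immutable index of a document collection by acquisition condition."""

    def __init__(self, entries: dict[CohortKey, AnnotationDocument]):
        self._entries = dict(entries)

    def __getitem__(self, key: CohortKey) -> AnnotationDocument:
        return self._entries[key]

    def __iter__(self) -> Iterator[CohortKey]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def volunteers(self) -> list[str]:
        return sorted({key[0] for key in self._entries})

    def xray(self, volunteer: str) -> AnnotationDocument | None:
        return self._entries.get((volunteer, Modality.XRAY, Phase.PRE, None))

    def ultrasound(self, volunteer: str, phase: Phase, load_kg: float) -> AnnotationDocument | None:
        return self._entries.get((volunteer, Modality.ULTRASOUND, phase, normalize_load(load_kg)))


def collect_cohort(
    sources: Iterable[str | Path | tuple[str, AnnotationDocument]],
) -> CohortIndex:
    """Build a cohort index from document paths or (name, document) pairs.

    Each document registers under (volunteer, modality, phase, load_kg);
    duplicate keys raise :class:`CohortConflictError` naming both sources.
    """
    entries: dict[CohortKey, AnnotationDocument] = {}
    origin: dict[CohortKey, str] = {}
    for source in sources:
        if isinstance(source, tuple):
            name, doc = source
        else:
            name = str(source)
            doc = load_annotation_document(source)
        key: CohortKey = (doc.meta.volunteer_id, doc.meta.modality, doc.meta.phase, doc.meta.load_kg)
        if key in entries:
            raise CohortConflictError(
                f"duplicate documents for {key}: {origin[key]!r} and {name!r}"
            )
        entries[key] = doc
        origin[key] = name
    return CohortIndex(entries)
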