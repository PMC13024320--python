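"""Load-ratio extrapolation, pre/during deltas, and cohort summaries.

The pipeline's core idea: the X-ray provides one high-resolution static
baseline per volunteer x region, and ultrasound tracks how the spine
deforms under graded traction.  For each volunteer x region, the
interspinous distance at a (phase, load) condition is divided by its
value at the pre-procedure 1.8 kg reference condition, giving a
dimensionless deformation ratio.  Every baseline metric m (area,
height, width, PDH, ADH) is then projected to that condition as

    extrapolated m = physical X-ray base value of m  *  ratio,

so the extrapolated value at the reference condition is the base value
itself.  The per-load delta is (during - pre) at the same load; positive
deltas indicate expansion under traction.  Cohort tables aggregate the
per-volunteer values with mean, sample SD, min, max and median.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .annotation import LOADS_KG, Phase, Region
from .errors import (
    EmptyGroupError,
    IncompleteAnnotationError,
    IncompleteDesignError,
    PairingError,
    ReferenceConditionError,
)
from .scaling import PhysicalBaseSet
from .geometry import UltrasoundMeasurement

__all__ = [
    "Metric",
    "REFERENCE_PHASE",
    "REFERENCE_LOAD_KG",
    "DeformationRatio",
    "ExtrapolatedRecord",
    "DeltaRecord",
    "SummaryRow",
    "deformation_ratio",
    "extrapolate_metric",
    "extrapolate_base_set",
    "compute_delta",
    "aggregate",
    "build_baseline_table",
    "build_delta_tables",
]

logger = logging.getLogger(__name__)

#: Normalization reference: the pre-procedure 4 lb (1.8 kg) condition.
REFERENCE_PHASE = Phase.PRE
REFERENCE_LOAD_KG = 1.8


class Metric(str, Enum):
    AREA = "AREA"
    HEIGHT = "HEIGHT"
    WIDTH = "WIDTH"
    PDH = "PDH"
    ADH = "ADH"

    @property
    def unit(self) -> str:
        return "mm2" if self is Metric.AREA else "mm"


def _base_value_mm(base: PhysicalBaseSet, metric: Metric) -> float:
    return {
        Metric.AREA: base.area_mm2,
        Metric.HEIGHT: base.height_mm,
        Metric.WIDTH: base.width_mm,
        Metric.PDH: base.pdh_mm,
        Metric.ADH: base.adh_mm,
    }[metric]


@dataclass(frozen=True)
class DeformationRatio:
    """Interspinous distance at a condition over its reference value."""

    volunteer_id: str
    region: Region
    phase: Phase
    load_kg: float
    ratio: float


@dataclass(frozen=True)
class ExtrapolatedRecord:
    """One metric projected to one phase x load condition (mm or mm^2)."""

    volunteer_id: str
    region: Region
    metric: Metric
    phase: Phase
    load_kg: float
    value: float


@dataclass(frozen=True)
class DeltaRecord:
    """during - pre difference of one extrapolated metric at one load."""

    volunteer_id: str
    region: Region
    metric: Metric
    load_kg: float
    delta: float


@dataclass(frozen=True)
class SummaryRow:
    """Cohort descriptive statistics for one region x metric (x load) cell."""

    region: Region
    metric: Metric
    load_kg: float | None
    n: int
    mean: float
    sd: float
    min: float
    max: float
    median: float


def deformation_ratio(
    us_at: UltrasoundMeasurement, us_ref: UltrasoundMeasurement
) -> DeformationRatio:
    """Ratio of an interspinous measurement to its reference condition.

    The reference must be the same volunteer and region measured at the
    pre-procedure 1.8 kg condition; the ratio there is exactly 1.
    """
    if (us_at.volunteer_id, us_at.region) != (us_ref.volunteer_id, us_ref.region):
        raise PairingError(
            f"ratio pairs must share volunteer and region: "
            f"({us_at.volunteer_id}, {us_at.region.value}) vs "
            f"({us_ref.volunteer_id}, {us_ref.region.value})"
        )
    if us_ref.phase is not REFERENCE_PHASE or not math.isclose(
        us_ref.load_kg, REFERENCE_LOAD_KG
    ):
        raise ReferenceConditionError(
            f"reference must be ({REFERENCE_PHASE.value}, {REFERENCE_LOAD_KG} kg), "
            f"got ({us_ref.phase.value}, {us_ref.load_kg} kg)"
        )
    if us_at.distance_mm <= 0 or us_ref.distance_mm <= 0:
        raise PairingError("interspinous distances must be > 0")
    if us_at is us_ref or (
        us_at.phase is REFERENCE_PHASE and math.isclose(us_at.load_kg, REFERENCE_LOAD_KG)
    ):
        ratio = 1.0  # the reference against itself, exactly
    else:
        ratio = us_at.distance_mm / us_ref.distance_mm
    return DeformationRatio(
        volunteer_id=us_at.volunteer_id,
        region=us_at.region,
        phase=us_at.phase,
        load_kg=us_at.load_kg,
        ratio=ratio,
    )


def extrapolate_metric(
    base: PhysicalBaseSet, metric: Metric, ratio: DeformationRatio
) -> ExtrapolatedRecord:
    """Project one physical baseline metric to the ratio's condition."""
    if (base.volunteer_id, base.region) != (ratio.volunteer_id, ratio.region):
        raise PairingError(
            f"base and ratio must share volunteer and region: "
            f"({base.volunteer_id}, {base.region.value}) vs "
            f"({ratio.volunteer_id}, {ratio.region.value})"
        )
    return ExtrapolatedRecord(
        volunteer_id=base.volunteer_id,
        region=base.region,
        metric=metric,
        phase=ratio.phase,
        load_kg=ratio.load_kg,
        value=_base_value_mm(base, metric) * ratio.ratio,
    )


def extrapolate_base_set(
    base: PhysicalBaseSet, ratio: DeformationRatio
) -> list[ExtrapolatedRecord]:
    """All five metrics projected to one condition."""
    return [extrapolate_metric(base, metric, ratio) for metric in Metric]


def compute_delta(pre: ExtrapolatedRecord, during: ExtrapolatedRecord) -> DeltaRecord:
    """during - pre at the same load; positive means expansion."""
    keys_pre = (pre.volunteer_id, pre.region, pre.metric, pre.load_kg)
    keys_dur = (during.volunteer_id, during.region, during.metric, during.load_kg)
    if keys_pre != keys_dur:
        raise PairingError(f"delta pairs must share keys: {keys_pre} vs {keys_dur}")
    if pre.phase is not Phase.PRE or during.phase is not Phase.DURING:
        raise PairingError(
            f"expected phases (PRE, DURING), got ({pre.phase.value}, {during.phase.value})"
        )
    return DeltaRecord(
        volunteer_id=pre.volunteer_id,
        region=pre.region,
        metric=pre.metric,
        load_kg=pre.load_kg,
        delta=during.value - pre.value,
    )


def aggregate(
    values: Sequence[float],
    *,
    region: Region,
    metric: Metric,
    load_kg: float | None = None,
) -> SummaryRow:
    """Cohort statistics: mean, sample SD (n-1), min, max, median.

    A singleton group has SD 0 by convention (logged), and the median of
    an even-sized group is the mean of the two central order statistics.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyGroupError(f"no values to aggregate for {region.value}/{metric.value}")
    if arr.size == 1:
        logger.warning(
            "singleton group %s/%s: sample SD defined as 0", region.value, metric.value
        )
        sd = 0.0
    elif np.min(arr) == np.max(arr):
        sd = 0.0  # all-equal groups get SD exactly 0, not mean round-off noise
    else:
        sd = float(np.std(arr, ddof=1))
    return SummaryRow(
        region=region,
        metric=metric,
        load_kg=load_kg,
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        min=float(np.min(arr)),
        max=float(np.max(arr)),
        median=float(np.median(arr)),
    )


def build_baseline_table(bases: Iterable[PhysicalBaseSet]) -> list[SummaryRow]:
    """One summary row per region x metric over physical baseline values.

    Requires a complete cohort: every volunteer must contribute all three
    lumbar regions.
    """
    by_key: dict[tuple[Region, Metric], list[float]] = {}
    seen: dict[str, set[Region]] = {}
    for base in bases:
        seen.setdefault(base.volunteer_id, set()).add(base.region)
        for metric in Metric:
            by_key.setdefault((base.region, metric), []).append(_base_value_mm(base, metric))
    if not seen:
        raise EmptyGroupError("no baseline measurement sets provided")
    for volunteer, regions in sorted(seen.items()):
        missing = [r.value for r in Region if r not in regions]
        if missing:
            raise IncompleteAnnotationError(
                f"volunteer {volunteer} lacks baseline regions {', '.join(missing)}"
            )
    return [
        aggregate(by_key[(region, metric)], region=region, metric=metric)
        for region in Region
        for metric in Metric
    ]


def build_delta_tables(
    deltas: Iterable[DeltaRecord], *, volunteers: Sequence[str] | None = None
) -> list[SummaryRow]:
    """Summary rows per metric x region x load over per-volunteer deltas.

    Validates the full loads design: every volunteer must contribute a
    delta for each region x metric x load cell.  Missing cells raise
    :class:`IncompleteDesignError` enumerating them.
    """
    records = list(deltas)
    if not records:
        raise EmptyGroupError("no delta records provided")
    cohort = sorted(volunteers) if volunteers is not None else sorted(
        {r.volunteer_id for r in records}
    )
    have = {(r.volunteer_id, r.region, r.metric, r.load_kg) for r in records}
    missing = [
        (v, region.value, metric.value, load)
        for v in cohort
        for region in Region
        for metric in Metric
        for load in LOADS_KG
        if (v, region, metric, load) not in have
    ]
    if missing:
        raise IncompleteDesignError("missing delta cells", missing=missing)
    rows: list[SummaryRow] = []
    for metric in Metric:
        for region in Region:
            for load in LOADS_KG:
                values = [
                    r.delta
                    for r in records
                    if (r.region, r.metric, r.load_kg) == (region, metric, load)
                ]
                rows.append(aggregate(values, region=region, metric=metric, load_kg=load))
    return rows
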