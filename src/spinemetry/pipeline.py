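"""End-to-end pipeline orchestration and table rendering.

Stages mirror the study workflow: annotation (document collection),
measurement (pixel geometry), scaling (CSF conversion), extrapolation
(ratios, projections, deltas) and reporting (cohort tables).  Any stage
failure propagates as :class:`PipelineStageError` naming the stage.

Outputs are fully deterministic for fixed inputs: rendered tables use
"mean (sd)" cells at a configurable decimal precision, and every
rendered number is also written at full precision to the JSON bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation import (
    LOADS_KG,
    AnnotationDocument,
    CohortIndex,
    Phase,
    Region,
    collect_cohort,
)
from .errors import (
    IncompleteDesignError,
    PipelineStageError,
    SpinemetryError,
)
from .extrapolation import (
    REFERENCE_LOAD_KG,
    REFERENCE_PHASE,
    DeltaRecord,
    ExtrapolatedRecord,
    Metric,
    SummaryRow,
    build_baseline_table,
    build_delta_tables,
    compute_delta,
    deformation_ratio,
    extrapolate_base_set,
)
from .geometry import measure_ultrasound, measure_xray_base
from .scaling import DEFAULT_CSF_CM_PER_PX, PhysicalBaseSet, ScalingFactor, convert_base_set

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "render_summary_table",
    "render_baseline_table",
    "summary_rows_frame",
]

_METRIC_TITLES = {
    Metric.AREA: "IVF area delta (mm^2)",
    Metric.WIDTH: "IVF width delta (mm)",
    Metric.HEIGHT: "IVF height delta (mm)",
    Metric.PDH: "Posterior disc height delta (mm)",
    Metric.ADH: "Anterior disc height delta (mm)",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one pipeline run."""

    input_dir: str | Path
    output_dir: str | Path
    csf_cm_per_px: float = DEFAULT_CSF_CM_PER_PX
    precision: int = 2
    fail_on_missing: bool = True

    def __post_init__(self):
        if self.csf_cm_per_px <= 0:
            raise ValueError("csf_cm_per_px must be > 0")
        if self.precision < 0:
            raise ValueError("precision must be >= 0")


@dataclass
class PipelineResult:
    """All computed artifacts of one run."""

    config: PipelineConfig
    bases: list[PhysicalBaseSet]
    extrapolated: list[ExtrapolatedRecord]
    deltas: list[DeltaRecord]
    baseline_rows: list[SummaryRow]
    delta_rows: list[SummaryRow]
    log: dict = field(default_factory=dict)


def _discover_documents(input_dir: Path) -> list[Path]:
    skip_prefixes = ("ground_truth", "generator_config")
    return sorted(
        p
        for p in input_dir.glob("*.json")
        if not p.name.startswith(skip_prefixes)
    )


def _measure_cohort(index: CohortIndex, csf: ScalingFactor):
    bases: list[PhysicalBaseSet] = []
    ratios = []
    missing: list[tuple] = []
    for volunteer in index.volunteers:
        xray = index.xray(volunteer)
        if xray is None:
            missing.append((volunteer, "*", "XRAY", Phase.PRE.value, None))
            continue
        for region in Region:
            bases.append(convert_base_set(measure_xray_base(xray, region), csf))
        refs = {}
        ref_doc = index.ultrasound(volunteer, REFERENCE_PHASE, REFERENCE_LOAD_KG)
        if ref_doc is None:
            missing.append(
                (volunteer, "*", "ULTRASOUND", REFERENCE_PHASE.value, REFERENCE_LOAD_KG)
            )
            continue
        for region in Region:
            refs[region] = measure_ultrasound(ref_doc, region)
        for phase in Phase:
            for load in LOADS_KG:
                doc = index.ultrasound(volunteer, phase, load)
                if doc is None:
                    missing.append((volunteer, "*", "ULTRASOUND", phase.value, load))
                    continue
                for region in Region:
                    ratios.append(
                        deformation_ratio(measure_ultrasound(doc, region), refs[region])
                    )
    if missing:
        raise IncompleteDesignError("missing documents", missing=missing)
    return bases, ratios


def run_pipeline(
    cfg: PipelineConfig,
    documents: Iterable[AnnotationDocument] | None = None,
) -> PipelineResult:
    """Run the full measurement -> scaling -> extrapolation -> reporting chain.

    ``documents`` may be passed directly (in-memory cohorts); otherwise all
    ``*.json`` annotation documents under ``cfg.input_dir`` are loaded.
    """
    csf = ScalingFactor(csf_cm_per_px=cfg.csf_cm_per_px)

    try:
        if documents is not None:
            index = collect_cohort((f"<memory:{i}>", d) for i, d in enumerate(documents))
        else:
            index = collect_cohort(_discover_documents(Path(cfg.input_dir)))
    except SpinemetryError as exc:
        raise PipelineStageError("annotation", exc) from exc

    try:
        bases, ratios = _measure_cohort(index, csf)
    except SpinemetryError as exc:
        raise PipelineStageError("measurement", exc) from exc

    try:
        base_by_key = {(b.volunteer_id, b.region): b for b in bases}
        extrapolated: list[ExtrapolatedRecord] = []
        for ratio in ratios:
            base = base_by_key[(ratio.volunteer_id, ratio.region)]
            extrapolated.extend(extrapolate_base_set(base, ratio))
        rec_by_key = {
            (r.volunteer_id, r.region, r.metric, r.phase, r.load_kg): r for r in extrapolated
        }
        deltas: list[DeltaRecord] = []
        for (volunteer, region, metric, phase, load), rec in sorted(
            rec_by_key.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value, kv[0][4])
        ):
            if phase is not Phase.PRE:
                continue
            during = rec_by_key.get((volunteer, region, metric, Phase.DURING, load))
            if during is None:
                raise IncompleteDesignError(
                    "missing during-phase record",
                    missing=[(volunteer, region.value, Phase.DURING.value, load)],
                )
            deltas.append(compute_delta(rec, during))
    except SpinemetryError as exc:
        raise PipelineStageError("extrapolation", exc) from exc

    try:
        baseline_rows = build_baseline_table(bases)
        delta_rows = build_delta_tables(deltas, volunteers=index.volunteers)
    except SpinemetryError as exc:
        raise PipelineStageError("reporting", exc) from exc

    log = {
        "n_volunteers": len(index.volunteers),
        "n_documents": len(index),
        "csf_cm_per_px": cfg.csf_cm_per_px,
        "n_baseline_sets": len(bases),
        "n_extrapolated_records": len(extrapolated),
        "n_delta_records": len(deltas),
    }
    return PipelineResult(
        config=cfg,
        bases=bases,
        extrapolated=extrapolated,
        deltas=deltas,
        baseline_rows=baseline_rows,
        delta_rows=delta_rows,
        log=log,
    )


def summary_rows_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    """Summary rows as a long-format DataFrame (full precision)."""
    return pd.DataFrame(
        {
            "region": [r.region.value for r in rows],
            "metric": [r.metric.value for r in rows],
            "load_kg": [r.load_kg for r in rows],
            "n": [r.n for r in rows],
            "mean": [r.mean for r in rows],
            "sd": [r.sd for r in rows],
            "min": [r.min for r in rows],
            "max": [r.max for r in rows],
            "median": [r.median for r in rows],
        }
    )


def _cell(mean: float, sd: float, precision: int) -> str:
    return f"{mean:.{precision}f} ({sd:.{precision}f})"


def render_summary_table(rows: Sequence[SummaryRow], precision: int = 2) -> str:
    """Render one metric's delta table: loads as rows, regions as columns."""
    metrics = {r.metric for r in rows}
    if len(metrics) != 1:
        raise ValueError("render_summary_table expects rows of a single metric")
    metric = metrics.pop()
    by_key = {(r.region, r.load_kg): r for r in rows}
    missing = [
        (region.value, load)
        for load in LOADS_KG
        for region in Region
        if (region, load) not in by_key
    ]
    if missing:
        raise IncompleteDesignError(
            f"cannot render {metric.value} table", missing=missing
        )
    header = ["Force (kg)"] + [region.display for region in Region]
    lines = [_METRIC_TITLES[metric], "\t".join(header)]
    for load in LOADS_KG:
        cells = [f"{load:g}"]
        for region in Region:
            row = by_key[(region, load)]
            cells.append(_cell(row.mean, row.sd, precision))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def render_baseline_table(rows: Sequence[SummaryRow], precision: int = 2) -> str:
    """Render the baseline table: regions as rows, metrics as columns."""
    by_key = {(r.region, r.metric): r for r in rows}
    order = [Metric.ADH, Metric.AREA, Metric.HEIGHT, Metric.PDH, Metric.WIDTH]
    header = ["Region"] + [
        f"{m.value.title()} ({'mm^2' if m is Metric.AREA else 'mm'})" for m in order
    ]
    lines = ["Pre-distraction baseline, mean (SD)", "\t".join(header)]
    for region in Region:
        cells = [region.display]
        for metric in order:
            row = by_key.get((region, metric))
            if row is None:
                raise IncompleteDesignError(
                    "cannot render baseline table", missing=[(region.value, metric.value)]
                )
            cells.append(_cell(row.mean, row.sd, precision))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def _json_bundle(result: PipelineResult) -> dict:
    def row_dict(r: SummaryRow) -> dict:
        return {
            "region": r.region.value,
            "metric": r.metric.value,
            "load_kg": r.load_kg,
            "n": r.n,
            "mean": r.mean,
            "sd": r.sd,
            "min": r.min,
            "max": r.max,
            "median": r.median,
        }

    return {
        "config": {
            "input_dir": str(result.config.input_dir),
            "csf_cm_per_px": result.config.csf_cm_per_px,
            "precision": result.config.precision,
        },
        "log": result.log,
        "baseline": [row_dict(r) for r in result.baseline_rows],
        "deltas": [row_dict(r) for r in result.delta_rows],
    }


def write_outputs(result: PipelineResult) -> Path:
    """Write tables, long-format CSVs and the JSON bundle to the output dir."""
    outdir = Path(result.config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    precision = result.config.precision

    summary_rows_frame(result.baseline_rows).drop(columns=["load_kg"]).to_csv(
        outdir / "baseline_table.csv", index=False
    )
    delta_frame = summary_rows_frame(result.delta_rows)
    delta_frame.to_csv(outdir / "delta_long.csv", index=False)
    for metric in Metric:
        rows = [r for r in result.delta_rows if r.metric is metric]
        frame = summary_rows_frame(rows).drop(columns=["metric"])
        frame.to_csv(outdir / f"delta_{metric.value.lower()}.csv", index=False)

    rendered = [render_baseline_table(result.baseline_rows, precision)]
    for metric in Metric:
        rows = [r for r in result.delta_rows if r.metric is metric]
        rendered.append(render_summary_table(rows, precision))
    (outdir / "tables.txt").write_text("\n".join(rendered), encoding="utf-8")

    (outdir / "results.json").write_text(
        json.dumps(_json_bundle(result), sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    return outdir
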