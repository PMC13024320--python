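"""Synthetic-cohort generator: annotation documents plus ground truth.

The generator emulates the study design end to end: ``n_volunteers``
volunteers, each contributing one pre-procedure X-ray document (IVF
polygon plus PDH/ADH landmark pairs for L3-L4, L4-L5, L5-S1) and eight
ultrasound documents (PRE/DURING x four traction loads, one
interspinous landmark pair per region).  Coordinates are constructed to
realize the drawn target metrics exactly, so with zero measurement
noise the full measurement pipeline recovers ground truth to floating-
point precision.

Baseline geometry model
-----------------------
Disc heights (PDH, ADH) and foramen width/height are truncated normals
(truncation at 0.1 x mean guards positivity).  Width and height share a
Gaussian copula with a region-specific z-correlation.  Foramen area is
NOT drawn marginally: any polygon satisfies area <= width x height, and
independent draws from the published moments violate that bound in up
to a third of samples, which would bias recovered means.  Instead the
generator draws a fill fraction phi from a Beta law scaled to
(0.05, 0.95) and sets area = phi * width * height.  The fill mean is
solved so that E[area] equals the configured area mean exactly (using
Gauss-Hermite quadrature for E[width x height] under the copula), and
the width-height z-correlation is solved so Var(area) matches the
configured SD as closely as the model allows.  Geometric feasibility is
therefore guaranteed by construction, with no rejection bias.

Deformation model
-----------------
Each volunteer x region has one true interspinous distance at the
pre-procedure 1.8 kg reference.  Each other phase x load condition has
a deformation factor: 1 exactly at the reference, N(1, pre_factor_sd)
truncated for the other pre-phase loads, and N(1 + gap, sd) truncated
for during-phase loads, with (gap, sd) back-solved per region x load
from the published area-delta summaries.  Measured values multiply
ground truth by (1 + eps), eps ~ N(0, noise_sd), independently per
measurement; noise_sd = 0 yields exact recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .annotation import (
    LOADS_KG,
    AnnotationDocument,
    ImageMeta,
    Label,
    LandmarkPair,
    Modality,
    Phase,
    Point2D,
    PolygonAnnotation,
    Region,
)
from .defaults import (
    AREA_DELTA_PARAMS,
    BASELINE_PARAMS,
    DEFAULT_N_VOLUNTEERS,
    DEFAULT_SEED,
    derive_factor_params,
)
from .errors import InfeasibleTargetError
from .extrapolation import Metric
from .scaling import DEFAULT_CSF_CM_PER_PX

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_cohort",
    "realize_polygon",
    "emit_ground_truth",
    "read_ground_truth",
    "write_cohort_directory",
]

_FILL_LO, _FILL_HI = 0.05, 0.95
_FACTOR_TRUNC_LO = 0.1


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the published design: 15 volunteers, baseline
    geometry from the pre-distraction summaries, deformation factors
    back-solved from the per-load area-delta summaries, and 1% relative
    measurement noise.
    """

    n_volunteers: int = DEFAULT_N_VOLUNTEERS
    seed: int = DEFAULT_SEED
    csf_cm_per_px: float = DEFAULT_CSF_CM_PER_PX
    baseline_params: dict[Region, dict[Metric, tuple[float, float]]] = field(
        default_factory=lambda: {r: dict(m) for r, m in BASELINE_PARAMS.items()}
    )
    area_delta_params: dict[Region, dict[float, tuple[float, float]]] = field(
        default_factory=lambda: {r: dict(d) for r, d in AREA_DELTA_PARAMS.items()}
    )
    noise_sd: float = 0.01
    pre_factor_sd: float = 0.02
    fill_sd: float = 0.04
    ultrasound_mm_per_px: float = 0.2
    interspinous_mm: tuple[float, float] = (30.0, 4.0)

    def __post_init__(self):
        if self.n_volunteers < 1:
            raise ValueError("n_volunteers must be >= 1")
        if self.csf_cm_per_px <= 0 or self.ultrasound_mm_per_px <= 0:
            raise ValueError("calibration factors must be > 0")
        if self.noise_sd < 0 or self.pre_factor_sd < 0 or self.fill_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for region, metrics in self.baseline_params.items():
            for metric, (mean, sd) in metrics.items():
                if mean <= 0 or sd < 0:
                    raise ValueError(f"invalid baseline params for {region}/{metric}")
        if self.interspinous_mm[0] <= 0 or self.interspinous_mm[1] < 0:
            raise ValueError("invalid interspinous distance parameters")

    def factor_params(self) -> dict[Region, dict[float, tuple[float, float]]]:
        return derive_factor_params(
            self.baseline_params, self.area_delta_params, pre_factor_sd=self.pre_factor_sd
        )

    def to_json(self) -> str:
        payload = {
            "n_volunteers": self.n_volunteers,
            "seed": self.seed,
            "csf_cm_per_px": self.csf_cm_per_px,
            "noise_sd": self.noise_sd,
            "pre_factor_sd": self.pre_factor_sd,
            "fill_sd": self.fill_sd,
            "ultrasound_mm_per_px": self.ultrasound_mm_per_px,
            "interspinous_mm": list(self.interspinous_mm),
            "baseline_params": {
                r.value: {m.value: list(v) for m, v in metrics.items()}
                for r, metrics in self.baseline_params.items()
            },
            "area_delta_params": {
                r.value: {str(load): list(v) for load, v in loads.items()}
                for r, loads in self.area_delta_params.items()
            },
        }
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free generating values, joinable against pipeline outputs.

    ``bases``:   volunteer_id, region, metric, value (mm / mm^2).
    ``factors``: volunteer_id, region, phase, load_kg, factor,
                 interspinous_mm (the true measured distance there).
    """

    bases: pd.DataFrame
    factors: pd.DataFrame

    def base_value(self, volunteer: str, region: Region, metric: Metric) -> float:
        frame = self.bases
        sel = frame[
            (frame.volunteer_id == volunteer)
            & (frame.region == region.value)
            & (frame.metric == metric.value)
        ]
        return float(sel.value.iloc[0])

    def factor(self, volunteer: str, region: Region, phase: Phase, load_kg: float) -> float:
        frame = self.factors
        sel = frame[
            (frame.volunteer_id == volunteer)
            & (frame.region == region.value)
            & (frame.phase == phase.value)
            & (np.isclose(frame.load_kg, load_kg))
        ]
        return float(sel.factor.iloc[0])


def _truncnorm_ppf(u, mean: float, sd: float, lower: float):
    if sd == 0:
        return np.full_like(np.asarray(u, dtype=float), mean)
    a = (lower - mean) / sd
    # clip away u == 0/1 so extreme quadrature nodes stay finite
    u = np.clip(np.asarray(u, dtype=float), 1e-12, 1.0 - 1e-12)
    return stats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def _wh_moments(
    w_params: tuple[float, float], h_params: tuple[float, float], rho: float, nodes: int = 40
) -> tuple[float, float]:
    """E[wh] and E[(wh)^2] for copula-correlated truncated normals.

    Gauss-Hermite quadrature over the two latent standard normals; the
    z-correlation rho couples the copula.
    """
    x, wx = np.polynomial.hermite_e.hermegauss(nodes)
    wx = wx / math.sqrt(2.0 * math.pi)
    zw = x[:, None] * np.ones(nodes)[None, :]
    zh = rho * x[:, None] + math.sqrt(max(1.0 - rho**2, 0.0)) * x[None, :]
    w = _truncnorm_ppf(stats.norm.cdf(zw), w_params[0], w_params[1], 0.1 * w_params[0])
    h = _truncnorm_ppf(stats.norm.cdf(zh), h_params[0], h_params[1], 0.1 * h_params[0])
    weight = wx[:, None] * wx[None, :]
    prod = w * h
    m1 = float(np.sum(weight * prod))
    m2 = float(np.sum(weight * prod**2))
    return m1, m2


def _solve_area_model(
    area_params: tuple[float, float],
    w_params: tuple[float, float],
    h_params: tuple[float, float],
    fill_sd: float,
) -> tuple[float, float, float]:
    """(rho, fill_mean, fill_sd_used) realizing the configured area moments.

    rho solves Var(area) = configured sd^2 where
    area = phi * w * h, phi ~ (fill_mean, fill_sd) independent of (w, h);
    if no rho in [-0.95, 0.95] attains it, the closest endpoint is used.
    The fill mean is always solved exactly: fill_mean = mu_area / E[wh].
    """
    mu_a, sd_a = area_params

    def excess(rho: float) -> float:
        m1, m2 = _wh_moments(w_params, h_params, rho)
        fill_mean = mu_a / m1
        var_area = (fill_sd**2 + fill_mean**2) * m2 - mu_a**2
        return var_area - sd_a**2

    lo, hi = -0.95, 0.95
    f_lo, f_hi = excess(lo), excess(hi)
    if f_lo == 0.0:
        rho = lo
    elif f_hi == 0.0:
        rho = hi
    elif f_lo * f_hi < 0:
        rho = float(optimize.brentq(excess, lo, hi, xtol=1e-10))
    else:
        rho = lo if abs(f_lo) < abs(f_hi) else hi
    m1, _ = _wh_moments(w_params, h_params, rho)
    fill_mean = mu_a / m1
    if not (_FILL_LO < fill_mean < _FILL_HI):
        raise InfeasibleTargetError(
            f"configured area mean {mu_a} implies fill fraction {fill_mean:.3f} "
            f"outside ({_FILL_LO}, {_FILL_HI}); area must be well below width*height"
        )
    span = _FILL_HI - _FILL_LO
    m_unit = (fill_mean - _FILL_LO) / span
    v_max = 0.9 * m_unit * (1.0 - m_unit)
    v_unit = min((fill_sd / span) ** 2, v_max)
    return rho, fill_mean, math.sqrt(v_unit) * span


def _beta_params(fill_mean: float, fill_sd: float) -> tuple[float, float]:
    span = _FILL_HI - _FILL_LO
    m = (fill_mean - _FILL_LO) / span
    v = (fill_sd / span) ** 2
    alpha = m * (m * (1.0 - m) / v - 1.0)
    beta = alpha * (1.0 - m) / m
    return alpha, beta


def realize_polygon(
    target_area_px2: float,
    target_width_px: float,
    target_height_px: float,
    *,
    region: Region,
    origin: tuple[float, float] = (0.0, 0.0),
) -> PolygonAnnotation:
    """A simple polygon hitting the area and bounding-box targets exactly.

    Construction: a rectangle-with-notch (L-shape) family.  With
    r = 1 - sqrt(1 - area / (w*h)), the vertices
    (0,0), (w,0), (w, r*h), (r*w, r*h), (r*w, h), (0, h)
    have bounding box (w, h) and shoelace area w*h*r*(2-r) = area.
    At r = 1 (area == w*h) the family degenerates to the rectangle.
    """
    a, w, h = target_area_px2, target_width_px, target_height_px
    if w <= 0 or h <= 0 or a <= 0:
        raise InfeasibleTargetError("polygon targets must be > 0")
    if a > w * h * (1.0 + 1e-12):
        raise InfeasibleTargetError(
            f"target area {a} exceeds width*height bound {w * h}"
        )
    ox, oy = origin
    r = 1.0 - math.sqrt(max(1.0 - a / (w * h), 0.0))
    if r > 1.0 - 1e-7:
        coords = [(0.0, 0.0), (w, 0.0), (w, h), (0.0, h)]
    else:
        t, t2 = h * r, w * r
        coords = [(0.0, 0.0), (w, 0.0), (w, t), (t2, t), (t2, h), (0.0, h)]
    vertices = tuple(Point2D(x=ox + x, y=oy + y) for x, y in coords)
    return PolygonAnnotation(label=Label.IVF, region=region, vertices=vertices)


def _vertical_pair(
    label: Label, region: Region, origin: tuple[float, float], length_px: float
) -> LandmarkPair:
    ox, oy = origin
    return LandmarkPair(
        label=label,
        region=region,
        p=Point2D(x=ox, y=oy),
        q=Point2D(x=ox, y=oy + length_px),
    )


def generate_cohort(
    cfg: GeneratorConfig | None = None,
) -> tuple[list[AnnotationDocument], GroundTruth]:
    """Generate a full synthetic cohort: documents plus ground truth.

    Deterministic given the config seed.  Per volunteer: one X-ray
    document and eight ultrasound documents (phase x load).
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    factor_params = cfg.factor_params()
    area_models = {
        region: _solve_area_model(
            cfg.baseline_params[region][Metric.AREA],
            cfg.baseline_params[region][Metric.WIDTH],
            cfg.baseline_params[region][Metric.HEIGHT],
            cfg.fill_sd,
        )
        for region in Region
    }

    base_rows: list[dict] = []
    factor_rows: list[dict] = []
    documents: list[AnnotationDocument] = []
    width_id = len(str(cfg.n_volunteers))

    def noisy(value: float) -> float:
        if cfg.noise_sd == 0:
            return value
        return value * (1.0 + cfg.noise_sd * rng.standard_normal())

    for idx in range(cfg.n_volunteers):
        volunteer = f"V{idx + 1:0{width_id}d}"
        truth: dict[Region, dict[Metric, float]] = {}
        base_dist: dict[Region, float] = {}
        factors: dict[tuple[Region, Phase, float], float] = {}

        for region in Region:
            params = cfg.baseline_params[region]
            rho, fill_mean, fill_sd_used = area_models[region]
            zx, zy = rng.standard_normal(2)
            zw = zx
            zh = rho * zx + math.sqrt(max(1.0 - rho**2, 0.0)) * zy
            w_mm = float(
                _truncnorm_ppf(
                    stats.norm.cdf(zw),
                    *params[Metric.WIDTH],
                    0.1 * params[Metric.WIDTH][0],
                )
            )
            h_mm = float(
                _truncnorm_ppf(
                    stats.norm.cdf(zh),
                    *params[Metric.HEIGHT],
                    0.1 * params[Metric.HEIGHT][0],
                )
            )
            if fill_sd_used > 0:
                alpha, beta = _beta_params(fill_mean, fill_sd_used)
                fill = _FILL_LO + (_FILL_HI - _FILL_LO) * rng.beta(alpha, beta)
            else:
                fill = fill_mean
            area_mm2 = fill * w_mm * h_mm
            pdh_mm = float(
                _truncnorm_ppf(rng.uniform(), *params[Metric.PDH], 0.1 * params[Metric.PDH][0])
            )
            adh_mm = float(
                _truncnorm_ppf(rng.uniform(), *params[Metric.ADH], 0.1 * params[Metric.ADH][0])
            )
            truth[region] = {
                Metric.AREA: area_mm2,
                Metric.HEIGHT: h_mm,
                Metric.WIDTH: w_mm,
                Metric.PDH: pdh_mm,
                Metric.ADH: adh_mm,
            }
            base_dist[region] = float(
                _truncnorm_ppf(rng.uniform(), *cfg.interspinous_mm, 0.1 * cfg.interspinous_mm[0])
            )
            for metric in Metric:
                base_rows.append(
                    {
                        "volunteer_id": volunteer,
                        "region": region.value,
                        "metric": metric.value,
                        "value": truth[region][metric],
                    }
                )
            for phase in Phase:
                for load in LOADS_KG:
                    if phase is Phase.PRE and load == 1.8:
                        f = 1.0
                    elif phase is Phase.PRE:
                        f = float(
                            _truncnorm_ppf(
                                rng.uniform(), 1.0, cfg.pre_factor_sd, _FACTOR_TRUNC_LO
                            )
                        )
                    else:
                        mean_f, sd_f = factor_params[region][load]
                        f = float(
                            _truncnorm_ppf(rng.uniform(), mean_f, sd_f, _FACTOR_TRUNC_LO)
                        )
                    factors[(region, phase, load)] = f
                    factor_rows.append(
                        {
                            "volunteer_id": volunteer,
                            "region": region.value,
                            "phase": phase.value,
                            "load_kg": load,
                            "factor": f,
                            "interspinous_mm": base_dist[region] * f,
                        }
                    )

        # X-ray document: targets in mm are converted to px via the CSF
        # (length: (mm/10)/csf; area: (mm^2/100)/csf^2), so the pipeline's
        # px -> cm -> mm conversion recovers them exactly.
        csf = cfg.csf_cm_per_px
        polygons: list[PolygonAnnotation] = []
        landmarks: list[LandmarkPair] = []
        for i, region in enumerate(Region):
            t = truth[region]
            area_n = noisy(t[Metric.AREA])
            w_n = noisy(t[Metric.WIDTH])
            h_n = noisy(t[Metric.HEIGHT])
            area_n = min(area_n, 0.98 * w_n * h_n)  # guard rare noise-induced overflow
            pdh_n = noisy(t[Metric.PDH])
            adh_n = noisy(t[Metric.ADH])
            oy = 200.0 * i
            polygons.append(
                realize_polygon(
                    (area_n / 100.0) / csf**2,
                    (w_n / 10.0) / csf,
                    (h_n / 10.0) / csf,
                    region=region,
                    origin=(0.0, oy),
                )
            )
            landmarks.append(
                _vertical_pair(Label.PDH, region, (50.0, oy), (pdh_n / 10.0) / csf)
            )
            landmarks.append(
                _vertical_pair(Label.ADH, region, (60.0, oy), (adh_n / 10.0) / csf)
            )
        documents.append(
            AnnotationDocument(
                meta=ImageMeta(volunteer_id=volunteer, modality=Modality.XRAY),
                polygons=tuple(polygons),
                landmarks=tuple(landmarks),
            )
        )

        for phase in Phase:
            for load in LOADS_KG:
                pairs = []
                for i, region in enumerate(Region):
                    dist_mm = noisy(base_dist[region] * factors[(region, phase, load)])
                    pairs.append(
                        _vertical_pair(
                            Label.INTERSPINOUS,
                            region,
                            (10.0, 400.0 * i),
                            dist_mm / cfg.ultrasound_mm_per_px,
                        )
                    )
                documents.append(
                    AnnotationDocument(
                        meta=ImageMeta(
                            volunteer_id=volunteer,
                            modality=Modality.ULTRASOUND,
                            phase=phase,
                            load_kg=load,
                            ultrasound_mm_per_px=cfg.ultrasound_mm_per_px,
                        ),
                        landmarks=tuple(pairs),
                    )
                )

    truth_df = GroundTruth(
        bases=pd.DataFrame(base_rows, columns=["volunteer_id", "region", "metric", "value"]),
        factors=pd.DataFrame(
            factor_rows,
            columns=["volunteer_id", "region", "phase", "load_kg", "factor", "interspinous_mm"],
        ),
    )
    return documents, truth_df


def emit_ground_truth(gt: GroundTruth, outdir: str | Path) -> tuple[Path, Path]:
    """Write ground truth as long-format CSVs: bases.csv and factors.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bases_path = outdir / "ground_truth_bases.csv"
    factors_path = outdir / "ground_truth_factors.csv"
    gt.bases.to_csv(bases_path, index=False)
    gt.factors.to_csv(factors_path, index=False)
    return bases_path, factors_path


def read_ground_truth(outdir: str | Path) -> GroundTruth:
    outdir = Path(outdir)
    return GroundTruth(
        bases=pd.read_csv(outdir / "ground_truth_bases.csv"),
        factors=pd.read_csv(outdir / "ground_truth_factors.csv"),
    )


def write_cohort_directory(
    cfg: GeneratorConfig | None = None, outdir: str | Path = "cohort"
) -> Path:
    """Generate a cohort and write documents, ground truth and config snapshot."""
    from .annotation import save_annotation_document

    cfg = cfg or GeneratorConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    documents, gt = generate_cohort(cfg)
    for doc in documents:
        meta = doc.meta
        if meta.modality is Modality.XRAY:
            name = f"{meta.volunteer_id}_xray.json"
        else:
            name = (
                f"{meta.volunteer_id}_us_{meta.phase.value.lower()}_"
                f"{str(meta.load_kg).replace('.', 'p')}kg.json"
            )
        save_annotation_document(doc, outdir / name)
    emit_ground_truth(gt, outdir)
    (outdir / "generator_config.json").write_text(cfg.to_json(), encoding="utf-8")
    return outdir
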