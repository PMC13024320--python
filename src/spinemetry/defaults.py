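"""Default study-condition parameters for the synthetic cohort generator.

Baseline geometry parameters are the published cohort's pre-distraction
mean (SD) values per lumbar region, in mm and mm^2.  Deformation-factor
defaults are back-solved from the published per-load IVF-area delta
summaries against those baselines: because a single interspinous ratio
per volunteer x region x condition drives all five metrics, the area
table fixes the factor means and SDs, and the other metrics' expected
deltas follow proportionally from their own baselines.
"""

from __future__ import annotations

from .annotation import Region
from .extrapolation import Metric

#: Cohort size of the study design.
DEFAULT_N_VOLUNTEERS = 15

#: Fixed seed used in documentation examples.
DEFAULT_SEED = 20260312

#: Pre-distraction baseline mean/SD per region x metric (mm, mm^2).
BASELINE_PARAMS: dict[Region, dict[Metric, tuple[float, float]]] = {
    Region.L3L4: {
        Metric.ADH: (1.62, 0.21),
        Metric.AREA: (58.89, 13.70),
        Metric.HEIGHT: (7.73, 1.63),
        Metric.PDH: (0.73, 0.17),
        Metric.WIDTH: (11.65, 2.09),
    },
    Region.L4L5: {
        Metric.ADH: (1.62, 0.21),
        Metric.AREA: (44.38, 15.83),
        Metric.HEIGHT: (6.91, 2.04),
        Metric.PDH: (0.76, 0.16),
        Metric.WIDTH: (9.85, 3.09),
    },
    Region.L5S1: {
        Metric.ADH: (1.87, 0.54),
        Metric.AREA: (17.67, 8.79),
        Metric.HEIGHT: (4.17, 1.26),
        Metric.PDH: (0.60, 0.24),
        Metric.WIDTH: (6.39, 2.44),
    },
}

#: Per-load IVF-area delta mean/SD per region (mm^2), the anchor from
#: which the generator's deformation-factor defaults are derived.
AREA_DELTA_PARAMS: dict[Region, dict[float, tuple[float, float]]] = {
    Region.L3L4: {
        1.8: (3.93, 5.56),
        3.6: (4.27, 4.89),
        5.4: (3.28, 2.81),
        11.3: (7.27, 6.34),
    },
    Region.L4L5: {
        1.8: (5.32, 6.01),
        3.6: (6.25, 6.05),
        5.4: (6.36, 7.30),
        11.3: (9.94, 8.02),
    },
    Region.L5S1: {
        1.8: (2.08, 1.88),
        3.6: (3.18, 2.67),
        5.4: (1.63, 1.27),
        11.3: (4.09, 4.88),
    },
}


def derive_factor_params(
    baseline_params: dict[Region, dict[Metric, tuple[float, float]]],
    area_delta_params: dict[Region, dict[float, tuple[float, float]]],
    *,
    pre_factor_sd: float,
) -> dict[Region, dict[float, tuple[float, float]]]:
    """During-phase deformation-factor (mean, sd) per region x load.

    Solved so that, with baselines independent of factors,
    E[delta_area] = mu_area * (f_during_mean - 1) matches the configured
    area-delta mean, and Var(delta_area) = E[b^2] Var(f_dur - f_pre)
    + Var(b) E[f_dur - f_pre]^2 matches the configured area-delta SD.
    The pre-phase factor is 1 exactly at the 1.8 kg reference and
    N(1, pre_factor_sd) at the other loads.
    """
    out: dict[Region, dict[float, tuple[float, float]]] = {}
    for region, loads in area_delta_params.items():
        mu_b, sd_b = baseline_params[region][Metric.AREA]
        out[region] = {}
        for load, (d_mean, d_sd) in loads.items():
            gap = d_mean / mu_b
            var_diff = (d_sd**2 - sd_b**2 * gap**2) / (mu_b**2 + sd_b**2)
            pre_var = 0.0 if load == 1.8 else pre_factor_sd**2
            var_dur = max(var_diff - pre_var, 1e-6)
            out[region][load] = (1.0 + gap, var_dur**0.5)
    return out
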