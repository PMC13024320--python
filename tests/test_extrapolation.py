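"""Deformation ratios, extrapolation, deltas and cohort aggregation."""

from __future__ import annotations

import math

import pytest

from spinemetry import (
    DeformationRatio,
    DeltaRecord,
    ExtrapolatedRecord,
    Metric,
    Phase,
    PhysicalBaseSet,
    Region,
    UltrasoundMeasurement,
    aggregate,
    build_baseline_table,
    build_delta_tables,
    compute_delta,
    deformation_ratio,
    extrapolate_base_set,
    extrapolate_metric,
)
from spinemetry.errors import (
    EmptyGroupError,
    IncompleteAnnotationError,
    IncompleteDesignError,
    PairingError,
    ReferenceConditionError,
)

LOADS = (1.8, 3.6, 5.4, 11.3)


def us(volunteer="V01", region=Region.L3L4, phase=Phase.PRE, load=1.8, mm=20.0):
    return UltrasoundMeasurement(
        volunteer_id=volunteer, region=region, phase=phase, load_kg=load, distance_mm=mm
    )


def base_set(volunteer="V01", region=Region.L3L4, area_cm2=0.5889, **kw):
    defaults = dict(height_cm=0.773, width_cm=1.165, pdh_cm=0.073, adh_cm=0.162)
    defaults.update(kw)
    return PhysicalBaseSet(volunteer_id=volunteer, region=region, area_cm2=area_cm2, **defaults)


class TestDeformationRatio:
    def test_reference_against_itself_is_exactly_one(self):
        ref = us()
        assert deformation_ratio(ref, ref).ratio == 1.0

    def test_direct_division(self):
        ratio = deformation_ratio(us(phase=Phase.DURING, load=3.6, mm=25.0), us(mm=20.0))
        assert ratio.ratio == pytest.approx(1.25, rel=1e-12)

    def test_mismatched_volunteer_or_region(self):
        with pytest.raises(PairingError):
            deformation_ratio(us(volunteer="V02"), us())
        with pytest.raises(PairingError):
            deformation_ratio(us(region=Region.L4L5), us())

    def test_non_reference_condition_rejected(self):
        with pytest.raises(ReferenceConditionError):
            deformation_ratio(us(), us(load=3.6))
        with pytest.raises(ReferenceConditionError):
            deformation_ratio(us(), us(phase=Phase.DURING))

    def test_homogeneity_in_ultrasound_scale(self):
        """Multiplying all of a volunteer's distances by c cancels in the ratio."""
        for c in (0.5, 2.0, 7.3):
            r1 = deformation_ratio(us(phase=Phase.DURING, load=5.4, mm=26.0), us(mm=20.0))
            r2 = deformation_ratio(
                us(phase=Phase.DURING, load=5.4, mm=26.0 * c), us(mm=20.0 * c)
            )
            assert r2.ratio == pytest.approx(r1.ratio, rel=1e-12)


class TestExtrapolation:
    def test_identity_ratio_returns_base(self):
        base = base_set()  # area 58.89 mm^2
        ratio = DeformationRatio(
            volunteer_id="V01", region=Region.L3L4, phase=Phase.PRE, load_kg=1.8, ratio=1.0
        )
        rec = extrapolate_metric(base, Metric.AREA, ratio)
        assert rec.value == base.area_mm2 == pytest.approx(58.89, rel=1e-12)

    def test_scalar_projection(self):
        base = base_set(width_cm=1.0)  # 10 mm
        ratio = DeformationRatio(
            volunteer_id="V01", region=Region.L3L4, phase=Phase.DURING, load_kg=3.6, ratio=1.1
        )
        assert extrapolate_metric(base, Metric.WIDTH, ratio).value == pytest.approx(11.0)

    def test_ratio_product_linearity(self, rng):
        base = base_set()
        for _ in range(20):
            r1, r2 = rng.uniform(0.5, 1.5, 2)
            combined = DeformationRatio(
                volunteer_id="V01",
                region=Region.L3L4,
                phase=Phase.DURING,
                load_kg=5.4,
                ratio=r1 * r2,
            )
            rec = extrapolate_metric(base, Metric.HEIGHT, combined)
            assert rec.value == pytest.approx(base.height_mm * r1 * r2, rel=1e-12)

    def test_all_five_metrics(self):
        base = base_set()
        ratio = DeformationRatio(
            volunteer_id="V01", region=Region.L3L4, phase=Phase.DURING, load_kg=11.3, ratio=1.2
        )
        records = extrapolate_base_set(base, ratio)
        assert {r.metric for r in records} == set(Metric)
        by_metric = {r.metric: r.value for r in records}
        assert by_metric[Metric.AREA] == pytest.approx(base.area_mm2 * 1.2, rel=1e-12)
        assert by_metric[Metric.PDH] == pytest.approx(base.pdh_mm * 1.2, rel=1e-12)

    def test_pairing_enforced(self):
        ratio = DeformationRatio(
            volunteer_id="V02", region=Region.L3L4, phase=Phase.PRE, load_kg=1.8, ratio=1.0
        )
        with pytest.raises(PairingError):
            extrapolate_metric(base_set(), Metric.AREA, ratio)


def rec(volunteer="V01", region=Region.L3L4, metric=Metric.AREA, phase=Phase.PRE, load=1.8, value=58.0):
    return ExtrapolatedRecord(
        volunteer_id=volunteer, region=region, metric=metric, phase=phase, load_kg=load, value=value
    )


class TestDelta:
    def test_expansion_is_positive(self):
        d = compute_delta(rec(value=58.0), rec(phase=Phase.DURING, value=60.0))
        assert d.delta == pytest.approx(2.0)

    def test_null_change(self):
        d = compute_delta(rec(value=58.0), rec(phase=Phase.DURING, value=58.0))
        assert d.delta == 0.0

    def test_key_mismatch(self):
        with pytest.raises(PairingError):
            compute_delta(rec(load=1.8), rec(phase=Phase.DURING, load=3.6))
        with pytest.raises(PairingError):
            compute_delta(rec(metric=Metric.PDH), rec(phase=Phase.DURING))

    def test_phase_order_enforced(self):
        with pytest.raises(PairingError):
            compute_delta(rec(phase=Phase.DURING), rec(phase=Phase.PRE))


class TestAggregate:
    def test_hand_computed(self):
        row = aggregate([2, 4, 6], region=Region.L3L4, metric=Metric.AREA)
        assert (row.mean, row.sd, row.min, row.max, row.median) == (4.0, 2.0, 2.0, 6.0, 4.0)
        assert row.n == 3

    def test_singleton_sd_zero(self):
        row = aggregate([5.0], region=Region.L3L4, metric=Metric.PDH)
        assert row.sd == 0.0
        assert row.mean == row.min == row.max == row.median == 5.0

    def test_even_median_midpoint(self):
        row = aggregate([1.0, 2.0, 10.0, 20.0], region=Region.L3L4, metric=Metric.ADH)
        assert row.median == pytest.approx(6.0)

    def test_empty_rejected(self):
        with pytest.raises(EmptyGroupError):
            aggregate([], region=Region.L3L4, metric=Metric.AREA)

    def test_matches_definitional_oracle(self, rng):
        """Brute-force formulas evaluated independently of numpy aggregation."""
        for _ in range(50):
            n = int(rng.integers(1, 40))
            values = list(rng.uniform(-100, 100, n))
            if rng.uniform() < 0.3:
                values[: n // 2] = [values[0]] * (n // 2)  # ties
            row = aggregate(values, region=Region.L4L5, metric=Metric.WIDTH)
            mean = sum(values) / n
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
            ordered = sorted(values)
            median = (
                ordered[n // 2]
                if n % 2
                else (ordered[n // 2 - 1] + ordered[n // 2]) / 2.0
            )
            assert row.mean == pytest.approx(mean, rel=1e-12, abs=1e-12)
            assert row.sd == pytest.approx(sd, rel=1e-9, abs=1e-12)
            assert row.median == pytest.approx(median, rel=1e-12, abs=1e-12)
            assert row.min == min(values) and row.max == max(values)


class TestBaselineTable:
    def test_identical_volunteers_have_zero_sd(self):
        bases = [
            base_set(volunteer=f"V{i}", region=region)
            for i in range(5)
            for region in Region
        ]
        rows = build_baseline_table(bases)
        assert len(rows) == 15
        assert all(row.sd == 0.0 for row in rows)

    def test_single_volunteer_means(self):
        bases = [base_set(region=region) for region in Region]
        rows = build_baseline_table(bases)
        area_row = next(r for r in rows if (r.region, r.metric) == (Region.L3L4, Metric.AREA))
        assert area_row.mean == pytest.approx(58.89, rel=1e-12)
        assert area_row.n == 1

    def test_incomplete_cohort_names_volunteer(self):
        bases = [base_set(region=Region.L3L4)]
        with pytest.raises(IncompleteAnnotationError, match="V01"):
            build_baseline_table(bases)


class TestDeltaTables:
    def _deltas(self, gap=0.0):
        out = []
        for v in ("V01", "V02", "V03"):
            for region in Region:
                for metric in Metric:
                    for load in LOADS:
                        out.append(
                            DeltaRecord(
                                volunteer_id=v,
                                region=region,
                                metric=metric,
                                load_kg=load,
                                delta=gap,
                            )
                        )
        return out

    def test_zero_gap_cohort(self):
        rows = build_delta_tables(self._deltas(gap=0.0))
        assert len(rows) == 5 * 3 * 4
        assert all(row.mean == 0.0 and row.sd == 0.0 for row in rows)

    def test_missing_cells_enumerated(self):
        deltas = self._deltas()
        removed = deltas.pop()
        with pytest.raises(IncompleteDesignError) as exc:
            build_delta_tables(deltas)
        assert removed.volunteer_id in str(exc.value)
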