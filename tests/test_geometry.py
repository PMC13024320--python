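"""Geometric measurement: shoelace area, distances, extents, composition."""

from __future__ import annotations

import math

import numpy as np
import pytest
from shapely.geometry import Polygon as ShapelyPolygon

from spinemetry import (
    Label,
    Region,
    measure_ultrasound,
    measure_xray_base,
    point_distance,
    polygon_area,
    polygon_extents,
)
from spinemetry.errors import DegenerateGeometryError, IncompleteAnnotationError

from conftest import (
    make_point,
    make_polygon,
    make_us_doc,
    make_xray_doc,
    random_star_polygon,
)


class TestPolygonArea:
    @pytest.mark.parametrize(
        "coords, expected",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
            ([(0, 0), (4, 0), (0, 3)], 6.0),
            ([(0, 0), (10, 0), (10, 4), (0, 4)], 40.0),
        ],
    )
    def test_known_areas(self, coords, expected):
        assert polygon_area(make_polygon(coords)) == pytest.approx(expected, rel=1e-12)

    def test_orientation_and_start_invariance(self, rng):
        for _ in range(20):
            poly = random_star_polygon(rng)
            coords = [(v.x, v.y) for v in poly.vertices]
            area = polygon_area(poly)
            assert polygon_area(make_polygon(coords[::-1])) == pytest.approx(area, rel=1e-12)
            k = int(rng.integers(1, len(coords)))
            rolled = coords[k:] + coords[:k]
            assert polygon_area(make_polygon(rolled)) == pytest.approx(area, rel=1e-12)

    def test_matches_shapely_on_random_simple_polygons(self, rng):
        """Independent library oracle for the shoelace computation."""
        for _ in range(50):
            poly = random_star_polygon(rng)
            expected = ShapelyPolygon([(v.x, v.y) for v in poly.vertices]).area
            assert polygon_area(poly) == pytest.approx(expected, rel=1e-12)

    def test_translation_rotation_invariance(self, rng):
        poly = random_star_polygon(rng)
        area = polygon_area(poly)
        theta, dx, dy = 0.7, 123.4, -56.7
        c, s = math.cos(theta), math.sin(theta)
        moved = make_polygon(
            [(c * v.x - s * v.y + dx, s * v.x + c * v.y + dy) for v in poly.vertices]
        )
        assert polygon_area(moved) == pytest.approx(area, rel=1e-9)

    def test_fan_triangulation_sums_to_area(self, rng):
        """On convex polygons the fan triangulation partitions the area."""
        for _ in range(20):
            n = int(rng.integers(4, 12))
            angles = np.sort(rng.uniform(0, 2 * np.pi, n))
            while np.any(np.diff(angles) < 1e-3):
                angles = np.sort(rng.uniform(0, 2 * np.pi, n))
            r = rng.uniform(2, 20)
            coords = [(r * np.cos(a), r * np.sin(a)) for a in angles]
            total = polygon_area(make_polygon(coords))
            fan = sum(
                polygon_area(make_polygon([coords[0], coords[i], coords[i + 1]]))
                for i in range(1, n - 1)
            )
            assert fan == pytest.approx(total, rel=1e-9)

    def test_collinear_polygon_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            polygon_area(make_polygon([(0, 0), (1, 1), (2, 2)]))


class TestPointDistance:
    def test_3_4_5_triangle(self):
        assert point_distance(make_point(0, 0), make_point(3, 4)) == 5.0

    def test_axis_aligned(self):
        assert point_distance(make_point(2, 3), make_point(2, 3 + 7.5)) == 7.5

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(100):
            a, b, c = (make_point(*rng.uniform(-100, 100, 2)) for _ in range(3))
            if a == b or b == c or a == c:
                continue
            assert point_distance(a, b) == point_distance(b, a)
            assert point_distance(a, c) <= point_distance(a, b) + point_distance(b, c) + 1e-12

    def test_matches_high_precision_oracle(self, rng):
        from decimal import Decimal, getcontext

        getcontext().prec = 50
        for _ in range(50):
            x0, y0, x1, y1 = (float(v) for v in rng.uniform(-1e3, 1e3, 4))
            expected = float(
                (
                    (Decimal(repr(x1)) - Decimal(repr(x0))) ** 2
                    + (Decimal(repr(y1)) - Decimal(repr(y0))) ** 2
                ).sqrt()
            )
            got = point_distance(make_point(x0, y0), make_point(x1, y1))
            assert got == pytest.approx(expected, rel=1e-14)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            point_distance(make_point(1, 1), make_point(1, 1))


class TestPolygonExtents:
    @pytest.mark.parametrize(
        "coords, expected",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], (1.0, 1.0)),
            ([(0, 0), (10, 0), (10, 4), (0, 4)], (10.0, 4.0)),
        ],
    )
    def test_known_extents(self, coords, expected):
        assert polygon_extents(make_polygon(coords)) == expected

    def test_matches_vertex_scan(self, rng):
        for _ in range(50):
            poly = random_star_polygon(rng)
            xs = [v.x for v in poly.vertices]
            ys = [v.y for v in poly.vertices]
            assert polygon_extents(poly) == (max(xs) - min(xs), max(ys) - min(ys))

    def test_extents_bound_pairwise_projections(self, rng):
        poly = random_star_polygon(rng)
        width, height = polygon_extents(poly)
        for a in poly.vertices:
            for b in poly.vertices:
                assert abs(a.x - b.x) <= width + 1e-12
                assert abs(a.y - b.y) <= height + 1e-12

    def test_reversal_invariance(self, rng):
        poly = random_star_polygon(rng)
        reversed_poly = make_polygon([(v.x, v.y) for v in poly.vertices][::-1])
        assert polygon_extents(poly) == polygon_extents(reversed_poly)


class TestMeasurementComposition:
    def test_xray_base_set(self):
        doc = make_xray_doc()
        base = measure_xray_base(doc, Region.L3L4)
        assert base.area_px2 == pytest.approx(1.0)
        assert base.width_px == pytest.approx(1.0)
        assert base.height_px == pytest.approx(1.0)
        assert base.pdh_px == pytest.approx(2.0)
        assert base.adh_px == pytest.approx(5.0)

    def test_missing_landmark_names_label_and_region(self):
        doc = make_xray_doc(regions=(Region.L5S1,))
        doc = doc.model_copy(
            update={"landmarks": tuple(lm for lm in doc.landmarks if lm.label is not Label.ADH)}
        )
        with pytest.raises(IncompleteAnnotationError, match="ADH.*L5S1"):
            measure_xray_base(doc, Region.L5S1)

    def test_missing_region_polygon(self):
        doc = make_xray_doc(regions=(Region.L3L4,))
        with pytest.raises(IncompleteAnnotationError, match="L4L5"):
            measure_xray_base(doc, Region.L4L5)

    def test_ultrasound_scaling(self):
        doc = make_us_doc(distances_px={Region.L3L4: 100.0}, mm_per_px=0.2)
        us = measure_ultrasound(doc, Region.L3L4)
        assert us.distance_mm == pytest.approx(20.0)

    def test_identity_calibration_reduces_to_pixels(self):
        doc = make_us_doc(distances_px={Region.L3L4: 137.5}, mm_per_px=1.0)
        assert measure_ultrasound(doc, Region.L3L4).distance_mm == pytest.approx(137.5)

    def test_wrong_modality_rejected(self):
        with pytest.raises(IncompleteAnnotationError):
            measure_xray_base(make_us_doc(), Region.L3L4)
        with pytest.raises(IncompleteAnnotationError):
            measure_ultrasound(make_xray_doc(), Region.L3L4)
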