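"""Shared fixtures and strategies for the spinemetry test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import strategies as st

from spinemetry import (
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

LOADS = (1.8, 3.6, 5.4, 11.3)


def make_point(x, y):
    return Point2D(x=x, y=y)


def make_polygon(coords, region=Region.L3L4):
    return PolygonAnnotation(
        label=Label.IVF, region=region, vertices=tuple(make_point(x, y) for x, y in coords)
    )


def make_pair(label, p, q, region=Region.L3L4):
    return LandmarkPair(label=label, region=region, p=make_point(*p), q=make_point(*q))


def make_xray_doc(volunteer="V01", regions=(Region.L3L4,)):
    """A complete X-ray document: unit-square IVF, PDH (0,0)-(0,2), ADH (0,0)-(0,5)."""
    polys, pairs = [], []
    for i, region in enumerate(regions):
        oy = 100.0 * i
        polys.append(
            make_polygon([(0, oy), (1, oy), (1, oy + 1), (0, oy + 1)], region=region)
        )
        pairs.append(make_pair(Label.PDH, (10, oy), (10, oy + 2), region=region))
        pairs.append(make_pair(Label.ADH, (20, oy), (20, oy + 5), region=region))
    return AnnotationDocument(
        meta=ImageMeta(volunteer_id=volunteer, modality=Modality.XRAY),
        polygons=tuple(polys),
        landmarks=tuple(pairs),
    )


def make_us_doc(
    volunteer="V01",
    phase=Phase.PRE,
    load_kg=1.8,
    mm_per_px=0.2,
    distances_px=None,
    regions=(Region.L3L4,),
):
    distances_px = distances_px or {r: 100.0 for r in regions}
    pairs = tuple(
        make_pair(Label.INTERSPINOUS, (0, 400.0 * i), (0, 400.0 * i + distances_px[r]), region=r)
        for i, r in enumerate(regions)
    )
    return AnnotationDocument(
        meta=ImageMeta(
            volunteer_id=volunteer,
            modality=Modality.ULTRASOUND,
            phase=phase,
            load_kg=load_kg,
            ultrasound_mm_per_px=mm_per_px,
        ),
        landmarks=pairs,
    )


def random_star_polygon(rng: np.random.Generator, n_min=4, n_max=24):
    """A random simple polygon: radial (star-shaped) vertices about a center."""
    n = int(rng.integers(n_min, n_max + 1))
    angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=n))
    # enforce distinct angles so consecutive vertices never coincide
    while np.any(np.diff(angles) < 1e-3):
        angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=n))
    radii = rng.uniform(1.0, 10.0, size=n)
    cx, cy = rng.uniform(-50.0, 50.0, size=2)
    coords = [(cx + r * np.cos(a), cy + r * np.sin(a)) for r, a in zip(radii, angles)]
    return make_polygon(coords)


finite_coord = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)


@st.composite
def polygon_coords(draw, n_min=3, n_max=12):
    """Coordinates of a random convex-position simple polygon (hypothesis)."""
    n = draw(st.integers(n_min, n_max))
    angles = sorted(
        draw(
            st.lists(
                st.floats(0.0, 6.28, allow_nan=False),
                min_size=n,
                max_size=n,
                unique=True,
            )
        )
    )
    radius = draw(st.floats(1.0, 100.0))
    cx = draw(st.floats(-1000.0, 1000.0))
    cy = draw(st.floats(-1000.0, 1000.0))
    return [(cx + radius * np.cos(a), cy + radius * np.sin(a)) for a in angles]


@pytest.fixture
def rng():
    return np.random.default_rng(20260312)
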