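# Methods

This note documents the measurement model, the scaling and
extrapolation procedure, the synthetic-cohort generator, and the
numerical and design choices behind them.

## Measurement model

An annotation document describes one image: pixel-space coordinates
(0-based, y increasing downward) plus provenance (volunteer, modality,
phase, traction load). X-ray documents are pre-procedure only and carry
the IVF polygon and the PDH/ADH landmark pairs per lumbar region;
ultrasound documents carry one interspinous landmark pair per region
and a per-image `ultrasound_mm_per_px` calibration, treated as known
from the device settings.

Five baseline metrics are extracted per volunteer × region:

* **IVF area** — shoelace formula over the polygon's cyclic vertex
  sequence, absolute-valued so tracing direction is irrelevant.
* **IVF width / height** — axis-aligned bounding-box extents of the IVF
  polygon. The measurement convention for foramen width/height is not
  uniquely determined by the annotation geometry; bounding-box extents
  are the simplest reproducible definition and are used consistently on
  both the measurement and the generation side. Principal-axis or
  caliper-style extents would be alternative conventions.
* **PDH / ADH** — Euclidean distances between the respective landmark
  pairs.

Polygons must be simple (validated via shapely at parse time) and
non-degenerate. Degenerate geometry — zero area, coincident landmarks,
collapsed extents — raises an error rather than returning 0, because a
zero baseline would silently poison every downstream ratio. A
duplicated closing vertex is dropped on parse, accommodating both open
and closed polygon export dialects.

## Common scaling factor

The CSF converts X-ray pixels to centimeters. Derivation from matched
landmarks: per axis, the arithmetic mean of per-pair
(ultrasound cm)/(X-ray px) ratios; across axes, the geometric mean
CSF = √(r_H · r_V). The geometric mean integrates the horizontal and
vertical adjustments into one isotropic factor and is a fixed point
when both axes agree. One CSF is applied globally — per-region or
anisotropic scaling is deliberately out of scope. The reproduction
default is 0.518 cm/px, shipped as configuration because the reference
landmark values behind it are not part of the public record.

A known tension, reproduced rather than resolved: converting mm-scale
disc heights (ADH ≈ 1.6 mm) with a 0.518 cm/px factor implies sub-pixel
annotation coordinates. Coordinates are floats throughout, so this is
numerically harmless.

Internal canonical unit is cm (matching the CSF); tables report mm and
mm² (1 cm = 10 mm, 1 cm² = 100 mm²).

## Extrapolation and deltas

The deformation ratio at (phase, load) is the interspinous distance
there divided by its value at the pre-procedure 1.8 kg reference; the
reference ratio is set to 1.0 exactly, so the extrapolated value at the
reference condition equals the physical base value bit-for-bit. All
five metrics are projected with the same (linear) ratio — including
area, which one could alternatively scale quadratically as a
length-ratio squared; the linear rule is the documented pipeline
definition and is applied uniformly.

Deltas are during − pre at the same load, so expansion under traction
is positive. The reference measurement is the sole normalization
anchor: if it is missing for any volunteer × region the pipeline
refuses to run (enumerated error), never substituting another load.
Missing-data policy is fail-loud throughout; the study design is
complete by construction.

Aggregation across volunteers: arithmetic mean; sample SD
(n−1 denominator), defined as 0 for singleton groups (logged) and
returned as exactly 0 for all-equal groups (suppressing mean round-off
noise of order 1e-16); median with the midpoint rule for even n;
exact min/max. Loads may be supplied in kg {1.8, 3.6, 5.4, 11.3} or as
lb aliases {4, 8, 12, 25}, normalized to kg on input.

## Synthetic cohort generator

The generator emulates the study design — 15 volunteers, each with one
X-ray document and eight ultrasound documents (2 phases × 4 loads),
all three regions per document — and emits ground truth alongside, so
recovery can be tested exactly.

**What it emulates.** Regional baseline anatomy with the published
per-region means/SDs; a per-volunteer interspinous distance
(30 ± 4 mm, a typical adult lumbar interspinous spacing) scaled by
per-condition deformation factors; multiplicative measurement noise
(default 1% relative, applied independently per measured quantity).

**Baseline geometry.** PDH and ADH are independent truncated normals
(truncated at 0.1 × mean to guard positivity). Width and height are
truncated normals coupled by a Gaussian copula with a region-specific
z-correlation. Area is *not* drawn marginally: any polygon satisfies
area ≤ width × height, and independent draws from the configured
moments violate that bound in up to a third of samples — any
rejection or redraw scheme then biases recovered means. Instead the
generator draws a fill fraction φ from a Beta law scaled to
(0.05, 0.95) and sets area = φ · width · height. The fill mean is
solved so E[area] equals the configured mean exactly (E[width·height]
is computed by 40-node Gauss–Hermite quadrature under the copula), and
the width–height z-correlation is solved (Brent root-finding on
[−0.95, 0.95]) so Var(area) matches the configured SD as closely as
the product model allows, with a small fill-fraction SD (default 0.04).
Feasibility is thus guaranteed by construction with no rejection bias;
the cost is that area is strongly correlated with the box extents and
the width–height correlation is a fitted, not an anatomical, quantity.

**Deformation factors.** The factor is 1 exactly at the reference
condition; N(1, 0.02) truncated for other pre-phase loads (pre-phase
measurements differ only by repositioning variability); and
N(1 + gap, sd) truncated for during-phase loads. The per-region ×
load (gap, sd) defaults are back-solved from the published per-load
area-delta summaries against the area baselines, so the expected area
delta mean and SD match those summaries. Because one interspinous
ratio drives all five metrics, the other metrics' expected deltas are
proportional to their own baselines — the published per-metric delta
tables are mutually inconsistent with a single-ratio generative model,
so only the area table can be matched exactly in expectation; the
remaining tables are approximated up to that proportionality.

**Coordinate realization.** Coordinates are constructed to hit the
(noisy) target metrics exactly: lengths become vertical landmark pairs
of length (mm/10)/CSF px (X-ray) or mm / `ultrasound_mm_per_px` px
(ultrasound, default 0.2 mm/px, a typical curvilinear depth setting);
the IVF polygon uses a rectangle-with-notch (L-shape) family whose
shoelace area and bounding box hit all three targets simultaneously
(degenerating to the exact rectangle at full fill). With noise 0 the
measurement pipeline therefore recovers ground truth to ~1e-12
relative, and the full pipeline satisfies the closed form
delta = base × (f_during − f_pre) analytically. A guard clamps the
noisy area at 0.98 × (noisy width × height); at the default 1% noise
this fires with probability ≈ 1e-8 and is bias-irrelevant.

**What it does not emulate.** Imaging physics, probe placement and
operator variability beyond the single relative-noise knob, vertebral
shape (the notch polygon is a measurement-target gadget, not an
anatomical contour), and any inter-metric correlation beyond the
size coupling described above. Passing recovery tests therefore
demonstrates correctness of the measurement/scaling/extrapolation
chain, not realism of the images the coordinates stand for.

## Determinism and problem sizes

All randomness flows through one `numpy` generator seeded from the
config; identical configs produce byte-identical documents, tables and
JSON bundles (no timestamps in any output). Statistical recovery tests
use the shipped design size (n = 15) with 200 replicate seeds for the
bias check; geometry oracles use 50 random star-shaped polygons with
10⁶ Monte-Carlo samples each. Floating-point geometric identities are
asserted at 1e-9 relative tolerance (double precision with far fewer
than 10³ vertices leaves orders of magnitude of headroom).

## Known limitations

* The bounding-box width/height convention and the linear area
  extrapolation are documented conventions; other choices would change
  numeric results.
* The generator's normality (and product-model) assumptions are
  modeling choices, not inferences about the study population.
* No inferential statistics (t-tests, ANOVA, mixed models, CIs) are
  provided — the pipeline is descriptive by design.
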