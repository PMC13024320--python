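# spinemetry

Multimodal lumbar spine morphometry: linking static X-ray baseline
geometry with dynamic ultrasound measurements under graded traction.

## The problem

Flexion-distraction traction applies graded axial loads (1.8, 3.6, 5.4
and 11.3 kg) to the prone lumbar spine. Radiography gives
high-resolution static anatomy — the intervertebral foramen (IVF)
boundary and the anterior/posterior disc tip landmarks at L3–L4, L4–L5
and L5–S1 — but only pre-procedure, while ultrasound tracks the
interspinous distance in real time during traction but sees a different
anatomy at a different scale. `spinemetry` implements the computational
bridge between the two for researchers studying spinal biomechanics:

1. **Annotation geometry.** From JSON annotation documents (polygon
   vertex rings and landmark point pairs in pixel coordinates), five
   baseline metrics are measured per volunteer × region: IVF area by the
   shoelace formula

   *A* = ½ |Σᵢ (xᵢ yᵢ₊₁ − xᵢ₊₁ yᵢ)|,

   IVF width/height as bounding-box extents, and posterior/anterior disc
   heights (PDH, ADH) as Euclidean landmark distances.
2. **Common scaling factor (CSF).** A single cm-per-pixel constant
   converts X-ray pixel measurements to physical units. It is derived
   from matched landmarks as the geometric mean of the horizontal and
   vertical (ultrasound cm)/(X-ray px) ratios, CSF = √(r_H·r_V); the
   study's configured value 0.518 cm/px ships as the default.
3. **Ratio extrapolation.** For each volunteer × region, the
   deformation ratio at a (phase, load) condition is the interspinous
   distance there divided by its value at the pre-procedure 1.8 kg
   reference. Every baseline metric *m* is projected as
   *m*(phase, load) = *m*_base × ratio, and the per-load delta
   (during − pre, positive = expansion) quantifies structural response.
4. **Cohort tables.** Mean, sample SD, min, max and median across
   volunteers, per region × metric (× load), rendered as
   "mean (sd)" tables and machine-readable CSV/JSON.

Because the underlying volunteer data is not publicly deposited, the
package includes a first-class synthetic-cohort generator that emulates
the full 15-volunteer × 3-region × 4-load × 2-phase design with
configurable baseline and deformation statistics — every pipeline stage
is testable against known ground truth (see `docs/methods.md`).

## Worked example

```python
import spinemetry as sm

cfg = sm.GeneratorConfig(n_volunteers=15, seed=20260312)
docs, truth = sm.generate_cohort(cfg)
result = sm.run_pipeline(
    sm.PipelineConfig(input_dir=".", output_dir="out"), documents=docs
)
print(sm.render_baseline_table(result.baseline_rows))
rows = [r for r in result.delta_rows if r.metric is sm.Metric.AREA]
print(sm.render_summary_table(rows))
```

prints

```
Pre-distraction baseline, mean (SD)
Region  Adh (mm)     Area (mm^2)    Height (mm)  Pdh (mm)     Width (mm)
L3-L4   1.62 (0.27)  58.57 (14.58)  7.47 (1.62)  0.72 (0.16)  11.84 (2.58)
L4-L5   1.54 (0.26)  49.78 (15.80)  6.65 (1.80)  0.67 (0.14)  11.03 (2.41)
L5-S1   1.72 (0.56)  14.85 (6.84)   3.78 (1.41)  0.64 (0.28)  5.76 (1.19)

IVF area delta (mm^2)
Force (kg)  L3-L4        L4-L5        L5-S1
1.8         6.35 (5.98)  5.24 (7.62)  1.88 (2.11)
3.6         3.89 (5.22)  8.79 (8.30)  3.39 (2.28)
5.4         3.53 (3.09)  9.68 (7.10)  1.00 (1.01)
11.3        8.79 (5.26)  8.56 (7.42)  2.94 (3.62)
```

The baseline table recovers the configured regional anatomy (e.g. the
L3–L4 foramen area near 58.9 mm² with tapering toward L5–S1), and the
delta tables show positive mean expansion at every load with the
characteristic inter-subject variability (SDs comparable to means).

The same workflow is available from the shell:

```sh
spinemetry generate --out cohort --n 15 --seed 20260312
spinemetry run --input cohort --out results
spinemetry measure --input cohort --out measurements.csv
```

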