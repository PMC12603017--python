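# mealscan

Automated food-volume and nutrition estimation from overhead depth-camera
captures of a dining table.

A depth camera mounted roughly half a meter above the table samples the
scene once a minute during a meal. From each pair of consecutive frames,
`mealscan` isolates the per-plate food point cloud, measures how much
food disappeared, and converts that volume into grams and nutrients:

1. **Geometry** — pixels with depth *d* are back-projected through the
   pinhole model, X = (u−cₓ)·d/fₓ, Y = (v−c_y)·d/f_y, Z = d, giving a
   metric point cloud per frame.
2. **Segmentation** — RANSAC plane fits peel off the table and the plate
   interior; DBSCAN plus an RMS-distance filter isolates the food mounds
   (and keeps an emptied plate's exposed bottom from being mistaken for
   food).
3. **Registration** — consecutive clouds are aligned by FPFH descriptors
   feeding a RANSAC over 3-point correspondence samples, refined with
   point-to-point ICP.
4. **Change volume** — points of the earlier cloud farther than a
   threshold from the later cloud form the removed surface; each is
   paired with the later surface directly beneath it (XY nearest
   neighbor), giving a height field Δz = z − z′. The field is meshed by
   2-D Delaunay triangulation and integrated as truncated triangular
   prisms,

   V = Σ (1/6)·|z₁+z₂+z₃|·|x₁y₂ − x₂y₁ + x₂y₃ − x₃y₂ + x₃y₁ − x₁y₃|,

   i.e. mean vertex height × projected triangle area per face.
5. **Nutrition** — weight = volume × ρ × μ, with ρ the food density
   (g/cm³) and μ a packing factor correcting the apparent stacked volume;
   weights join a nutrition table (per-100 g values) for nutrient totals
   and eating speed (g/min).
6. **Association** — plates are re-identified across frames by fusing
   Bhattacharyya histogram similarity, radius similarity, and optional
   externally-supplied embedding cosine similarity, solved as a Hungarian
   assignment.

A parametric scene generator (plates as rimmed disks, food as spherical
caps with closed-form volume (π·h/6)(3a²+h²)) renders depth frames
through the same camera model with sensor noise and simulates bites, so
the whole pipeline is testable end to end with analytic ground truth.

## Worked example

The package ships per-bite reference measurements for three single-food
meals (broccoli, chicken, rice): kitchen-scale weights alongside
camera-measured volumes per eating sequence. Re-deriving the weights and
signed errors from the volumes:

```python
from mealscan import accumulate_meal, load_reference_meals, NutritionEntry

rice = load_reference_meals()["rice"]
entry = NutritionEntry("rice", density=1.0, packing=rice.effective_factor)
summary = accumulate_meal(
    [(60.0 * (i + 1), v) for i, v in enumerate(rice.volumes_cm3)],
    entry,
    references_g=rice.reference_g,
)
for iv in summary.ledger.intervals:
    print(f"t={iv.timestamp:5.0f}s  volume={iv.volume_cm3:8.4f} cm^3  "
          f"weight={iv.weight_g:8.4f} g  error={iv.error_pct:+6.2f}%")
print(f"total: {summary.total_weight_g:.3f} g vs {summary.total_reference_g:.1f} g "
      f"reference -> {summary.total_error_pct:+.2f}%")
```

```
t=   60s  volume= 28.6671 cm^3  weight= 28.6671 g  error=+21.46%
t=  120s  volume= 31.3682 cm^3  weight= 31.3682 g  error= +1.36%
t=  180s  volume= 39.8051 cm^3  weight= 39.8051 g  error= -0.26%
t=  240s  volume= 16.5793 cm^3  weight= 16.5793 g  error=+30.34%
t=  300s  volume= 40.5053 cm^3  weight= 40.5053 g  error=-11.58%
total: 156.925 g vs 168.1 g reference -> +6.65%
```

For rice ρ·μ = 1 (density of water, no packing correction), so weights
equal volumes; the per-sequence errors show the method's typical spread
— a bite that barely changes the surface is under-measured (+30 %), and
the errors largely cancel in the running total (+6.65 %).

The same pipeline runs from the shell on simulated data:

```bash
mealscan simulate --out demo/meal --bites 3
mealscan meal-report demo/meal --category rice --out demo/report.json
```

The report's recovered per-interval volumes (28.85, 29.01, 20.77 cm³)
sit within a percent of the generator's ground truth (28.82, 28.82,
20.73 cm³), with weights, nutrient totals and eating speed derived from
them. CLI verbs `segment`, `register`, `diff`, `volume`, and `match`
expose the individual stages on PLY/PCD clouds and signature JSON files.

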