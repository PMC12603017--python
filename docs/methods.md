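# Methods

This note documents the models, numerical choices, and limitations
behind `mealscan`. Units throughout: depth rasters in millimeters
(consumer depth-camera convention, 0 = invalid pixel), point clouds in
meters in the camera frame (X right, Y down, Z along the optical axis
toward the table), volumes in cm³, weights in grams.

## Camera model and scene conventions

A pinhole model without lens distortion maps pixels to rays. The camera
is assumed nadir-mounted 45–55 cm above the table (default simulated
depth 50 cm), so the table is a plane of near-constant Z and "up" is
−Z. Pixel coordinates are 0-based with centers on integer coordinates.
Default simulation intrinsics are 640×480, fx = fy = 615,
cx = 319.5, cy = 239.5 — representative of the sensor class used for
tabletop capture; everything is configurable.

## Segmentation

Per-plate crops are segmented in four steps:

1. **First RANSAC plane** (threshold 3 mm, 1000 iterations,
   least-squares refit over the consensus set): the dominant flat
   surface — the plate interior or the table ring, whichever covers more
   of the crop.
2. **Second plane pass**, restricted to candidates within 15° of the
   first plane's orientation, removes the other flat surface. The
   orientation restriction stops a tilted plane from slicing a band out
   of a curved food mound. The deeper plane (larger mean Z) is reported
   as table, the other as plate. Without the second pass an emptied
   plate's flat bottom would be clustered and misread as food.
3. **DBSCAN** (eps 8 mm, min_pts 10) clusters the remainder;
   **RMS filtering** drops clusters whose RMS point distance to the
   global cloud centroid exceeds a threshold (default: the estimated
   plate radius). The RMS distance of a cluster is defined as the root
   mean square of its points' Euclidean distances to the whole-crop
   centroid — a per-point form rather than a centroid-distance form, so
   elongated clutter reaching away from the plate is penalized.
4. **Rim rule**: a surviving cluster whose points lie ≥ 80 % beyond
   0.8 × plate radius is the raised plate rim, assigned to the plate
   rather than to food.

The plane-inlier threshold couples to scene geometry: two parallel
surfaces can only be told apart when their separation exceeds twice the
threshold. This is why the synthetic plate's interior sits 8 mm above
the table (typical of ceramic dinner plates); with a 4 mm plate a single
midway plane would swallow both surfaces at the 3 mm threshold.

## Registration

Consecutive frame clouds (later → earlier) are aligned coarse-to-fine:
voxel downsampling (3 mm, grid anchored at the origin, centroid
representative to preserve surface position), PCA surface normals over
all neighbors within 2×voxel oriented toward the camera, 33-bin FPFH
descriptors over 5×voxel, mutual-nearest feature matching, RANSAC over
3-correspondence samples with edge-length compatibility pruning (ratio
> 0.9), and point-to-point ICP (max correspondence 2×voxel,
tolerance 1e-6, 50 iterations). Point-to-point rather than
point-to-plane ICP: tabletop scenes are shallow, so per-point normals on
near-flat regions are noise-dominated. An ICP iteration that would raise
the RMSE is rejected and iteration stops, making the reported RMSE
sequence non-increasing by construction.

`register_pair` tries ICP from the identity first and accepts it at
fitness ≥ 0.8. For a fixed camera sampling once a minute the true
transform is near-identity, and this fast path avoids a real failure
mode: global registration of a rotationally near-symmetric scene (a
round plate with similar mounds) can snap to a wrong symmetry with high
fitness. Feature-based global registration is the fallback for plates
that moved.

Accuracy caveats, measured on synthetic scenes: under per-point noise
comparable to the local feature scale, FPFH needs wider radii on
downsampled clouds (noise averages out in voxels); and scenes whose only
asymmetry is small mounds on a round plate leave a shallow (±2°)
rotational valley that point-to-point ICP cannot resolve — container
exterior features carry the alignment, which is also why deformable or
transparent containers are out of scope.

## Change extraction and volume integration

For an aligned pair (earlier cloud E, later cloud L):

1. **Extraction**: points of E whose nearest neighbor in L is farther
   than the change threshold form the removed ("top") surface.
2. **Denoising**: DBSCAN (eps 4 mm, min 12 points) on the extracted set
   drops scattered survivors. This step is load-bearing: even a handful
   of isolated noise points elsewhere on the plate create huge spurious
   Delaunay triangles whose prisms dominate the integral.
3. **Region closing ("fill")**: every point of E whose XY distance to a
   detected point is ≤ 5 mm joins the top set. Threshold detection alone
   keeps only points that noise pushed *past* the threshold, biasing the
   integrated heights upward near the detection margin, and it misses
   sloped rim regions where the 3-D gap is geometrically smaller than
   the vertical drop (by cos of the surface slope). Closing the region
   samples heights unconditionally; points added beyond the true change
   region carry near-zero heights and are harmless.
4. **Bottom pairing**: each top point pairs with the L point nearest in
   the XY plane (2-D KD-tree).
5. **Z-origin correction**: heights Δz = z − z′ per pair, XY unchanged.
   In the camera frame Z points down, so removed food yields negative
   Δz; the field is sign-normalized (flipped if its sum is negative),
   then negative heights — sensor noise — are clamped to zero and the
   clamped fraction reported. Consumed volume cannot be negative.
6. **Integration**: 2-D Delaunay triangulation of the XY projection
   (degenerate zero-area triangles dropped), summing truncated-prism
   volumes V = mean vertex height × projected area against the
   reference plane z = 0. The corrected cloud alone is meshed; the
   bottom surface enters only through the heights.

The change threshold trades detectability against false positives. The
package default is 5 mm, conservative for consumer sensors; when the
noise level σ is known, ~2σ is the recommended setting (2 mm at
σ = 1 mm), paired with the denoise + fill steps above. A bite that
lowers the surface by less than the threshold is invisible — the
characteristic failure of sequential differencing on sticky foods eaten
in thin layers, which shows up as underestimated sequences.

## Nutrition accounting

weight = volume × ρ × μ with ρ in g/cm³ and μ ∈ (0, 1] a packing
factor for stacked food. Signed percent error against a reference
weighing is 100·(reference − estimated)/reference, reported to two
decimals (positive = underestimate). The bundled reference meals carry
effective factors ρ·μ = 0.7 (broccoli — loose florets) and 1.0
(chicken, rice), with density taken as that of water; the general
nutrition-table schema keeps ρ and μ independent
(`category,density_g_cm3,packing_mu,kcal_100g,protein_100g,carb_100g,fat_100g,fiber_100g`,
per-100 g basis as in standard food-composition databases). Mask-based
apportionment splits a weight over food classes by valid-pixel share;
label 0 is reserved for background. Eating speed divides per-interval
consumed weight by elapsed minutes (the first interval counts from meal
start at t = 0); the mean is total weight over total duration. A
"without sequencing" estimate is the single first-frame-vs-last-frame
volume through the same conversion.

## Plate association

Plate signatures hold per-channel 256-bin RGB histograms, estimated
radius, and optionally an externally computed embedding vector (the
package never runs a learned model; embeddings are inputs). Histogram
similarity is 1 − mean-over-channels Hellinger-form Bhattacharyya
distance sqrt(1 − Σ√(pᵢqᵢ)) on normalized histograms — bounded in
[0, 1], so it composes with radius similarity min(r₁,r₂)/max(r₁,r₂) and
cosine similarity rescaled by (s+1)/2. Fusion is a weighted sum
(defaults 0.5/0.3/0.2 with embeddings, renormalized to 0.6/0.4
without); assignment is maximum-total-score Hungarian with pairs below
0.3 left unmatched. A weighted sum was chosen over gating for
transparency; the weights are configuration.

## Synthetic scenes and what they do (not) show

Plates are flat disks 8 mm above the table with an 8 mm-wide rim ring
raised 10 mm (stable exterior features for registration); food mounds
are spherical caps, V = (π·h/6)(3a² + h²), rendered by analytic
ray-surface intersection per pixel with additive Gaussian depth noise
(default σ = 1 mm) and per-surface colors. Bites shrink a cap along its
own sphere — height reduced, base radius recomputed on the same
curvature — so every intermediate state has a closed-form volume and
removed amounts are exact; mass bookkeeping is conserved to machine
precision. Identical seeds give bit-identical frames.

The generator reproduces the geometry and noise level of the target
setting but not: mixed-texture real food surfaces, specular or
low-reflectivity dropouts, occlusion by hands and cutlery, deformable
or transparent containers, or liquids (structured-light sensors see
through clear liquid, so soup removal reads as near-zero change).
Passing synthetic-recovery tests therefore demonstrates the numerical
pipeline is correct under the stated geometry and noise, not that
real-world error will match. The bundled real-meal reference
measurements calibrate expectations: re-derived totals err within
±13 % of the scale weighings while individual sequences reach ±31 %.

The end-to-end evaluation uses one plate (radius 9 cm) with a single cap
mound a = 3 cm, h = 2 cm (32.46 cm³) eaten in five bites. The bite
schedule is front-loaded (cap heights 20 → 17 → 14 → 11 → 8 mm, then
full removal) so every inter-frame surface drop stays resolvable above
σ = 1 mm sensor noise with the 2σ change threshold — the generator's
bites model a normal eater who takes larger bites from a fuller plate.
Frame sizes are the default 640×480; the registration study uses 50
random rigid perturbations (≤ 10°, ≤ 2 cm) of a 3 mm-downsampled
plate-plus-mounds crop (~5000 points).

## Degenerate inputs and tie-breaking

Plane fitting requires ≥ 3 non-collinear points; triangulation requires
≥ 3 non-collinear XY projections; empty depth frames give empty clouds
(not errors); change extraction against an empty later cloud returns
everything with a warning; a failed registration returns an identity
transform flagged unreliable rather than raising, and downstream volume
results carry a `reliable` flag (the CLI exits 4 on unreliable
intervals unless forced). RANSAC ties on inlier count keep the earlier
candidate in seed order; all stochastic stages take explicit seeds
expanded from one global seed by fixed offsets, so every pipeline run is
reproducible from a single integer.
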