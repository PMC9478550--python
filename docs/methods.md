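# Methods

## Model

A damaged section is modeled as a piecewise-affine deformation of the
intact tissue: each connected region of undamaged tissue moves (nearly)
affinely, and the damage line — fold or crack — is a discontinuity locus.
Registration estimates, for every moving-image pixel `x`, an expected
affine

    E_n(A_x) = Σ_{i=1..r} P_n(c_i | x) · A_i

over `r` local affines `A_i`, one per match cluster `c_i`. The posterior
weights come from K-nearest-neighbor densities of the clusters' RANSAC
inliers,

    p_n(x, c_i) = (k_i / n) / V_x,   V_x = d²,
    P_n(c_i | x) = p_n(x, c_i) / Σ_j p_n(x, c_j),

where `n` is the total inlier count, `k_i = min(K, |c_i|)`, and `d` is the
**path distance** from `x` to the k_i-th nearest inlier of `c_i`: the
length of the shortest 8-connected pixel path that avoids damage pixels.
`V_x = d²` is used literally (no geometric prefactor); only density ratios
enter the posteriors, so a constant factor would cancel.

Assumptions: the damage mask is correct and given in the moving frame;
each geodesically connected tissue region is covered by enough matches to
fit at least one affine; deformation within a region is affine to within
the RANSAC threshold.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `grid` | 10 × 10 | extraction patches per section |
| `max_per_patch` | 50 | keypoint cap per patch |
| `confidence_threshold` | 0.015 | minimum detector score (scores normalized to [0, 1]) |
| `k_clusters` | 20 | K-means clusters requested |
| `knn_K` | 3 | density neighbor count K |
| `min_inliers` | 8 | cluster retention cutoff |
| `ransac_threshold_px` | 3.0 px | RANSAC residual threshold |
| `connectivity` | 8 | grid graph connectivity (weights 1, √2) |
| `epsilon_px` | 0.5 px | lower clamp on d before squaring |
| `downscale` | 1 | integer factor for the geodesic/density grid |

The operating point (grid, cap, threshold, k, K) is the method's published
configuration; the remaining values are this implementation's declared
choices. `min_inliers = 8` is at least twice the 3-point minimal affine
sample, rejecting spurious micro-clusters. The RANSAC threshold mirrors the
3-px correct-match radius used in evaluation. `epsilon_px` bounds the
density at sample points, where the raw KNN estimate diverges (d = 0);
0.5 px keeps the estimate effectively winner-take-all at an inlier without
producing infinities. Connectivity 8 with √2 diagonals is chosen because it
approaches Euclidean distance in the no-damage limit, matching the
Euclidean special case of the density; it remains a chamfer metric, so
off-axis distances exceed Euclidean by up to ~8 %.

### Geodesic engine

Wavefront expansion is implemented as an exact priority-queue (Dijkstra)
propagation over the pixel grid, with damage pixels removed from the graph;
distances on barrier or unreachable pixels are +∞. Seeds falling on barrier
pixels are snapped to the nearest free pixel (Euclidean, ties in row-major
order), since labeled masks can overlap detected keypoints by a pixel.

The per-pixel distance to the K-th nearest member of a point set is
computed by a multi-label variant of the same propagation: every pixel may
be settled up to K times, each time from a distinct source point, and a
label is dropped once its pixel holds K settled sources (any dropped label
is dominated by K distinct closer sources at every pixel downstream, so
the result is exact — it equals per-point maps sorted per pixel, at the
cost of O(K) rather than O(#points) grid sweeps). Coincident points count
as distinct sample points.

### Clustering

K-means runs on moving-frame match coordinates under the geodesic metric:
assignment evaluates one wavefront map per centroid at the (pixel-snapped)
match positions; the centroid update is the arithmetic member mean snapped
to the nearest free pixel and is kept only if it does not increase that
cluster's assignment cost, which makes the objective non-increasing even
though a snapped Euclidean mean is not the geodesic median. Empty clusters
reseed to the geodesically farthest match. Initialization is
k-means++-style with geodesic distances, seeded; unreachable matches are
taken first as new centers. RANSAC per cluster uses 3-point minimal
samples, Euclidean reprojection residuals in the reference frame, a
degeneracy guard on the linear part, and a final least-squares refit on the
consensus set.

### Field evaluation and warping

Posteriors are normalized per pixel; where every density is zero (pixels
geodesically unreachable from all clusters, including the damage band
itself), the posterior is assigned one-hot to the cluster with the nearest
single inlier (ties to the lower index), so the field — and the repaired
image — is defined everywhere. Blending is entrywise on the 2 × 3
matrices, equivalent to blending mapped coordinates since the map is
linear in the entries.

The fitted field maps moving → reference (clustering and the mask live in
the moving frame). Warping inverts it numerically: the backward coordinate
at each output pixel starts at the inverse of the field's global
least-squares affine and is refined by 5 fixed-point steps
`x ← x + (y − u(x))` with bilinear sampling of the coordinate map, followed
by bilinear sampling of the moving image. Output pixels whose backward
coordinate leaves the moving image are zero-filled and flagged in a
validity mask. The fixed-point iteration converges when the field's
deviation from its global affine is contractive, which holds for the
near-rigid local affines of section registration; a non-invertible blended
linear part at more than 1 % of pixels raises a warning.

With `downscale = s > 1`, the mask is block-reduced (a coarse pixel is a
barrier if any fine pixel is), densities and posteriors are computed on the
coarse grid in full-resolution pixel units, and the posterior planes are
bilinearly upsampled and renormalized before blending with the
full-resolution affines. The CLI enables `s = 2` automatically for images
with shorter side above 1500 px.

## Synthetic scenes

The generator emulates what the pipeline needs from real damaged sections:
a band-limited texture with gradients in every extraction patch (plus dark
membrane-like arcs and lighter organelle-like blobs), a straight or tilted
damage line, one affine per side, and the damage sign conventions — tissue
moves toward a fold and away from a crack, where "damage displacement" is
`x − T(x)` for the stored moving → reference truth map `T`. The crack gap
is filled with dark debris texture; a fold darkens its band and records
intact tissue with no damaged-frame image in a lost-tissue mask. The mask
band width is the largest normal jump implied by the side affines along
the line (at least 2 px). Scenes whose side affines would move tissue
across the line beyond that band are rejected as geometrically
inconsistent. A blend zone and in-image line endpoints model shallow or
partial damage by interpolating the side affines smoothly.

It deliberately does **not** model staining artifacts, charging, knife
marks, descriptor-breaking appearance change between sections, or
segmentation errors in the mask — so passing tests demonstrate the
geometry of the method (discontinuity recovery, posterior behavior,
exactness of the geodesic engine), not robustness to real-world appearance
noise, which depends mainly on the feature backend used.

The discontinuity benchmark (`benchmark_crack_scene`) uses 256 × 256
scenes with a 10-px gap and sides additionally rotated by ±2° about the
section center: a plain opposite-translation crack can be partially
absorbed by a global affine's shear ramp, whereas physically broken
sections also rotate, which is the regime where a single global transform
genuinely fails. Problem sizes throughout the test suite (32–48 px oracle
grids, 256–320 px scenes, 20 benchmark seeds) were chosen as the smallest
scales at which every property is exercised meaningfully.

## Evaluation

* Correct match: truth-mapped moving keypoint strictly within 3 px of the
  reference keypoint (an error of exactly 3 px is incorrect).
* Area%: image and points rescaled so the shorter side is 1,000 px;
  coverage is the fraction of pixel centers within 35 px of any match
  point, overlaps counted once, rasterized by exact per-pixel distance
  test.
* Patch NCC: zero-lag normalized cross-correlation over non-overlapping
  64 × 64 patches, trailing partial patches dropped. Patches with zero
  variance in either image, or (when a validity mask is supplied)
  containing pixels without registered content, are recorded as 0, flagged,
  and excluded from the mean/std — NCC is undefined there.
* Endpoint error: per-pixel Euclidean deviation between estimated and true
  mapped coordinates, summarized by median/mean/95th percentile outside an
  exclusion zone (typically the dilated damage band, where truth itself is
  occluded).

## Known limitations

* The chamfer (8-connected) metric overestimates Euclidean distance by up
  to ~8 % off-axis; density ratios inherit this anisotropy.
* The classical default backend is not invariant to large rotation or
  scale between sections; the 0.015 threshold is calibrated to its
  [0, 1]-normalized scores and is backend-relative by design.
* The blended field is not guaranteed diffeomorphic; strongly conflicting
  cluster affines can fold the warp (detected only via the determinant
  warning).
* Content inside fold bands is genuinely lost and is not inpainted; the
  field merely places the surviving tissue correctly.
* K-means with a fixed k = 20 can oversegment sparse match sets; clusters
  that end up below `min_inliers` are dropped, so heavily undersampled
  regions fall back to neighboring clusters' affines.
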