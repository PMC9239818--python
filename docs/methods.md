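# Methods

This note records the models, defaults and numerical choices behind
`mriseg`, and what the synthetic experiments do and do not demonstrate.

## Clustering model

Pixels of a 2-D slice are clustered in feature space.  By default the
feature is intensity alone (a 1-D problem); `spatial_weight w > 0`
optionally appends scaled coordinates `(w·row/height, w·col/width)` for
users who want position-aware clustering, but the default is `w = 0` so
the objective is exactly the classical within-cluster scatter
H = Σ_h Σ_{i∈c_h} ‖x_i − c_h‖².

The metric inside H is squared Euclidean: the per-cluster mean update is
the exact minimizer only for that form, which is what guarantees Lloyd's
monotone descent (asserted on every run via the objective trace).  Plain
Euclidean distance is available through `distance()` for inspection but is
not used in the iteration.

Convergence: absolute ΔH ≤ `tol` (default 1e-6) or an unchanged
assignment, with `max_iter` = 100 center updates as a hard stop.  Empty
clusters are re-seeded at the data point farthest from its currently
assigned center (farthest-point policy), never silently dropped; the
re-seeding cannot increase H because an empty center's position does not
contribute to the objective under the current assignment.  All tie-breaks
(nearest center, density ranking, mode merging) resolve to the lowest
index, which makes every deterministic path bit-reproducible.

On zero-noise phantoms the converged H is *numerically* zero rather than
literally zero: the floating-point mean of n identical values can differ
from that value by one ulp, leaving H around 1e-29 on a 256×256 slice.
Tests therefore assert H ≤ 1e-18 together with an exactly-zero error rate.

## Density-peaks initialization

The improved initializer scores every point by the product of

* **local density** ρ_i — the cut-off-kernel count of points within radius
  r of x_i (a Gaussian kernel would be a smooth alternative; the cut-off
  count is kept because it makes the histogram-weighted computation exact);
* **separation** δ_i — the distance to the nearest point of higher
  density, with the global maximum assigned the dataset's largest pairwise
  distance.

Ranking by ρ_i·δ_i (descending) and skipping candidates within r of an
already chosen center yields K centers that are actual data points, one
per intensity mode, with no randomness.  If K exceeds the number of
separated peaks the remaining slots are filled in ranking order.

Two semantic choices matter on quantized or clipped images, where many
pixels share an exact intensity value:

* Points with identical values are one *data object*: zero-distance pairs
  never count as each other's higher-density neighbor, and density ties
  are ordered by first occurrence.  This makes the direct O(n²) path and
  the histogram-weighted path agree exactly, and leaves exactly one global
  density maximum carrying the maximal separation.
* The default radius is the 2% quantile of the **positive** pairwise
  distances (subsampled to 1000 points with a fixed seed for large n).
  Including zero distances would be degenerate: on a noisy slice clipped
  at 0 and 1, duplicated values alone can exceed 2% of all pairs and
  collapse the radius to the smallest representable gap.

Scaling: with more than 100 000 points (or more than 8192 distinct
values) in 1-D, intensities are quantized to 256 levels for the density
ranking — the native resolution of 8-bit images, where the quantization
is the identity — and each selected level is replaced by the nearest
actual data value.  This is why initialization is fast on 512×512 slices.
Multi-feature datasets beyond 8192 points are ranked on a fixed-seed
subsample.

## Traditional baseline

Random initialization draws K distinct pixel *indices* uniformly.  On
quantized images two picks may share a value; the resulting empty cluster
is handled by the farthest-point re-seed.  This is deliberately the
literal "random data objects" scheme: replacing it with sampling over
distinct values would amount to stratified initialization and would erase
the initialization sensitivity the comparison is designed to measure.

## Mean-shift baseline

Flat (uniform) kernel; every distinct data value is a seed; a seed moves
to the mean of the points within `bandwidth` until the displacement is
below 1e-4·bandwidth or 300 iterations.  In 1-D the window means come
from prefix sums over the sorted data, so whole slices are processed
exactly.  Converged positions are merged greedily in seed order with
`merge_tol = bandwidth/2`; each new mode keeps its first representative's
position, so modes stay pairwise more than `merge_tol` apart.  The default
bandwidth is 15% of the intensity range.  Because the number of modes is
data-driven, surplus modes are mapped many-to-one onto truth classes
during evaluation.

The fixed points of this iteration are the stationary points of the
Epanechnikov (shadow-kernel) density estimate, which is what the test
oracle grid-searches.

## Error rate

`error_rate(pred, truth)` = 1 − (matched agreement)/n, where the matching
maximizes agreement over the contingency table: an injective assignment
(scipy's Hungarian solver) when the prediction has at most as many labels
as the truth, otherwise per-prediction-label majority vote, which is the
optimal many-to-one map.  A majority-vote-only mode is not exposed; the
assignment solve is O(K³) on tables no larger than the label counts and is
never a bottleneck.  Runtimes recorded by the comparison harness wrap the
segmentation call only and are informational — they are hardware-bound and
never asserted.

## Phantom generator

A phantom emulates a brain slice as K = 4 intensity classes — regional
background, soft tissue, fat, bone — on [0, 1]:

* class means (0.05, 0.35, 0.65, 0.95): well separated, background darkest;
* area fractions (0.4, 0.3, 0.2, 0.1): unbalanced on purpose, mirroring a
  slice where background dominates and bone is the thinnest class.
  Unequal masses are also what gives the initialization comparison its
  discriminating power — with equal-mass classes, randomly initialized
  Lloyd on 1-D intensities essentially never falls into a bad local
  minimum and all methods coincide at the noise floor;
* geometry: `concentric` nests slightly elliptical rings (background
  outermost), `blobs` thresholds a Gaussian-smoothed random field; both
  assign classes by rank quantiles of a scalar field, so empirical area
  fractions are exact up to ties;
* pixel model: `class_mean[truth] × bias + N(0, noise_sigma)`, clipped to
  [0, 1].  The bias field is a low-order cosine surface
  (1 + A/2·cos(2πr/H)·cos(2πc/W)), disabled by default;
* one seeded generator per phantom, seed recorded in the spec.

Clipping truncates the noise of the extreme classes, which biases their
empirical means inward by about 0.08·σ — well inside the 0.01 tolerance
asserted at σ = 0.05 — and concentrates mass at exactly 0.0 and 1.0,
which is the realistic quantization/saturation behavior that motivated the
positive-distance radius rule above.

What the phantoms do *not* model: partial-volume mixing at tissue
boundaries, spatially correlated (Rician) MR noise, anatomy-shaped class
geometry, and 3-D structure.  Passing results therefore demonstrate
correctness of the algorithms and their relative behavior under controlled
intensity statistics, not clinical-grade performance on real scans.

## Study conditions

* **Separable recovery**: zero-noise, zero-bias 256×256 phantoms are
  exactly 4-valued, so any correct 4-cluster segmentation must reach error
  rate 0; density-initialized k-means and auto-bandwidth mean shift are
  both required to achieve it exactly.
* **Noisy ordering**: twenty 64×64 phantoms (alternating layouts) at
  σ = 0.06, where adjacent class histograms overlap (means 0.3 apart,
  ±3σ = 0.18 per side).  The 64×64 size keeps the twenty-phantom,
  three-method grid fast while leaving ≥ 400 pixels in the smallest
  class.  Under these conditions random initialization misses a small
  class in a large share of runs (mean error ≈ 10%) while the density
  initialization stays at the noise floor (≈ 1%) and mean shift sits in
  between — the qualitative ordering, which is asserted; the printed
  error percentages of any particular clinical dataset are not.
* **Runtime**: two 256×256 and two 512×512 phantoms at σ = 0.05.  The
  density initialization costs a histogram density ranking (~tens of
  milliseconds) but typically converges in ~3 Lloyd iterations versus
  5–40 from random centers, so it is net faster; the difference is
  reported in seconds and never asserted.

## Image I/O conventions

Intensities are normalized by container bit depth (8-bit → /255,
16-bit → /65535), never per-image min–max, so `noise_sigma`, radii and
bandwidths keep their meaning across images.  Coordinates are (row, col),
0-based, row-major; label images store class integers verbatim.  NIfTI
volumes are handled slice-wise (slice axis default: last); integer NIfTI
data is scaled by its dtype's maximum, float data is assumed already in
[0, 1] and clipped.  RGB input is rejected rather than silently converted.

## Known limitations

* Intensity-only features make the segmentation blind to position; the
  optional spatial weight is provided but untuned.
* K must be supplied; the package deliberately offers no model selection.
* The density profile is O(m²) in the number of distinct feature vectors;
  multi-feature datasets beyond the subsample cap lose exactness.
* Mean shift's greedy first-fit merging depends on seed order (ascending
  value), which is deterministic but not the only defensible choice.
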