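# mriseg

Density-initialized k-means segmentation of grayscale brain-MRI slices,
with a traditional randomly-initialized k-means and a flat-kernel
mean-shift baseline, an error-rate evaluator with optimal label matching,
and a synthetic brain-phantom generator with per-pixel ground truth.

The package is for image-analysis practitioners who want to study how the
*initialization* of k-means affects MRI tissue segmentation — bone, soft
tissue, fat and regional background on a single slice — without access to
patient data: the phantom module supplies verifiable stand-ins.

## The methods

**k-means.** A slice's pixels form the dataset Y = {x_1 … x_n} (intensity
features in [0, 1]).  Given K centers M = {c_1 … c_K}, Lloyd iteration
alternates nearest-center assignment and the mean update
c_h = (1/n_h) Σ_{i ∈ h} x_i^h, monotonically decreasing the within-cluster
objective

    H = Σ_h Σ_{i ∈ c_h} ‖x_i − c_h‖²

until the decrease falls below `tol` or the assignment repeats.  The
traditional variant draws the K initial centers as random data points,
which can leave small tissue classes without a nearby center and trap the
iteration in a poor local minimum.

**Density-peaks initialization** (the "improved" variant).  Each point gets
a local density ρ_i (count of points within a radius r, by default the 2%
quantile of the positive pairwise distances) and a separation δ_i (distance
to the nearest point of higher density).  The K initial centers are the
data points with the largest ρ_i·δ_i products — dense *and* mutually
separated — so every intensity mode receives exactly one center,
deterministically.  For whole slices the computation runs on the intensity
histogram with per-bin multiplicities, which keeps 512×512 images fast.

**Mean shift** (comparator).  Every distinct intensity seeds a flat-kernel
ascent to the mean of its bandwidth-neighborhood (default bandwidth: 15% of
the intensity range); converged positions are merged into modes that define
the segments.

**Evaluation.**  Because cluster indices are arbitrary, the segmentation
error rate is the misclassified-pixel fraction *after* the
prediction-to-truth label mapping that maximizes agreement (assignment
problem; many-to-one for surplus mean-shift modes).

## Worked example

```sh
$ mriseg phantom --size 256 --noise 0.06 --seed 4 --out phantoms
wrote 1 phantom(s) to phantoms

$ mriseg segment --input phantoms/phantom_00_concentric_256x256.png \
    --output labels.png --method kmeans-density --k 4
segmented phantoms/phantom_00_concentric_256x256.png -> labels.png (kmeans-density)

$ mriseg eval --pred labels.png --truth phantoms/phantom_00_concentric_256x256_truth.png
error_rate: 0.008987

$ mriseg segment --input phantoms/phantom_00_concentric_256x256.png \
    --output labels_rand.png --method kmeans --k 4 --seed 2
$ mriseg eval --pred labels_rand.png --truth phantoms/phantom_00_concentric_256x256_truth.png
error_rate: 0.275009
```

The phantom has four tissue classes (area fractions 0.4/0.3/0.2/0.1,
intensity means 0.05/0.35/0.65/0.95) under Gaussian noise σ = 0.06, so the
class histograms overlap.  Density-initialized k-means places one center
per intensity mode and misclassifies 0.9% of pixels (noise-induced
overlap); the randomly initialized run with this seed starts two centers
inside one class, merges two tissues, and misclassifies 27.5%.  The
multi-method grid is available as one command:

```sh
mriseg compare --preset noisy_ordering --k 4 --out report.json --csv report.csv
```

which writes per-cell error rates and runtimes plus per-method means.

The same operations are available as library functions
(`generate_phantom`, `segment_image`, `error_rate`, `run_comparison`, …);
see the module docstrings and `docs/methods.md`.

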