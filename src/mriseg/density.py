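"""Density-based selection of initial k-means centers.

Instead of drawing initial centers at random, centers are chosen as actual
data objects of high local density that are mutually well separated.  Local
density is a cut-off-kernel neighbour count; each point also carries a
*separation*, the distance to the nearest point of higher density
(density-peaks style).  Centers are ranked by the product
density x separation, which favours points that are both dense and far from
any denser region, so no two centers land in the same dense blob.

For intensity-only image features the computation runs on the value
histogram (distinct values with multiplicities) rather than on every pixel,
which is exactly equivalent and makes the method fast on 512x512 slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .kmeans import Dataset, _as_points

__all__ = [
    "DensityProfile",
    "local_density",
    "select_initial_centers",
    "auto_radius",
    "density_init_centers",
]

#: intensity levels of the histogram fast path (8-bit image resolution)
HIST_LEVELS = 256
#: above this many points, 1-D features are quantized to HIST_LEVELS for
#: density estimation
FAST_PATH_N = 100_000
#: hard cap on distinct values entering the O(m^2) density profile
MAX_EXACT_UNIQUE = 8192
_EPS_RADIUS = 1e-6


@dataclass
class DensityProfile:
    """Per-point local density and separation at a given radius.

    ``density[i]`` counts the points within ``radius`` of point i (the point
    itself included, with multiplicity).  ``separation[i]`` is the distance
    to the nearest point of higher density; the global density maximum gets
    the maximum pairwise distance of the dataset.  Density ties are ordered
    by first occurrence, so exactly one point carries the maximal separation.
    """

    density: np.ndarray
    separation: np.ndarray
    radius: float


def _compress(points: np.ndarray):
    """Distinct rows with multiplicities and first-occurrence indices."""
    if points.shape[1] == 1:  # axis-based unique is needlessly slow in 1-D
        uniq, first, inverse, counts = np.unique(
            points[:, 0], return_index=True, return_inverse=True, return_counts=True
        )
        return uniq[:, None], first, inverse, counts
    uniq, first, inverse, counts = np.unique(
        points, axis=0, return_index=True, return_inverse=True, return_counts=True
    )
    return uniq, first, np.asarray(inverse).ravel(), counts


def _profile_on_values(vals: np.ndarray, weights: np.ndarray, first: np.ndarray, radius: float):
    """Density/separation on value rows; O(m^2) in the row count.

    Rows at distance zero are the same data object and never count as each
    other's higher-density neighbour; density ties are broken toward the
    earlier first occurrence, so exactly one value (the tie-broken global
    maximum) carries the max-pairwise-distance separation.
    """
    m = vals.shape[0]
    dmat = cdist(vals, vals)
    density = (dmat <= radius) @ weights
    dmax = dmat.max()
    separation = np.empty(m)
    order = np.lexsort((first, -density))
    for pos in range(m):
        i = order[pos]
        cand = dmat[i, order[:pos]]
        cand = cand[cand > 0]
        separation[i] = cand.min() if cand.size else dmax
    return density, separation


def local_density(data, radius: float, method: str = "auto") -> DensityProfile:
    """Cut-off-kernel local density and density-peaks separation per point.

    ``method`` is "auto"/"compressed" (compute on distinct values with
    multiplicities — exact) or "direct" (O(n^2) on the raw points, for
    verification).
    """
    points = data.points if isinstance(data, Dataset) else _as_points(data)
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if method == "direct":
        n = points.shape[0]
        _, first, inverse, _ = _compress(points)
        density, separation = _profile_on_values(
            points, np.ones(n), first[inverse], radius
        )
        return DensityProfile(density, separation, radius)
    if method not in ("auto", "compressed"):
        raise ValueError(f"unknown method {method!r}")
    uniq, first, inverse, counts = _compress(points)
    density_u, separation_u = _profile_on_values(
        uniq, counts.astype(np.float64), first, radius
    )
    return DensityProfile(density_u[inverse], separation_u[inverse], radius)


def select_initial_centers(data, k: int, radius: float | None = None) -> np.ndarray:
    """Pick K data points ranked by density x separation, descending.

    Candidates within ``radius`` of an already chosen center are skipped
    unless K exceeds the number of separated peaks, in which case the
    remaining slots are filled in ranking order.  The result is deterministic
    (no RNG) and every returned center is a member of the dataset.
    """
    points = data.points if isinstance(data, Dataset) else _as_points(data)
    if radius is None:
        radius = auto_radius(points)
    if radius <= 0:
        raise ValueError("radius must be > 0")
    uniq, first, _, counts = _compress(points)
    m = uniq.shape[0]
    if not 1 <= k <= m:
        raise ValueError(f"K={k} exceeds the {m} distinct points")
    density, separation = _profile_on_values(
        uniq, counts.astype(np.float64), first, radius
    )
    gamma = density * separation
    order = np.lexsort((first, -gamma))
    chosen: list[int] = []
    for i in order:
        if len(chosen) == k:
            break
        if all(np.linalg.norm(uniq[i] - uniq[j]) > radius for j in chosen):
            chosen.append(int(i))
    if len(chosen) < k:  # fewer separated peaks than K: fill in ranking order
        for i in order:
            if len(chosen) == k:
                break
            if int(i) not in chosen:
                chosen.append(int(i))
    return uniq[chosen]


def auto_radius(
    data,
    quantile: float = 0.02,
    max_sample: int = 1000,
    seed: int = 0,
) -> float:
    """Neighborhood radius as a low quantile of the pairwise distances.

    Uses the 2% quantile of the *positive* pairwise distances by default
    (zero distances belong to duplicated values — the same data object — and
    on clipped or quantized images they can swamp the low quantiles); when
    n > max_sample the distances are estimated on a fixed-seed subsample.
    Degenerate data (all points identical) falls back to a small epsilon.
    """
    points = data.points if isinstance(data, Dataset) else _as_points(data)
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if n > max_sample:
        idx = np.random.default_rng(seed).permutation(n)[:max_sample]
        points = points[np.sort(idx)]
    dists = pdist(points)
    dists = dists[dists > 0]
    if dists.size == 0:
        return _EPS_RADIUS
    return float(np.quantile(dists, quantile))


def density_init_centers(data, k: int, radius: float | str | None = "auto") -> np.ndarray:
    """High-level initializer used by the segmentation pipeline.

    Resolves ``radius`` ("auto" or a number).  Large intensity-only datasets
    (d = 1 with n > FAST_PATH_N or more than MAX_EXACT_UNIQUE distinct
    values) are quantized to HIST_LEVELS levels for the density ranking;
    each selected level is then replaced by the nearest actual data value so
    centers remain dataset members.  Large multi-feature datasets rank
    density on a fixed-seed subsample of MAX_EXACT_UNIQUE points.
    """
    points = data.points if isinstance(data, Dataset) else _as_points(data)
    if radius in (None, "auto"):
        radius = auto_radius(points)
    radius = float(radius)
    n, d = points.shape
    if d == 1:
        vals = np.unique(points[:, 0])
        if n > FAST_PATH_N or vals.size > MAX_EXACT_UNIQUE:
            q = np.round(points * (HIST_LEVELS - 1)) / (HIST_LEVELS - 1)
            picked = select_initial_centers(q, k, radius)
            idx = np.clip(np.searchsorted(vals, picked[:, 0]), 0, vals.size - 1)
            # nearest actual value to each quantized pick (check the left
            # neighbor as well)
            lo = np.clip(idx - 1, 0, vals.size - 1)
            better = np.abs(vals[lo] - picked[:, 0]) < np.abs(vals[idx] - picked[:, 0])
            idx[better] = lo[better]
            return vals[idx][:, None]
        return select_initial_centers(points, k, radius)
    if n > MAX_EXACT_UNIQUE:
        idx = np.random.default_rng(0).permutation(n)[:MAX_EXACT_UNIQUE]
        return select_initial_centers(points[np.sort(idx)], k, radius)
    return select_initial_centers(points, k, radius)
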