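"""Independent reference computations used only by the tests.

These deliberately avoid the package's own code paths: dynamic programming
for exact 1-D k-means, double loops for objectives and densities, and
exhaustive permutation search for label matching.
"""

from itertools import permutations

import numpy as np


def dp_kmeans_1d(values: np.ndarray, k: int) -> float:
    """Exact optimal 1-D k-means objective (squared Euclidean) by dynamic
    programming over sorted data; O(k n^2)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    p1 = np.concatenate([[0.0], np.cumsum(x)])
    p2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def interval_cost(i: int, j: int) -> float:  # points i..j inclusive
        cnt = j - i + 1
        s = p1[j + 1] - p1[i]
        return (p2[j + 1] - p2[i]) - s * s / cnt

    inf = float("inf")
    dp = np.full((k + 1, n + 1), inf)
    dp[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            dp[kk, j] = min(
                dp[kk - 1, i] + interval_cost(i, j - 1) for i in range(kk - 1, j)
            )
    return float(dp[k, n])


def brute_objective(points: np.ndarray, centers: np.ndarray, assignment) -> float:
    total = 0.0
    for i, a in enumerate(assignment):
        total += float(np.sum((points[i] - centers[a]) ** 2))
    return total


def brute_assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    out = np.empty(len(points), dtype=int)
    for i, p in enumerate(points):
        dists = [float(np.sum((p - c) ** 2)) for c in centers]
        out[i] = int(np.argmin(dists))
    return out


def brute_density(points: np.ndarray, radius: float):
    """O(n^2) cut-off density and strictly-higher-density separation
    (density ties broken toward the lower index)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    density = (d <= radius).sum(axis=1).astype(float)
    separation = np.empty(n)
    for i in range(n):
        higher = [
            j
            for j in range(n)
            if density[j] > density[i] or (density[j] == density[i] and j < i)
        ]
        separation[i] = d[i, higher].min() if higher else d.max()
    return density, separation


def brute_min_error(pred: np.ndarray, truth: np.ndarray) -> float:
    """Minimum misclassification fraction over all injective label
    permutations (requires equal label counts)."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    plabels = np.unique(pred)
    tlabels = np.unique(truth)
    assert plabels.size == tlabels.size
    best = pred.size
    for perm in permutations(tlabels):
        mapping = dict(zip(plabels, perm))
        mis = int(np.sum(np.vectorize(mapping.get)(pred) != truth))
        best = min(best, mis)
    return best / pred.size


def epanechnikov_kde_maxima(x: np.ndarray, h: float, step: float = 2e-4):
    """Local maxima of the Epanechnikov KDE (the shadow kernel whose
    stationary points are the flat-kernel mean-shift fixed points), located
    by dense grid search."""
    x = np.asarray(x, dtype=float).ravel()
    grid = np.arange(x.min() - h, x.max() + h + step, step)
    u = (grid[:, None] - x[None, :]) / h
    kde = np.clip(1.0 - u**2, 0.0, None).sum(axis=1)
    interior = np.arange(1, grid.size - 1)
    is_max = (kde[interior] >= kde[interior - 1]) & (kde[interior] >= kde[interior + 1])
    # collapse plateaus of equal value to their center
    maxima = []
    run: list[int] = []
    for idx, flag in zip(interior, is_max):
        if flag and kde[idx] > 0:
            if run and idx != run[-1] + 1:
                maxima.append(grid[run[len(run) // 2]])
                run = []
            run.append(idx)
        elif run:
            maxima.append(grid[run[len(run) // 2]])
            run = []
    if run:
        maxima.append(grid[run[len(run) // 2]])
    return np.array(maxima)
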