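"""Lloyd-style k-means machinery, independent of center initialization.

The clustering objective is the within-cluster scatter

    H = sum_h sum_{i in cluster h} d(x_i, c_h),

with squared Euclidean distance by default, minimized by alternating
nearest-center assignment and per-cluster mean updates.  All tie-breaks
go to the lowest index so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Dataset",
    "ClusterModel",
    "distance",
    "assign_points",
    "compute_objective",
    "update_centers",
    "run_kmeans",
    "random_init",
]

_METRICS = ("sqeuclidean", "euclidean")


def _as_points(x) -> np.ndarray:
    """Coerce input to an (n, d) float64 array; 1-D input becomes (n, 1)."""
    pts = np.asarray(x, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("dataset must be a non-empty (n, d) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("dataset contains non-finite values")
    return pts


@dataclass
class Dataset:
    """Flattened feature set Y = {x_1 .. x_n} fed to clustering.

    ``points`` is (n, d); when built from an image the rows are the pixels in
    row-major order and ``image_shape`` records (height, width) so labels can
    be mapped back onto the raster.
    """

    points: np.ndarray
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if self.image_shape is not None:
            h, w = self.image_shape
            if h * w != self.n:
                raise ValueError("image_shape inconsistent with number of points")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @classmethod
    def from_image(cls, pixels: np.ndarray, spatial_weight: float = 0.0) -> "Dataset":
        """Build the pixel feature set from a 2-D intensity raster.

        With ``spatial_weight`` w > 0 each pixel's features are
        (intensity, w*row/height, w*col/width); with w = 0 (default) the
        feature is intensity alone.
        """
        pixels = np.asarray(pixels, dtype=np.float64)
        if pixels.ndim != 2:
            raise ValueError("expected a 2-D grayscale image")
        h, w = pixels.shape
        feats = pixels.reshape(-1, 1)
        if spatial_weight > 0:
            rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            feats = np.column_stack(
                [
                    feats[:, 0],
                    spatial_weight * rr.ravel() / h,
                    spatial_weight * cc.ravel() / w,
                ]
            )
        return cls(feats, image_shape=(h, w))


@dataclass
class ClusterModel:
    """Fitted model: K centers, per-point assignment and the objective trace."""

    centers: np.ndarray
    assignment: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_per_cluster: np.ndarray | None = None
    converged: bool = False
    iterations: int = 0

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]

    def labels_as_image(self, shape: tuple[int, int]) -> np.ndarray:
        return self.assignment.reshape(shape)

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "objective_trace": [float(v) for v in self.objective_trace],
            "n_per_cluster": None
            if self.n_per_cluster is None
            else self.n_per_cluster.tolist(),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
        }


def distance(a, b, metric: str = "sqeuclidean") -> float:
    """Distance between two feature vectors (default squared Euclidean)."""
    a = np.atleast_1d(np.asarray(a, dtype=np.float64))
    b = np.atleast_1d(np.asarray(b, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    sq = float(np.sum((a - b) ** 2))
    return sq if metric == "sqeuclidean" else float(np.sqrt(sq))


def _pairwise(points: np.ndarray, centers: np.ndarray, metric: str) -> np.ndarray:
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    return cdist(points, centers, metric=metric)


def assign_points(data, centers, metric: str = "sqeuclidean") -> np.ndarray:
    """Map every point to its nearest center; ties go to the lowest index."""
    points = data.points if isinstance(data, Dataset) else _as_points(data)
    centers = _as_points(centers)
    if centers.shape[1] != points.shape[1]:
        raise ValueError("centers and points have different dimensionality")
    # np.argmin returns the first (lowest-index) minimizer, the documented
    # tie-break.
    return np.argmin(_pairwise(points, centers, metric), axis=1)


def compute_objective(data, centers, assignment, metric: str = "sqeuclidean") -> float:
    """Within-cluster scatter H = sum_h sum_{i in c_h} d(x_i, c_h)."""
    points = data.points if isinstance(data, Dataset) else _as_points(data)
    centers = _as_points(centers)
    assignment = np.asarray(assignment)
    if assignment.shape[0] != points.shape[0]:
        raise ValueError("assignment does not cover all points")
    diff = points - centers[assignment]
    sq = np.einsum("ij,ij->i", diff, diff)
    if metric == "euclidean":
        return float(np.sum(np.sqrt(sq)))
    return float(np.sum(sq))


def update_centers(data, assignment, n_clusters: int | None = None) -> np.ndarray:
    """Move each center to the mean of its members.

    An empty cluster is re-seeded at the data point farthest from the center
    it is currently assigned to (farthest-point policy); once a point seeds a
    cluster it is excluded from seeding further empty clusters.  Ties go to
    the lowest point index.
    """
    points = data.points if isinstance(data, Dataset) else _as_points(data)
    assignment = np.asarray(assignment)
    k = int(n_clusters if n_clusters is not None else assignment.max() + 1)
    centers = np.zeros((k, points.shape[1]))
    counts = np.bincount(assignment, minlength=k)
    for h in range(k):
        if counts[h] > 0:
            centers[h] = points[assignment == h].mean(axis=0)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        diff = points - centers[assignment]
        dist_to_own = np.einsum("ij,ij->i", diff, diff)
        for h in empty:
            far = int(np.argmax(dist_to_own))
            centers[h] = points[far]
            dist_to_own[far] = -1.0  # do not reuse this point
    return centers


def run_kmeans(
    data,
    init_centers,
    max_iter: int = 100,
    tol: float = 1e-6,
    metric: str = "sqeuclidean",
) -> ClusterModel:
    """Lloyd iteration from the given initial centers.

    Alternates assignment and mean update until the decrease in H is <= tol,
    the assignment repeats, or ``max_iter`` center updates have been made.
    The objective trace (H after each assignment) is non-increasing.
    """
    points = data.points if isinstance(data, Dataset) else _as_points(data)
    centers = _as_points(np.array(init_centers, dtype=np.float64, copy=True))
    k = centers.shape[0]
    if not 1 <= k <= points.shape[0]:
        raise ValueError(f"K={k} must satisfy 1 <= K <= n={points.shape[0]}")
    if tol < 0:
        raise ValueError("tol must be >= 0")

    trace: list[float] = []
    prev_assign: np.ndarray | None = None
    converged = False
    updates = 0
    while True:
        assign = assign_points(points, centers, metric)
        trace.append(compute_objective(points, centers, assign, metric))
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            converged = True
            break
        if len(trace) >= 2 and trace[-2] - trace[-1] <= tol:
            converged = True
            break
        if updates >= max_iter:
            break
        centers = update_centers(points, assign, k)
        prev_assign = assign
        updates += 1

    return ClusterModel(
        centers=centers,
        assignment=assign,
        objective_trace=trace,
        n_per_cluster=np.bincount(assign, minlength=k),
        converged=converged,
        iterations=updates,
    )


def random_init(data, k: int, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Traditional initialization: K data objects (points) drawn at random.

    K distinct point *indices* are sampled uniformly; on quantized images
    two picks may share the same intensity value, which is the documented
    weakness of the traditional algorithm (coincident centers leave a
    cluster empty and trigger the farthest-point re-seed during Lloyd
    iteration).
    """
    points = data.points if isinstance(data, Dataset) else _as_points(data)
    if not 1 <= k <= points.shape[0]:
        raise ValueError(f"K={k} must satisfy 1 <= K <= n={points.shape[0]}")
    rng = np.random.default_rng(rng)
    idx = rng.choice(points.shape[0], size=k, replace=False)
    return points[np.sort(idx)]
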