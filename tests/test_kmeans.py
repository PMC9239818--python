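"""Clustering core: objective, assignment, mean update, Lloyd descent."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mriseg import (
    Dataset,
    assign_points,
    compute_objective,
    distance,
    random_init,
    run_kmeans,
    update_centers,
)
from oracles import brute_assign, brute_objective, dp_kmeans_1d


@pytest.mark.parametrize(
    "a,b,metric,expected",
    [
        ([0.0], [0.0], "sqeuclidean", 0.0),
        ([0.0], [3.0], "sqeuclidean", 9.0),
        ([1.0, 2.0], [4.0, 6.0], "sqeuclidean", 25.0),
        ([1.0, 2.0], [4.0, 6.0], "euclidean", 5.0),
    ],
)
def test_distance_closed_forms(a, b, metric, expected):
    assert distance(a, b, metric) == pytest.approx(expected)
    assert distance(b, a, metric) == pytest.approx(expected)  # symmetry


def test_distance_dimension_mismatch():
    with pytest.raises(ValueError, match="dimension"):
        distance([1.0], [1.0, 2.0])


def test_objective_trivial_cases():
    assert compute_objective([[5.0]], [[5.0]], [0]) == 0.0
    # points {0, 2} both assigned to center 1 -> 1 + 1
    assert compute_objective([[0.0], [2.0]], [[1.0]], [0, 0]) == pytest.approx(2.0)


def test_objective_matches_double_loop(rng):
    pts = rng.random((20, 2))
    centers = rng.random((3, 2))
    assign = rng.integers(0, 3, size=20)
    ours = compute_objective(pts, centers, assign)
    assert ours == pytest.approx(brute_objective(pts, centers, assign), rel=1e-12)


def test_assign_nearest_and_tie_to_lowest_index():
    assert assign_points([[0.9]], [[0.0], [1.0]])[0] == 1
    assert assign_points([[0.5]], [[0.0], [1.0]])[0] == 0  # exact tie


def test_assign_matches_exhaustive_search(rng):
    pts = rng.random((100, 3))
    centers = rng.random((4, 3))
    np.testing.assert_array_equal(
        assign_points(pts, centers), brute_assign(pts, centers)
    )


def test_update_centers_is_cluster_mean():
    centers = update_centers([[1.0], [3.0], [7.0]], [0, 0, 1], n_clusters=2)
    np.testing.assert_allclose(centers, [[2.0], [7.0]])


def test_update_centers_reseeds_empty_cluster_at_farthest_point():
    pts = [[0.0], [1.0], [2.0], [10.0]]
    centers = update_centers(pts, [0, 0, 0, 0], n_clusters=2)
    np.testing.assert_allclose(centers[0], [3.25])  # mean of all members
    np.testing.assert_allclose(centers[1], [10.0])  # farthest from its center


def test_run_kmeans_fixed_point_converges_in_one_update():
    pts = [[0.2]] * 5 + [[0.8]] * 5
    model = run_kmeans(pts, [[0.2], [0.8]])
    assert model.converged and model.iterations == 1
    assert model.objective == 0.0


def test_run_kmeans_two_cluster_enumeration_optimum():
    # all 2-partitions of {0, .1, .9, 1} give H >= 0.01; split at 0.5 attains it
    pts = [[0.0], [0.1], [0.9], [1.0]]
    model = run_kmeans(pts, [[0.3], [0.7]])
    np.testing.assert_allclose(np.sort(model.centers[:, 0]), [0.05, 0.95])
    assert model.objective == pytest.approx(0.01)
    assert np.array_equal(model.n_per_cluster, [2, 2])


def test_run_kmeans_validates_k_and_finiteness():
    with pytest.raises(ValueError, match="K="):
        run_kmeans([[1.0]], [[0.0], [1.0]])
    with pytest.raises(ValueError, match="finite"):
        run_kmeans([[np.nan]], [[0.0]])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(5, 60),
    k=st.integers(1, 5),
    d=st.integers(1, 3),
)
def test_objective_trace_monotone_descent(seed, n, k, d):
    """Lloyd's descent property: H never increases across iterations."""
    rng = np.random.default_rng(seed)
    pts = rng.random((n, d))
    init = random_init(pts, k, rng)
    model = run_kmeans(pts, init)
    trace = np.asarray(model.objective_trace)
    assert np.all(np.diff(trace) <= 1e-12 * (1.0 + trace[0]))
    assert model.iterations <= 100


def test_permutation_equivariance(rng):
    pts = rng.random((80, 2))
    init = random_init(pts, 4, rng)
    perm = np.array([2, 0, 3, 1])
    a = run_kmeans(pts, init)
    b = run_kmeans(pts, init[perm])
    assert a.objective == pytest.approx(b.objective, rel=1e-12)
    # labels correspond through the permutation (continuous data: no ties)
    np.testing.assert_array_equal(perm[b.assignment], a.assignment)


def test_best_distinct_init_reaches_dp_optimum(rng):
    """On small 1-D data, the best Lloyd run over all K-subsets of distinct
    points attains the exact DP optimum."""
    for n, k in [(6, 2), (8, 3), (9, 2)]:
        x = rng.random(n)
        best = min(
            run_kmeans(x[:, None], np.array(c)[:, None]).objective
            for c in combinations(np.unique(x), k)
        )
        assert best == pytest.approx(dp_kmeans_1d(x, k), rel=1e-10, abs=1e-12)


def test_final_objective_matches_sklearn_from_same_init(rng):
    """Independent cross-check: scikit-learn's Lloyd iteration from the same
    initial centers reaches the same local optimum."""
    sklearn_cluster = pytest.importorskip("sklearn.cluster")
    pts = rng.random((200, 2))
    init = random_init(pts, 5, rng)
    ours = run_kmeans(pts, init, max_iter=300, tol=0.0)
    km = sklearn_cluster.KMeans(
        n_clusters=5, init=init, n_init=1, max_iter=300, tol=0.0, algorithm="lloyd"
    ).fit(pts)
    assert ours.objective == pytest.approx(km.inertia_, rel=1e-9)


def test_dataset_from_image_row_major_and_spatial_features():
    img = np.array([[0.0, 0.25], [0.5, 1.0]])
    ds = Dataset.from_image(img)
    np.testing.assert_allclose(ds.points[:, 0], [0.0, 0.25, 0.5, 1.0])
    ds2 = Dataset.from_image(img, spatial_weight=1.0)
    assert ds2.dim == 3
    np.testing.assert_allclose(ds2.points[3], [1.0, 0.5, 0.5])


def test_random_init_samples_data_points_and_is_seeded(rng):
    pts = rng.random((50, 2))
    init = random_init(pts, 3, 42)
    assert all(any(np.array_equal(c, p) for p in pts) for c in init)
    np.testing.assert_array_equal(init, random_init(pts, 3, 42))
    with pytest.raises(ValueError, match="K="):
        random_init(pts, 51, 0)


def test_coincident_random_centers_still_yield_k_clusters():
    # two initial centers share the value 0.1: the emptied cluster must be
    # re-seeded rather than silently dropping K
    pts = np.array([[0.1]] * 20 + [[0.9]] * 20)
    model = run_kmeans(pts, [[0.1], [0.1]])
    assert np.unique(model.assignment).size == 2
    assert model.objective == pytest.approx(0.0, abs=1e-18)
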