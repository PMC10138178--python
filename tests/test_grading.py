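import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from paddygrade.grading import (PIndex, assign_grades, compute_p_index, kmeans,
                                kmedoids, nearest_grade, scan_k, grade_trajectory)
from paddygrade.synthetic import (StorageCondition, default_params, simulate_series,
                                  GrowthParams)


# ------------------------------------------------------------------- P index
def test_p_index_arithmetic_means():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    fc = np.array([5.0, 6.0, 7.0])
    p = compute_p_index(obs, fc, j=3, n=3)
    assert (p.past_mean, p.current, p.future_mean) == (2.0, 4.0, 6.0)


def test_p_index_constant_and_window_one():
    obs = np.full(10, 3.0)
    p = compute_p_index(obs, np.full(5, 3.0), j=5, n=3)
    assert (p.past_mean, p.current, p.future_mean) == (3.0, 3.0, 3.0)
    p1 = compute_p_index(np.array([1.0, 2.0]), np.array([9.0]), j=1, n=1)
    assert (p1.past_mean, p1.current, p1.future_mean) == (1.0, 2.0, 9.0)


def test_p_index_errors_name_the_short_side():
    obs = np.arange(1.0, 6.0)
    with pytest.raises(ValueError, match="history"):
        compute_p_index(obs, np.ones(5), j=2, n=3)
    with pytest.raises(ValueError, match="horizon"):
        compute_p_index(obs, np.ones(2), j=4, n=3)
    with pytest.raises(ValueError):
        PIndex(past_mean=-1.0, current=0.0, future_mean=0.0, n=1)


# ------------------------------------------------------------------ k-medoids
def test_kmedoids_k_equals_n_gives_zero_cost():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(5, 3))
    res = kmedoids(x, 5, seed=1)
    assert res.cost == 0.0
    assert sorted(res.medoid_indices.tolist()) == list(range(5))


def test_kmedoids_two_tight_triples_split_correctly():
    rng = np.random.default_rng(1)
    x = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(20, 0.1, (3, 2))])
    for seed in range(5):
        res = kmedoids(x, 2, seed=seed)
        groups = {tuple(sorted(np.where(res.labels == c)[0])) for c in (1, 2)}
        assert groups == {(0, 1, 2), (3, 4, 5)}


def test_kmedoids_matches_exhaustive_optimum_small_n():
    rng = np.random.default_rng(2)
    for trial in range(20):
        n = int(rng.integers(4, 9))
        x = rng.normal(size=(n, 3))
        best = min(cdist(x, x[list(pair)]).min(axis=1).sum()
                   for pair in itertools.combinations(range(n), 2))
        res = kmedoids(x, 2, seed=trial, restarts=10)
        assert res.cost == pytest.approx(best)


def test_kmedoids_medoids_are_input_points_and_k_validated():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(10, 3))
    res = kmedoids(x, 3, seed=0)
    assert all(any(np.array_equal(m, xi) for xi in x) for m in res.centers)
    assert set(res.labels) <= {1, 2, 3}
    with pytest.raises(ValueError):
        kmedoids(x, 1, seed=0)
    with pytest.raises(ValueError):
        kmedoids(x, 11, seed=0)


# -------------------------------------------------------------------- k-means
def test_kmeans_exact_on_coincident_groups():
    x = np.repeat(np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 1.0]]), 4, axis=0)
    res = kmeans(x, 3, seed=0)
    found = {tuple(c) for c in np.round(res.centers, 9)}
    assert found == {(0.0, 0.0), (5.0, 5.0), (9.0, 1.0)}
    assert res.cost == pytest.approx(0.0)


def test_kmeans_squared_cost_nonincreasing_per_sweep():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(60, 3))
    res = kmeans(x, 4, seed=1)
    hist = np.array(res.cost_history)
    assert np.all(np.diff(hist) <= 1e-9)


def test_kmedoids_at_least_as_good_as_kmeans_with_outliers(planted_blobs):
    """With gross outliers, medoid centers resist contamination."""
    pts, _, _ = planted_blobs
    rng = np.random.default_rng(5)
    contaminated = np.vstack([pts, rng.uniform(30, 45, size=(4, 3))])
    med = kmedoids(contaminated, 3, seed=2)
    km = kmeans(contaminated, 3, seed=2)
    assert km.silhouette <= med.silhouette + 0.05


# --------------------------------------------------------------------- scan_k
def test_scan_k_selects_three_on_planted_components(planted_blobs):
    pts, truth, _ = planted_blobs
    for alg in ("kmedoids", "kmeans"):
        selected, scores, results = scan_k(pts, alg, range(3, 8), seed=1)
        assert selected == 3
        assert all(-1.0 <= v <= 1.0 for v in scores.values())
        assert adjusted_rand_score(truth, results[3].labels) >= 0.9


def test_scan_k_two_blobs_and_validation():
    rng = np.random.default_rng(6)
    x = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(8, 0.3, (10, 2))])
    selected, scores, _ = scan_k(x, "kmedoids", [2], seed=0)
    assert selected == 2 and set(scores) == {2}
    with pytest.raises(ValueError):
        scan_k(x, "kmedoids", [], seed=0)
    with pytest.raises(ValueError):
        scan_k(x, "dbscan", [2], seed=0)


# -------------------------------------------------------------------- grading
def test_assign_grades_orders_by_center_norm():
    pts = np.vstack([np.full((4, 3), 9.0), np.full((4, 3), 1.0), np.full((5, 3), 5.0)])
    res = kmedoids(pts, 3, seed=0)
    grades = assign_grades(res)
    norms = np.linalg.norm(grades.centers, axis=1)
    assert np.all(np.diff(norms) > 0)
    assert grades.counts.sum() == len(pts)
    # level 1 must be the cluster at (1,1,1), level 3 the one at (9,9,9)
    assert np.allclose(grades.centers[0], 1.0)
    assert np.allclose(grades.centers[2], 9.0)
    lv = {tuple(p): g for p, g in zip(pts, grades.levels)}
    assert lv[(1.0, 1.0, 1.0)] == 1 and lv[(9.0, 9.0, 9.0)] == 3
    with pytest.raises(ValueError):
        assign_grades(kmedoids(pts, 2, seed=0))


def test_assign_grades_invariant_to_label_permutation():
    rng = np.random.default_rng(7)
    pts = np.vstack([rng.normal(c, 0.2, (6, 3)) for c in (2.0, 6.0, 12.0)])
    res = kmedoids(pts, 3, seed=1)
    grades = assign_grades(res)
    perm = np.array([3, 1, 2])
    permuted = type(res)(k=3, labels=perm[res.labels - 1],
                         centers=res.centers[[1, 2, 0]],
                         medoid_indices=res.medoid_indices[[1, 2, 0]],
                         cost=res.cost, silhouette=res.silhouette)
    grades2 = assign_grades(permuted)
    assert np.array_equal(grades.levels, grades2.levels)
    assert np.allclose(grades.centers, grades2.centers)


def test_per_level_means_increase_on_monotone_data(planted_blobs):
    pts, _, _ = planted_blobs
    grades = assign_grades(kmedoids(pts, 3, seed=3))
    means = [pts[grades.levels == lv].mean(axis=0) for lv in (1, 2, 3)]
    for c in range(3):
        assert means[0][c] < means[1][c] < means[2][c]


# ----------------------------------------------------------------- trajectory
def _persistence_fc(values, n):
    return lambda j: np.full(n, values[j])


def test_grade_trajectory_constant_sample_is_flat(planted_blobs):
    pts, _, _ = planted_blobs
    grades = assign_grades(kmedoids(pts, 3, seed=4))
    const = np.full(20, 8.0)
    levels, skipped = grade_trajectory(const, _persistence_fc(const, 7), grades, n=7)
    assert skipped == list(range(7))
    assert len(set(levels.values())) == 1


def test_grade_trajectory_monotone_on_noiseless_growth():
    """Levels never decrease along a noiseless logistic trajectory, and the
    warm/humid condition reaches the top level no later than the cold/dry one."""
    params = GrowthParams("AFB1", 0.5, 20.0, max_rate=0.25, noise_sd=0.0)
    n = 5
    trajs = {}
    for cond in (StorageCondition(30, 0.98), StorageCondition(10, 0.92)):
        s = simulate_series(cond, 40, params, seed=0)
        trajs[cond.temperature] = s.values[:, 0]
    # grade space fitted on pooled P points of both trajectories
    pool = []
    for v in trajs.values():
        for j in range(n, len(v) - n):
            pool.append([v[j - n:j].mean(), v[j], v[j + 1:j + 1 + n].mean()])
    grades = assign_grades(kmedoids(np.array(pool), 3, seed=5))
    first_top = {}
    for temp, v in trajs.items():
        fc = lambda j: v[j + 1:j + 1 + n]  # noqa: E731 - oracle forecast
        levels, _ = grade_trajectory(v[:len(v) - n], fc, grades, n=n)
        seq = [levels[j] for j in sorted(levels)]
        assert np.all(np.diff(seq) >= 0)
        tops = [j for j, lv in levels.items() if lv == 3]
        first_top[temp] = min(tops) if tops else np.inf
    assert first_top[30.0] <= first_top[10.0]
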