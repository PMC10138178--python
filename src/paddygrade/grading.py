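"""Storage-quality grading from the evaluation index P.

For each sample and day j the evaluation index is the triple
P = (mean toxin over the previous n days, toxin at day j, mean forecast toxin
over the next n days).  Pooled P points are clustered with k-medoids (k-means
is available as a comparator), the cluster count is selected by the silhouette
coefficient, and the three clusters are mapped to ordered quality levels 1–3
by the distance of their centers from the origin of P-space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .metrics import silhouette

__all__ = ["PIndex", "ClusterResult", "GradeResult", "compute_p_index",
           "kmedoids", "kmeans", "scan_k", "assign_grades",
           "nearest_grade", "grade_trajectory"]


@dataclass(frozen=True)
class PIndex:
    """The clustering feature (past mean, current, predicted mean), µg/kg."""

    past_mean: float
    current: float
    future_mean: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("window length n must be >= 1")
        if min(self.past_mean, self.current, self.future_mean) < 0:
            raise ValueError("P components must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.past_mean, self.current, self.future_mean])


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray            # in 1..k
    centers: np.ndarray           # (k, dim): medoid coordinates or means
    medoid_indices: np.ndarray | None  # indices into the input, k-medoids only
    cost: float                   # sum of point-to-center Euclidean distances
    silhouette: float
    cost_history: list = field(default_factory=list)  # kmeans: squared cost per sweep


@dataclass
class GradeResult:
    """Clusters mapped to quality levels 1–3, ordered by center norm."""

    levels: np.ndarray            # per-point level in {1, 2, 3}
    centers: np.ndarray           # (3, dim), centers[i] is level i+1's center
    counts: np.ndarray            # per-level sample counts


def compute_p_index(observed: np.ndarray, forecast: np.ndarray, j: int, n: int) -> PIndex:
    """P at day position ``j`` (0-based into ``observed``).

    Requires ``observed[j-n:j]`` for the past mean and ``forecast[:n]`` as the
    predicted levels for days j+1..j+n.
    """
    observed = np.asarray(observed, dtype=float)
    forecast = np.asarray(forecast, dtype=float)
    if n < 1:
        raise ValueError("window length n must be >= 1")
    if j - n < 0 or j >= len(observed):
        raise ValueError(f"insufficient history: need {n} observed days before day {j}")
    if len(forecast) < n:
        raise ValueError(f"insufficient horizon: need {n} forecast days, got {len(forecast)}")
    return PIndex(past_mean=float(observed[j - n:j].mean()),
                  current=float(observed[j]),
                  future_mean=float(forecast[:n].mean()), n=n)


def _assign(points: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-center labels (1-based; ties -> lowest center index) and cost."""
    d = cdist(points, centers)
    labels = d.argmin(axis=1)
    return labels + 1, float(d[np.arange(len(points)), labels].sum())


def _check_k(points: np.ndarray, k: int) -> None:
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(points):
        raise ValueError(f"k={k} exceeds the number of points ({len(points)})")


def kmedoids(points, k: int, seed: int = 0, max_iter: int = 300,
             restarts: int = 10) -> ClusterResult:
    """Randomized-swap greedy k-medoids.

    From seeded random initial medoids, repeatedly propose swapping one medoid
    with a randomly chosen non-medoid and keep the swap iff the total cost
    (sum of Euclidean distances to the nearest medoid) strictly decreases;
    stop when a full pass over proposals yields no improvement or ``max_iter``
    is reached.  ``restarts`` independent seeded starts are run and the best
    final cost kept.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    _check_k(x, k)
    n = len(x)
    best: tuple[float, np.ndarray] | None = None
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(restarts):
        rng = np.random.default_rng(child)
        medoids = rng.choice(n, size=k, replace=False)
        _, cost = _assign(x, x[medoids])
        stale = 0
        full_pass = k * n  # expected proposals to try every (medoid, candidate) pair
        for _ in range(max_iter):
            if stale >= full_pass:
                break
            m_pos = rng.integers(k)
            candidate = rng.integers(n)
            if candidate in medoids:
                stale += 1
                continue
            trial = medoids.copy()
            trial[m_pos] = candidate
            _, trial_cost = _assign(x, x[trial])
            if trial_cost < cost:
                medoids, cost = trial, trial_cost
                stale = 0
            else:
                stale += 1
        if best is None or cost < best[0]:
            best = (cost, np.sort(medoids))
    cost, medoids = best
    labels, cost = _assign(x, x[medoids])
    return ClusterResult(k=k, labels=labels, centers=x[medoids],
                         medoid_indices=medoids, cost=cost,
                         silhouette=silhouette(x, labels))


def kmeans(points, k: int, seed: int = 0, max_iter: int = 300,
           restarts: int = 10) -> ClusterResult:
    """Lloyd iterations from seeded random data points (comparator).

    ``restarts`` independent seeded starts are run, keeping the lowest
    within-cluster squared cost.  The returned result carries
    ``cost_history`` — the squared cost after each Lloyd iteration of the
    winning start, non-increasing by construction.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    _check_k(x, k)
    best = None
    for child in np.random.SeedSequence(seed).spawn(restarts):
        rng = np.random.default_rng(child)
        centers = x[rng.choice(len(x), size=k, replace=False)].copy()
        labels, _ = _assign(x, centers)
        history = []
        for _ in range(max_iter):
            new_centers = centers.copy()
            for c in range(k):
                members = x[labels == c + 1]
                if len(members):
                    new_centers[c] = members.mean(axis=0)
            new_labels, _ = _assign(x, new_centers)
            sq = float((cdist(x, new_centers).min(axis=1) ** 2).sum())
            history.append(sq)
            if np.array_equal(new_labels, labels) and np.allclose(new_centers, centers):
                break
            centers, labels = new_centers, new_labels
        sq_cost = history[-1] if history else np.inf
        if best is None or sq_cost < best[0]:
            best = (sq_cost, centers, history)
    _, centers, history = best
    labels, cost = _assign(x, centers)
    return ClusterResult(k=k, labels=labels, centers=centers,
                         medoid_indices=None, cost=cost,
                         silhouette=silhouette(x, labels), cost_history=history)


def scan_k(points, algorithm: str = "kmedoids", k_range: Sequence[int] = range(3, 8),
           seed: int = 0) -> tuple[int, dict[int, float], dict[int, ClusterResult]]:
    """Cluster at each k, score by silhouette, pick the best (ties -> smaller k)."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    fit = {"kmedoids": kmedoids, "kmeans": kmeans}.get(algorithm)
    if fit is None:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    results = {k: fit(points, k, seed=seed) for k in k_range}
    scores = {k: r.silhouette for k, r in results.items()}
    selected = max(sorted(scores), key=lambda k: scores[k])
    return selected, scores, results


def assign_grades(result: ClusterResult) -> GradeResult:
    """Map a 3-cluster result to ordered levels by center distance from origin."""
    if result.k != 3:
        raise ValueError("grading requires exactly 3 clusters")
    norms = np.linalg.norm(result.centers, axis=1)
    order = np.argsort(norms)  # nearest origin -> level 1
    level_of_cluster = np.empty(3, dtype=int)
    level_of_cluster[order] = np.arange(1, 4)
    levels = level_of_cluster[result.labels - 1]
    centers = result.centers[order]
    counts = np.array([(levels == lv).sum() for lv in (1, 2, 3)])
    return GradeResult(levels=levels, centers=centers, counts=counts)


def nearest_grade(p: np.ndarray, grades: GradeResult) -> int:
    """Quality level of a single P point: nearest grade center (ties -> lower)."""
    d = np.linalg.norm(grades.centers - np.asarray(p, dtype=float), axis=1)
    return int(d.argmin()) + 1


def grade_trajectory(series_values: np.ndarray, forecast_fn, grades: GradeResult,
                     n: int = 7) -> tuple[dict[int, int], list[int]]:
    """Level per day for one sample's toxin channel.

    ``forecast_fn(j)`` must return the predicted levels for days j+1..j+n
    (0-based j into ``series_values``).  Days whose past window or forecast
    horizon is unavailable are skipped and reported, not silently dropped.
    Returns (day_position -> level, skipped day positions).
    """
    values = np.asarray(series_values, dtype=float)
    levels: dict[int, int] = {}
    skipped: list[int] = []
    for j in range(len(values)):
        try:
            fc = forecast_fn(j)
            p = compute_p_index(values, fc, j, n)
        except ValueError:
            skipped.append(j)
            continue
        levels[j] = nearest_grade(p.as_array(), grades)
    return levels, skipped
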