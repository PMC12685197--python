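"""Functional K-means for fixed-window dose curves.

"Functional" here means clustering the hourly discretized step
trajectories directly as vectors on a common time grid (no smoothing or
basis expansion), which is faithful to how the curves are built. The
algorithm is entirely deterministic:

* **max-dist (maximin) initialization** — the first two seeds are the
  pair of curves at maximum Euclidean distance; each further seed is the
  curve maximizing its minimum distance to the seeds already chosen.
  All ties break to the smallest row index.
* **Lloyd iterations** — alternate nearest-centroid assignment (ties to
  the lower cluster label) and centroid-as-mean updates until the
  assignment is stable or 100 iterations; an empty cluster is repaired
  by moving into it the point farthest from its current centroid.
* **single-move polish** — after Lloyd converges, Hartigan-style single
  reassignments (evaluated on the k-means objective with
  partition-induced centroids) are applied while any strictly improves,
  best improvement first, ties to the smallest point index; moves that
  would empty a cluster are disallowed. Lloyd fixed points are not in
  general optimal under single reassignments (a point can profitably
  migrate from a large cluster to a small one even when it already sits
  nearest its own centroid); the polish guarantees 1-swap local
  optimality of the returned partition while keeping the objective
  monotone.

Cluster labels are re-lettered A, B, C, ... by descending cluster size
(ties to the smallest member index) so that "A" is always the largest
cluster.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectories import DoseTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "CurveMatrix",
    "ClusterSolution",
    "vectorize",
    "maxdist_init",
    "lloyd",
    "fit_range",
    "TrajectoryKMeans",
    "TrajectoryKMeansResults",
]

MAX_LLOYD_ITER = 100


@dataclass
class CurveMatrix:
    """Curves on a common hourly grid: n_courses x window, zero-padded
    past each course's end. Row order is fixed and recorded."""

    course_ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if len(self.course_ids) != self.X.shape[0]:
            raise ValueError("course_ids length must match the number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def window(self) -> int:
        return self.X.shape[1]


@dataclass
class ClusterSolution:
    k: int
    course_ids: list[str]
    labels: np.ndarray  # integer cluster per course, 0 = "A"
    centroids: np.ndarray  # k x window, ordered by label
    wcss: float
    n_iter: int
    converged: bool
    wcss_path: list[float] = field(default_factory=list)

    @property
    def letters(self) -> list[str]:
        return [string.ascii_uppercase[i] for i in self.labels]

    @property
    def assignments(self) -> pd.Series:
        return pd.Series(self.letters, index=pd.Index(self.course_ids, name="course_id"),
                         name="cluster")

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def vectorize(trajectories, window: int) -> CurveMatrix:
    """Sample each trajectory at hours 0..window-1 (0 past its end)."""
    trajs = [t for t in trajectories if (t.end_hour if isinstance(t, DoseTrajectory) else len(t)) >= 1]
    if not trajs:
        raise ValueError("no trajectories to vectorize")
    ids, rows = [], []
    for i, t in enumerate(trajs):
        if isinstance(t, DoseTrajectory):
            ids.append(t.course_id)
            rows.append(t.sample(int(window)))
        else:
            ids.append(str(i))
            v = np.zeros(int(window))
            arr = np.asarray(t, dtype=float)
            m = min(len(arr), int(window))
            v[:m] = arr[:m]
            rows.append(v)
    return CurveMatrix(ids, np.vstack(rows))


def _as_X(X) -> np.ndarray:
    if isinstance(X, CurveMatrix):
        return X.X
    X = np.asarray(X, dtype=float)
    return X.reshape(len(X), -1)


def maxdist_init(X, k: int) -> np.ndarray:
    """Deterministic maximin seeding; returns row indices of the seeds."""
    A = _as_X(X)
    n = A.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    d2 = ((A[:, None, :] - A[None, :, :]) ** 2).sum(-1)
    best, pair = -1.0, (0, 1)
    for i in range(n - 1):
        j = i + 1 + int(np.argmax(d2[i, i + 1:]))
        if d2[i, j] > best:
            best, pair = d2[i, j], (i, j)
    seeds = [pair[0], pair[1]]
    while len(seeds) < k:
        mind = d2[:, seeds].min(axis=1)
        mind[seeds] = -np.inf
        seeds.append(int(np.argmax(mind)))  # ties -> smallest index
    return np.array(seeds, dtype=int)


def _dist2(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    return ((A[:, None, :] - C[None, :, :]) ** 2).sum(-1)


def _repair_empties(A, labels, centroids, k) -> np.ndarray:
    """Move the point farthest from its centroid into each empty cluster."""
    labels = labels.copy()
    for empty in range(k):
        if (labels == empty).any():
            continue
        sizes = np.bincount(labels, minlength=k)
        eligible = sizes[labels] > 1
        d2own = ((A - centroids[labels]) ** 2).sum(-1)
        d2own = np.where(eligible, d2own, -np.inf)
        labels[int(np.argmax(d2own))] = empty
    return labels


def _means(A, labels, k) -> np.ndarray:
    C = np.empty((k, A.shape[1]))
    for c in range(k):
        C[c] = A[labels == c].mean(axis=0)
    return C


def lloyd(X, k: int, seeds, max_iter: int = MAX_LLOYD_ITER, polish: bool = True) -> ClusterSolution:
    """K-means from the given seed rows; see the module docstring for the
    iteration scheme, tie rules and the single-move polish."""
    cm = X if isinstance(X, CurveMatrix) else CurveMatrix([str(i) for i in range(len(_as_X(X)))], _as_X(X))
    A = cm.X
    n = A.shape[0]
    seeds = np.asarray(seeds, dtype=int)
    centroids = A[seeds].copy()
    labels_prev = None
    labels = np.zeros(n, dtype=int)
    path: list[float] = []
    n_iter = 0
    converged = False

    for outer in range(max_iter):
        # Lloyd sweep(s)
        while n_iter < max_iter:
            d2 = _dist2(A, centroids)
            labels = d2.argmin(axis=1)  # ties -> lower label (first min)
            labels = _repair_empties(A, labels, centroids, k)
            if labels_prev is not None and np.array_equal(labels, labels_prev):
                converged = True
                break
            labels_prev = labels.copy()
            centroids = _means(A, labels, k)
            path.append(float(((A - centroids[labels]) ** 2).sum()))
            n_iter += 1
        if not converged:
            break
        if not polish:
            break
        # single-move polish: best strictly improving reassignment
        sizes = np.bincount(labels, minlength=k).astype(float)
        d2 = _dist2(A, centroids)
        best_delta, best_move = -1e-12, None
        for i in range(n):
            a = labels[i]
            if sizes[a] <= 1:
                continue
            gain_a = sizes[a] / (sizes[a] - 1.0) * d2[i, a]
            for b in range(k):
                if b == a:
                    continue
                delta = sizes[b] / (sizes[b] + 1.0) * d2[i, b] - gain_a
                if delta < best_delta:
                    best_delta, best_move = delta, (i, b)
        if best_move is None:
            break
        i, b = best_move
        labels[i] = b
        labels_prev = labels.copy()
        centroids = _means(A, labels, k)
        path.append(float(((A - centroids[labels]) ** 2).sum()))
        converged = False  # re-enter Lloyd from the polished partition

    wcss = float(((A - centroids[labels]) ** 2).sum())

    # relabel by descending size, ties to the smallest member index
    order = sorted(
        range(k),
        key=lambda c: (-(labels == c).sum(), int(np.flatnonzero(labels == c).min())),
    )
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    labels = remap[labels]
    centroids = centroids[order]

    return ClusterSolution(
        k=k,
        course_ids=list(cm.course_ids),
        labels=labels,
        centroids=centroids,
        wcss=wcss,
        n_iter=n_iter,
        converged=converged,
        wcss_path=path,
    )


def fit_range(X, ks=(2, 3, 4), polish: bool = True) -> list[ClusterSolution]:
    """One independently initialized solution per k; k > n is skipped."""
    A = _as_X(X)
    out = []
    for k in ks:
        if k > A.shape[0]:
            logger.warning("k=%d exceeds the %d available courses; skipped", k, A.shape[0])
            continue
        out.append(lloyd(X, k, maxdist_init(X, k), polish=polish))
    return out


class TrajectoryKMeans:
    """Functional K-means model over a curve matrix.

    Parameters
    ----------
    X : CurveMatrix or array-like
        Curves on a common hourly grid.
    k : int
        Number of clusters.
    """

    def __init__(self, X, k: int = 3):
        self.data = X if isinstance(X, CurveMatrix) else CurveMatrix(
            [str(i) for i in range(len(_as_X(X)))], _as_X(X)
        )
        self.k = int(k)

    @classmethod
    def from_trajectories(cls, trajectories, window: int, k: int = 3) -> "TrajectoryKMeans":
        return cls(vectorize(trajectories, window), k=k)

    def fit(self, polish: bool = True) -> "TrajectoryKMeansResults":
        seeds = maxdist_init(self.data, self.k)
        sol = lloyd(self.data, self.k, seeds, polish=polish)
        return TrajectoryKMeansResults(self, sol)


class TrajectoryKMeansResults:
    """Fitted clustering: assignments, centroids, objective and diagnostics."""

    def __init__(self, model: TrajectoryKMeans, solution: ClusterSolution):
        self.model = model
        self.solution = solution

    @property
    def assignments(self) -> pd.Series:
        return self.solution.assignments

    @property
    def centroids(self) -> np.ndarray:
        return self.solution.centroids

    @property
    def wcss(self) -> float:
        return self.solution.wcss

    def centroid_frame(self) -> pd.DataFrame:
        letters = [string.ascii_uppercase[i] for i in range(self.solution.k)]
        df = pd.DataFrame(self.centroids.T, columns=letters)
        df.insert(0, "hour", np.arange(self.model.data.window))
        return df

    def summary(self) -> str:
        sol = self.solution
        lines = [
            f"Functional K-means (max-dist init), k={sol.k}, "
            f"n={len(sol.course_ids)}, window={self.model.data.window} h",
            f"WCSS: {sol.wcss:.6g}   iterations: {sol.n_iter}   "
            f"converged: {sol.converged}",
            "Cluster sizes: "
            + ", ".join(f"{lab}={cnt}" for lab, cnt in sol.sizes().items()),
        ]
        return "\n".join(lines)
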