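"""Analysis-window selection for trajectory clustering.

Fixed-length clustering needs a common follow-up window. Too short a
window discards late dosing structure; too long a window pads most
curves with zeros and groups short courses together regardless of their
early shape. The selection rule scores each candidate window by the
sample standard deviation of all pairwise Euclidean distances between
the curves truncated (and zero-padded) to that window, and picks the
maximizing window — with an analyst override for cases where the global
maximum sits at an unrealistically short window and a local maximum is
preferred (the esmolol situation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectories import DoseTrajectory

__all__ = [
    "WindowScore",
    "InsufficientCurvesError",
    "curve_distance",
    "score_window",
    "score_profile",
    "select_window",
    "WindowSelection",
]


class InsufficientCurvesError(ValueError):
    """A sample SD over pairwise distances needs at least 3 curves."""


@dataclass(frozen=True)
class WindowScore:
    window: int
    sd_distance: float


@dataclass
class WindowSelection:
    chosen: int
    argmax: int
    overridden: bool
    profile: pd.DataFrame  # columns window, sd_distance

    def to_frame(self) -> pd.DataFrame:
        return self.profile.assign(chosen=self.profile["window"] == self.chosen)


def _as_matrix(curves, window: int) -> np.ndarray:
    rows = []
    for c in curves:
        if isinstance(c, DoseTrajectory):
            rows.append(c.sample(window))
        else:
            v = np.zeros(int(window))
            arr = np.asarray(c, dtype=float)
            m = min(len(arr), int(window))
            v[:m] = arr[:m]
            rows.append(v)
    return np.vstack(rows) if rows else np.empty((0, int(window)))


def curve_distance(a, b, window: int) -> float:
    """Euclidean distance between two step curves sampled at hours
    0..window-1, each curve 0 beyond its end."""
    if window < 1:
        raise ValueError("window must be >= 1")
    X = _as_matrix([a, b], int(window))
    return float(np.linalg.norm(X[0] - X[1]))


def _pairwise_cum_sq(X: np.ndarray) -> np.ndarray:
    """(n_pairs, W) cumulative squared differences over hours, pairs in
    lexicographic (i, j) order."""
    n, W = X.shape
    out = np.empty((n * (n - 1) // 2, W))
    r = 0
    for i in range(n - 1):
        d2 = (X[i + 1:] - X[i]) ** 2
        out[r : r + n - 1 - i] = np.cumsum(d2, axis=1)
        r += n - 1 - i
    return out


def score_window(curves, window: int) -> WindowScore:
    """Sample SD (n-1 denominator) of all C(n,2) pairwise distances."""
    X = _as_matrix(curves, int(window))
    if X.shape[0] < 3:
        raise InsufficientCurvesError(
            f"need >= 3 curves for a sample SD of pairwise distances, got {X.shape[0]}"
        )
    cum = _pairwise_cum_sq(X)
    d = np.sqrt(cum[:, -1])
    return WindowScore(int(window), float(np.std(d, ddof=1)))


def score_profile(curves, grid) -> pd.DataFrame:
    """Window-score profile over a candidate grid (shared cumulative
    pass, identical to scoring each window separately)."""
    grid = sorted({int(w) for w in grid})
    if not grid or grid[0] < 1:
        raise ValueError("candidate grid must contain positive integer hours")
    X = _as_matrix(curves, grid[-1])
    if X.shape[0] < 3:
        raise InsufficientCurvesError(
            f"need >= 3 curves for a sample SD of pairwise distances, got {X.shape[0]}"
        )
    cum = _pairwise_cum_sq(X)
    idx = np.asarray(grid, dtype=int) - 1
    d = np.sqrt(cum[:, idx])
    sds = np.std(d, axis=0, ddof=1)
    return pd.DataFrame({"window": grid, "sd_distance": sds})


def default_grid(curves) -> list[int]:
    """Every integer hour from 1 to the longest observed course."""
    longest = max(
        (c.end_hour if isinstance(c, DoseTrajectory) else len(np.asarray(c)))
        for c in curves
    )
    return list(range(1, max(int(longest), 1) + 1))


def select_window(curves, grid=None, override: int | None = None) -> WindowSelection:
    """Choose the clustering window.

    Without an override: argmax of the SD profile, ties to the smallest
    window. With an override (which must sit on the grid): the override
    is returned while the full profile and the unconstrained argmax are
    still reported.
    """
    if grid is None:
        grid = default_grid(curves)
    profile = score_profile(curves, grid)
    best = profile["sd_distance"].to_numpy()
    argmax = int(profile["window"].iloc[int(np.argmax(best))])  # first max = smallest window
    if override is not None:
        if int(override) not in set(profile["window"]):
            raise ValueError(f"override window {override} is not on the candidate grid")
        return WindowSelection(int(override), argmax, True, profile)
    return WindowSelection(argmax, argmax, False, profile)
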