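"""Behavioral predictivity metrics for pursuit trajectories.

The central quantity is the shortcut metric: the average distance between a
pursuit trajectory and the straight reference segment from the pursuer's
start to the target's final position (the path an agent with perfect
knowledge of the outcome would take). Smaller values mean more
shortcut-like, i.e. more predictive, pursuit. Distributions of the metric
across trials are compared between the RNN and the reactive control with
the two-sample Kolmogorov-Smirnov statistic and the order-1 Wasserstein
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .arena_targets import ArenaConfig, displacement, geodesic_distance

__all__ = [
    "MetricsReport",
    "point_segment_distance",
    "shortcut_metric",
    "normalized_deviation",
    "path_length",
    "ks_two_sample",
    "wasserstein_1d",
    "detect_waiting",
    "distance_to_endpoint_curves",
]


@dataclass
class MetricsReport:
    """Per-trial and per-condition behavioral quantities."""

    end_distance: np.ndarray | None = None  # (n_trials,) m
    shortcut: np.ndarray | None = None  # (n_trials,) m
    normalized_deviation: np.ndarray | None = None  # unitless
    ks_D: float | None = None
    ks_p: float | None = None
    wasserstein: float | None = None
    waiting_intervals: list = field(default_factory=list)


def point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to the closed segment [a, b]."""
    points = np.atleast_2d(np.asarray(points, float))
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=-1)
    s = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + s[:, None] * ab
    return np.linalg.norm(points - proj, axis=-1)


def shortcut_metric(
    traj: np.ndarray,
    ref_start: np.ndarray,
    target_end: np.ndarray,
    arena: ArenaConfig,
) -> float:
    """Mean distance from ``traj`` to the straight reference segment.

    The reference runs from the pursuer's start to the target's final
    position. In a periodic arena the reference is the minimal-image chord
    and point-to-segment distances are evaluated over the 3x3 periodic
    images of each point (exact torus distance to the segment).
    """
    traj = np.asarray(traj, float)
    ref_start = np.asarray(ref_start, float)
    target_end = np.asarray(target_end, float)
    if arena.boundary == "reflective":
        return float(np.mean(point_segment_distance(traj, ref_start, target_end)))
    L = arena.side_length
    end_unwrapped = ref_start + displacement(target_end, ref_start, arena)
    best = None
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            shifted = traj + np.array([ix * L, iy * L])
            d = point_segment_distance(shifted, ref_start, end_unwrapped)
            best = d if best is None else np.minimum(best, d)
    return float(np.mean(best))


def path_length(traj: np.ndarray, arena: ArenaConfig | None = None) -> float:
    """Total length traveled along a trajectory (geodesic per step)."""
    traj = np.asarray(traj, float)
    steps = np.diff(traj, axis=0)
    if arena is not None and arena.boundary == "periodic":
        L = arena.side_length
        steps = steps - L * np.round(steps / L)
    return float(np.sum(np.linalg.norm(steps, axis=-1)))


def normalized_deviation(
    traj_a: np.ndarray,
    traj_b: np.ndarray,
    arena: ArenaConfig | None = None,
) -> float:
    """Mean pointwise separation of two trajectories over the length of the first.

    ``traj_a`` is the RNN trajectory (its path length normalizes); returns
    NaN (flagged undefined) when that length is zero.
    """
    traj_a = np.asarray(traj_a, float)
    traj_b = np.asarray(traj_b, float)
    if traj_a.shape != traj_b.shape:
        raise ValueError("trajectories must have equal shapes")
    diff = traj_a - traj_b
    if arena is not None and arena.boundary == "periodic":
        L = arena.side_length
        diff = diff - L * np.round(diff / L)
    mean_sep = float(np.mean(np.linalg.norm(diff, axis=-1)))
    length = path_length(traj_a, arena)
    if length == 0.0:
        return float("nan")
    return mean_sep / length


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic D and asymptotic p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def wasserstein_1d(x, y) -> float:
    """Order-1 Wasserstein (earth mover's) distance between two samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    return float(stats.wasserstein_distance(x, y))


def detect_waiting(dist_series: np.ndarray, eps: float, min_len: int) -> list:
    """Find waiting periods in a distance-to-endpoint series.

    Returns maximal intervals ``(start_step, end_step)`` over which every
    per-step change satisfies ``|dist[t+1] - dist[t]| < eps``, keeping only
    intervals spanning at least ``min_len`` steps (``end - start >= min_len``).
    """
    dist_series = np.asarray(dist_series, float)
    small = np.abs(np.diff(dist_series)) < eps
    intervals = []
    start = None
    for i, ok in enumerate(small):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_len:
                intervals.append((start, i))
            start = None
    if start is not None and len(small) - start >= min_len:
        intervals.append((start, len(small)))
    return intervals


def distance_to_endpoint_curves(
    rollouts: list,
    trials: list,
    arena: ArenaConfig,
    group_by_ct_start: bool = True,
) -> dict:
    """Mean distance-to-target-endpoint curve per trial group.

    For each trial, the per-step geodesic distance from the pursuer to that
    trial's target end location is computed; curves are averaged within
    groups (CT start index, or a single group when ``group_by_ct_start`` is
    False or for RTs, keyed -1).
    """
    if len(rollouts) != len(trials) or not trials:
        raise ValueError("rollouts and trials must be non-empty and aligned")
    groups: dict[int, list] = {}
    for ro, tr in zip(rollouts, trials):
        end = tr.target.positions[-1]
        curve = geodesic_distance(ro.positions, end[None, :], arena)
        key = tr.target.ct_start_index if (group_by_ct_start and tr.target.ct_start_index is not None) else -1
        groups.setdefault(key, []).append(curve)
    return {k: np.mean(np.stack(v), axis=0) for k, v in groups.items()}
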