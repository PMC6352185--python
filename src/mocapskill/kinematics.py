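"""Kinematic skill indicators computed from a dual-hand motion recording.

Five base indicators summarise one trial:

* task completion time (s) — last minus first timestamp;
* manipulator collisions (count) — occasions on which the 3D Euclidean
  distance between the two hands falls below a threshold (100 mm default),
  where an *occasion* is one maximal contiguous run of sub-threshold frames,
  not one frame (a per-frame count would scale with the frame rate);
* high-acceleration movements (count) — occasions on which either hand's
  acceleration magnitude exceeds a threshold (10 m/s² default), counted the
  same run-wise way and summed over the two hands;
* economy-of-motion (mm) — each hand's path length (sum of consecutive-frame
  displacements); the mean of the two hands feeds the composite score;
* used workspace (mm³) — volume of 3D space covered by the hands' movement,
  by default the convex hull of both hands' pooled positions (an axis-aligned
  bounding box is available as a cheap alternative).

Four ratio derivatives accompany them: workspace/time, time/workspace,
economy-of-motion/time and time/economy-of-motion.

Acceleration is estimated by double numerical differentiation of position
(mm converted to m) with an optional centered moving-average pre-smoothing
of the position signal: raw double-differencing at 25 fps amplifies sensor
noise.  Smoothing runs in "valid" mode — the (window − 1) edge frames without
a full window are trimmed rather than padded, because padding a linear track
creates boundary kinks that register as spurious events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import InsufficientDataError
from .io import MotionRecording

logger = logging.getLogger(__name__)

MM_PER_M = 1000.0


@dataclass(frozen=True)
class KinematicsConfig:
    """Thresholds and numerical options for the indicator computations.

    Attributes
    ----------
    collision_threshold : float
        Inter-hand distance below which the hands are in collision, mm.
    accel_threshold : float
        Acceleration magnitude above which a movement counts as
        high-acceleration, m/s².
    smoothing_window : int
        Odd frame count of the centered moving average applied to position
        before double differentiation; 1 disables smoothing.
    hull_method : {"convex_hull", "aabb"}
        Volume estimator for the used workspace.
    """

    collision_threshold: float = 100.0
    accel_threshold: float = 10.0
    smoothing_window: int = 5
    hull_method: Literal["convex_hull", "aabb"] = "convex_hull"

    def __post_init__(self) -> None:
        if self.collision_threshold <= 0:
            raise ValueError("collision_threshold must be > 0")
        if self.accel_threshold <= 0:
            raise ValueError("accel_threshold must be > 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be an odd integer >= 1")
        if self.hull_method not in ("convex_hull", "aabb"):
            raise ValueError(f"unknown hull_method {self.hull_method!r}")


@dataclass(frozen=True)
class IndicatorSet:
    """The five base indicators plus ratio derivatives for one trial.

    The derivatives are exact ratios of the stored base fields and are
    populated by :func:`compute_indicators`.
    """

    time_s: float
    collisions: int
    high_accel_events: int
    eom_left_mm: float
    eom_right_mm: float
    eom_mean_mm: float
    workspace_mm3: float
    workspace_per_time: float = field(default=float("nan"))
    time_per_workspace: float = field(default=float("nan"))
    eom_per_time: float = field(default=float("nan"))
    time_per_eom: float = field(default=float("nan"))

    #: Names of the five base indicators, in reporting order.
    BASE_NAMES = (
        "time_s",
        "collisions",
        "high_accel_events",
        "eom_mean_mm",
        "workspace_mm3",
    )
    #: Names of the four ratio derivatives.
    DERIVATIVE_NAMES = (
        "workspace_per_time",
        "time_per_workspace",
        "eom_per_time",
        "time_per_eom",
    )

    def as_dict(self) -> dict[str, float]:
        return {
            "time_s": self.time_s,
            "collisions": self.collisions,
            "high_accel_events": self.high_accel_events,
            "eom_left_mm": self.eom_left_mm,
            "eom_right_mm": self.eom_right_mm,
            "eom_mean_mm": self.eom_mean_mm,
            "workspace_mm3": self.workspace_mm3,
            "workspace_per_time": self.workspace_per_time,
            "time_per_workspace": self.time_per_workspace,
            "eom_per_time": self.eom_per_time,
            "time_per_eom": self.time_per_eom,
        }


def count_runs(mask: np.ndarray) -> int:
    """Number of maximal contiguous runs of True in a boolean sequence."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return 0
    starts = mask & ~np.concatenate(([False], mask[:-1]))
    return int(starts.sum())


def task_time(rec: MotionRecording) -> float:
    """Task completion time: last recorded timestamp minus the first, s."""
    return rec.duration


def count_collisions(rec: MotionRecording, cfg: KinematicsConfig | None = None) -> int:
    """Count manipulator collisions (inter-hand distance < threshold).

    One collision is one maximal contiguous run of frames whose 3D Euclidean
    inter-hand distance is strictly below ``cfg.collision_threshold``.
    """
    cfg = cfg or KinematicsConfig()
    dist = np.linalg.norm(rec.left.pos - rec.right.pos, axis=1)
    return count_runs(dist < cfg.collision_threshold)


def _smooth_valid(pos: np.ndarray, t: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average in valid mode; trims (window-1) edge frames."""
    if window <= 1:
        return pos, t
    kernel = np.full(window, 1.0 / window)
    sm = np.column_stack(
        [np.convolve(pos[:, k], kernel, mode="valid") for k in range(pos.shape[1])]
    )
    half = window // 2
    return sm, t[half : len(t) - half]


def acceleration_magnitude(
    pos_mm: np.ndarray, t: np.ndarray, *, smoothing_window: int = 1
) -> np.ndarray:
    """Acceleration magnitude series (m/s²) for one hand's positions.

    Positions (mm) are optionally pre-smoothed, converted to metres and
    differentiated twice with second-order central differences
    (:func:`numpy.gradient`, exact for quadratic-in-time motion).
    """
    pos, t = _smooth_valid(np.asarray(pos_mm, dtype=float), np.asarray(t, dtype=float), smoothing_window)
    if len(t) < 3:
        raise InsufficientDataError("need >= 3 frames after smoothing to estimate acceleration")
    pos_m = pos / MM_PER_M
    vel = np.gradient(pos_m, t, axis=0)
    acc = np.gradient(vel, t, axis=0)
    return np.linalg.norm(acc, axis=1)


def count_high_accel(rec: MotionRecording, cfg: KinematicsConfig | None = None) -> int:
    """Count high-acceleration occasions, summed over both hands.

    For each hand, the acceleration magnitude series is thresholded at
    ``cfg.accel_threshold`` and the number of maximal supra-threshold runs
    is counted.
    """
    cfg = cfg or KinematicsConfig()
    if rec.n_frames < 3:
        raise InsufficientDataError("need >= 3 frames to estimate acceleration")
    total = 0
    for track in (rec.left, rec.right):
        acc = acceleration_magnitude(track.pos, track.t, smoothing_window=cfg.smoothing_window)
        total += count_runs(acc > cfg.accel_threshold)
    return total


def economy_of_motion(rec: MotionRecording) -> tuple[float, float, float]:
    """Per-hand path lengths and their mean, mm.

    Returns ``(left, right, mean)`` where each hand's economy-of-motion is
    the sum of consecutive-frame Euclidean displacements.
    """
    left = float(np.linalg.norm(np.diff(rec.left.pos, axis=0), axis=1).sum())
    right = float(np.linalg.norm(np.diff(rec.right.pos, axis=0), axis=1).sum())
    return left, right, (left + right) / 2.0


def used_workspace(rec: MotionRecording, cfg: KinematicsConfig | None = None) -> float:
    """Volume covered by the hands' movement, mm³.

    Pools both hands' positions and returns the convex-hull volume
    (default) or the axis-aligned bounding-box volume.  A degenerate
    (coplanar or collinear) point set under the convex hull yields 0 with
    a logged warning.
    """
    cfg = cfg or KinematicsConfig()
    points = np.vstack([rec.left.pos, rec.right.pos])
    if cfg.hull_method == "aabb":
        extents = points.max(axis=0) - points.min(axis=0)
        return float(np.prod(extents))
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        logger.warning("%s: degenerate point set, workspace volume set to 0", rec.trial_id)
        return 0.0


def compute_indicators(
    rec: MotionRecording, cfg: KinematicsConfig | None = None
) -> IndicatorSet:
    """Compute all base indicators and ratio derivatives for one recording."""
    cfg = cfg or KinematicsConfig()
    t = task_time(rec)
    eom_l, eom_r, eom_mean = economy_of_motion(rec)
    ws = used_workspace(rec, cfg)
    return IndicatorSet(
        time_s=t,
        collisions=count_collisions(rec, cfg),
        high_accel_events=count_high_accel(rec, cfg),
        eom_left_mm=eom_l,
        eom_right_mm=eom_r,
        eom_mean_mm=eom_mean,
        workspace_mm3=ws,
        workspace_per_time=ws / t,
        time_per_workspace=t / ws if ws > 0 else float("inf"),
        eom_per_time=eom_mean / t,
        time_per_eom=t / eom_mean if eom_mean > 0 else float("inf"),
    )
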