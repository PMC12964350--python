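"""Per-frame displacement/speed and per-track locomotion summaries.

Summary statistics are computed over the *good* (unflagged) frames only.
Gaps left by excised frames are never bridged: displacement is summed
only between temporally consecutive retained frames, so removing frames
can only shorten a track's distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import Calibration

__all__ = [
    "TrackSummary",
    "frame_displacement",
    "frame_speed",
    "aggregate_track",
    "body_length",
]


@dataclass
class TrackSummary:
    """Aggregated locomotion statistics for one track (good frames only)."""

    object_id: int
    total_distance_mm: float
    mean_speed_mm_s: float
    time_elongated_s: float
    time_bent_s: float
    distance_elongated_mm: float
    mean_speed_elongated_mm_s: float
    body_length_mm: float  # NaN when no elongated good frame exists
    normalised_distance: float  # body lengths
    normalised_mean_speed: float  # body lengths / s
    frames_total: int
    frames_removed: int
    omit_recommended: bool


def frame_displacement(
    x_px, y_px, calibration: Calibration, frame_index=None
) -> np.ndarray:
    """Per-frame centroid displacement in mm.

    ``distance[t]`` is the straight-line distance from the previous
    observation; the first frame is 0 by convention.  When a
    ``frame_index`` array is given, observations need not be contiguous
    (the displacement is still the full step between the two
    observations).
    """
    x = np.asarray(x_px, dtype=float)
    y = np.asarray(y_px, dtype=float)
    d = np.zeros(len(x))
    if len(x) > 1:
        d[1:] = np.hypot(np.diff(x), np.diff(y)) * calibration.scale
    return d


def frame_speed(
    distance_mm, calibration: Calibration, frame_index=None
) -> np.ndarray:
    """Instantaneous speed in mm/s: displacement times frame rate.

    With a non-contiguous ``frame_index`` the step is divided by the
    frame gap so that speed stays an average over the elapsed time.
    """
    d = np.asarray(distance_mm, dtype=float)
    speed = d * calibration.fps
    if frame_index is not None and len(d) > 1:
        gaps = np.diff(np.asarray(frame_index, dtype=float))
        speed[1:] = speed[1:] / gaps
    return speed


def _consecutive_steps(df: pd.DataFrame, calibration: Calibration):
    """Displacement per retained row, zeroed where the preceding frame
    index is not exactly one less (gap-non-bridging)."""
    frames = df["frame"].to_numpy(dtype=float)
    x = df["x_px"].to_numpy(dtype=float)
    y = df["y_px"].to_numpy(dtype=float)
    step = np.zeros(len(df))
    if len(df) > 1:
        consecutive = np.diff(frames) == 1
        step[1:] = np.where(
            consecutive,
            np.hypot(np.diff(x), np.diff(y)) * calibration.scale,
            0.0,
        )
    return step


def aggregate_track(
    good: pd.DataFrame,
    calibration: Calibration,
    *,
    object_id: int | None = None,
    frames_total: int | None = None,
    omit_recommended: bool = False,
) -> TrackSummary:
    """Summarise the good frames of one track.

    ``good`` needs ``frame``, ``x_px``, ``y_px``, ``state`` and
    ``ellipse_major_mm`` columns.  Total distance sums displacements only
    between consecutive retained frames; mean speed is the mean of the
    per-frame speeds implied by those steps (frames following a gap — and
    frame 0 — contribute a speed of 0, mirroring the raw convention).
    """
    obj = object_id if object_id is not None else (
        int(good["object_id"].iloc[0]) if len(good) else -1
    )
    n_total = frames_total if frames_total is not None else len(good)
    n_removed = n_total - len(good)
    if len(good) == 0:
        return TrackSummary(
            obj, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
            float("nan"), float("nan"), float("nan"),
            n_total, n_removed, True,
        )
    good = good.reset_index(drop=True)
    step = _consecutive_steps(good, calibration)
    speeds = step * calibration.fps
    states = good["state"].to_numpy()
    elongated = states == "elongated"
    bent = states == "bent"

    total_distance = float(step.sum())
    mean_speed = float(speeds.mean())
    time_elongated = float(elongated.sum() / calibration.fps)
    time_bent = float(bent.sum() / calibration.fps)
    distance_elongated = float(step[elongated].sum())
    mean_speed_elongated = (
        float(speeds[elongated].mean()) if elongated.any() else 0.0
    )
    length = body_length(good)
    if np.isfinite(length) and length > 0:
        norm_distance = total_distance / length
        norm_speed = mean_speed / length
    else:
        norm_distance = float("nan")
        norm_speed = float("nan")
    return TrackSummary(
        object_id=obj,
        total_distance_mm=total_distance,
        mean_speed_mm_s=mean_speed,
        time_elongated_s=time_elongated,
        time_bent_s=time_bent,
        distance_elongated_mm=distance_elongated,
        mean_speed_elongated_mm_s=mean_speed_elongated,
        body_length_mm=float(length),
        normalised_distance=float(norm_distance),
        normalised_mean_speed=float(norm_speed),
        frames_total=n_total,
        frames_removed=n_removed,
        omit_recommended=omit_recommended,
    )


def body_length(good: pd.DataFrame) -> float:
    """Approximate body length: median ellipse major axis (mm) over
    elongated good frames.  NaN when the track has no elongated frame."""
    elongated = good.loc[good["state"] == "elongated", "ellipse_major_mm"]
    elongated = elongated.dropna()
    if len(elongated) == 0:
        return float("nan")
    return float(elongated.median())
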