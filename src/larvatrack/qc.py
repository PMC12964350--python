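"""Tracking-error detection and excision.

Segmentation-based trackers fail in a handful of characteristic ways:
the track detaches from the animal and freezes on background; two
animals collide and merge under one identity; an identity drifts or
switches to a different animal; an identity momentarily "jumps" across
the arena; two identities collapse onto one animal (duplicates).  Each
failure leaves a signature in the per-frame object-size or speed series,
and this module flags the affected frames, partitions every track into
inlier/outlier segments and resolves duplicate tracks.  All thresholds
live in :class:`QCConfig` and are user-configurable.

Comparison conventions: every threshold comparison is strict ("greater
than"), and the static-size rule compares raw integer pixel counts so
that exact equality is meaningful.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "QCConfig",
    "Segment",
    "QCReport",
    "flag_static_size",
    "segment_track",
    "infill_flags",
    "flag_size_jump",
    "flag_size_drift",
    "drift_candidate_windows",
    "flag_id_switch",
    "flag_statistical_outliers",
    "detect_duplicates",
    "run_qc_pipeline",
]


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the error-detection pipeline.

    static_run_min : frames
        A run of frames with *identical* object size longer than this is
        flagged as a detached (frozen) track.
    jump_threshold : mm^2
        Frame-to-frame absolute size change above this flags a collision
        merge.
    drift_median_kernel, drift_smooth_kernel : frames (odd)
        Median-filter kernel applied to the size series, and the
        moving-average kernel applied to its first difference, for the
        gradual-drift detector.
    drift_window : frames
        Sliding-window length over the smoothed difference signal.
    drift_fraction : proportion
        A window is a drift candidate when at least this fraction of its
        entries change size in the same direction.
    drift_min_delta : mm^2
        A candidate drift region is kept only when the filtered size at
        its start and end differ by more than this.
    baseline_min_frames : frames
        Minimum length of the inlier segment used as the size baseline
        for identity-switch detection.
    segment_median_delta : mm^2
        An inlier segment whose median size differs from the baseline by
        more than this is flagged as an identity switch.
    size_sd_limit, speed_sd_limit : s.d. units
        Statistical-outlier cuts on size and instantaneous speed.
    duplicate_min_frames : frames
        Two tracks whose centroids coincide for more than this many
        frames are duplicates.
    duplicate_tolerance_px : pixels
        Centroid distance below which two tracks "coincide" on a frame.
    infill_radius : frames
        Inlier frames within this distance of outlier segments on both
        sides are re-flagged; also the dilation applied around duplicate
        regions.
    omit_fraction : proportion
        Recommend omitting a track when more than this fraction of its
        frames is flagged.
    """

    static_run_min: int = 20
    jump_threshold: float = 1.5
    drift_median_kernel: int = 201
    drift_smooth_kernel: int = 11
    drift_window: int = 80
    drift_fraction: float = 0.75
    drift_min_delta: float = 1.0
    baseline_min_frames: int = 200
    segment_median_delta: float = 1.0
    size_sd_limit: float = 4.0
    speed_sd_limit: float = 5.0
    duplicate_min_frames: int = 100
    duplicate_tolerance_px: float = 0.5
    infill_radius: int = 20
    omit_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        for k in ("drift_median_kernel", "drift_smooth_kernel"):
            if getattr(self, k) % 2 == 0:
                raise ValueError(f"{k} must be odd")
        for k in ("drift_fraction", "omit_fraction"):
            if not (0 < getattr(self, k) <= 1):
                raise ValueError(f"{k} must lie in (0, 1]")


@dataclass(frozen=True)
class Segment:
    """Contiguous run of frames sharing inlier/outlier status (inclusive)."""

    start: int
    end: int
    label: str  # "inlier" | "outlier"

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class QCReport:
    """Summary of a QC run over a set of tracks."""

    flag_counts: dict[int, Counter] = field(default_factory=dict)
    removed_duplicates: list[int] = field(default_factory=list)
    omit_recommended: dict[int, bool] = field(default_factory=dict)

    def flagged_frames(self, object_id: int) -> int:
        return sum(self.flag_counts.get(object_id, Counter()).values())


# ---------------------------------------------------------------------------
# individual rules


def _runs_of_equal(values: np.ndarray):
    """Yield (start, end) inclusive runs of consecutive equal values."""
    n = len(values)
    if n == 0:
        return
    change = np.flatnonzero(values[1:] != values[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))
    yield from zip(starts.tolist(), ends.tolist())


def flag_static_size(sizes, config: QCConfig = QCConfig()) -> np.ndarray:
    """Flag maximal runs of identical consecutive sizes longer than the cut.

    Sizes should be the raw integer pixel counts so that equality is
    exact; the rule targets tracks frozen onto static background.
    """
    sizes = np.asarray(sizes)
    flags = np.zeros(len(sizes), dtype=bool)
    for start, end in _runs_of_equal(sizes):
        if end - start + 1 > config.static_run_min:
            flags[start : end + 1] = True
    return flags


def segment_track(flags) -> list[Segment]:
    """Partition a flag series into maximal inlier/outlier segments."""
    flags = np.asarray(flags, dtype=bool)
    return [
        Segment(start, end, "outlier" if flags[start] else "inlier")
        for start, end in _runs_of_equal(flags)
    ]


def infill_flags(flags, config: QCConfig = QCConfig()) -> np.ndarray:
    """Re-flag short inlier gaps sandwiched between outlier segments.

    A frame inside an inlier segment bounded by outlier segments on both
    sides is re-flagged iff it lies within ``infill_radius`` frames of
    the end of the preceding outlier segment *and* of the start of the
    following one.  Returns the boolean mask of newly flagged frames.
    """
    flags = np.asarray(flags, dtype=bool)
    segments = segment_track(flags)
    new = np.zeros_like(flags)
    for i, seg in enumerate(segments):
        if seg.label != "inlier" or i == 0 or i == len(segments) - 1:
            continue
        prev_end = segments[i - 1].end
        next_start = segments[i + 1].start
        frames = np.arange(seg.start, seg.end + 1)
        close = ((frames - prev_end) <= config.infill_radius) & (
            (next_start - frames) <= config.infill_radius
        )
        new[frames[close]] = True
    return new


def flag_size_jump(sizes_mm2, config: QCConfig = QCConfig()) -> np.ndarray:
    """Flag frames whose absolute size step from the previous frame
    exceeds ``jump_threshold`` (strict)."""
    sizes = np.asarray(sizes_mm2, dtype=float)
    flags = np.zeros(len(sizes), dtype=bool)
    if len(sizes) > 1:
        flags[1:] = np.abs(np.diff(sizes)) > config.jump_threshold
    return flags


def _drift_signals(sizes: np.ndarray, config: QCConfig):
    """Median-filtered size and smoothed first difference."""
    n = len(sizes)
    k = min(config.drift_median_kernel, n if n % 2 == 1 else n - 1)
    m = median_filter(sizes, size=k, mode="reflect")
    d = np.diff(m)
    d = uniform_filter1d(d, size=config.drift_smooth_kernel, mode="reflect")
    return m, d


def drift_candidate_windows(d: np.ndarray, config: QCConfig) -> np.ndarray:
    """Boolean mask over difference-signal windows: window ``i`` covers
    ``d[i : i + drift_window]`` and is a candidate when at least
    ``drift_fraction`` of its entries share one strict sign."""
    w = config.drift_window
    n = len(d)
    if n < w:
        return np.zeros(0, dtype=bool)
    need = config.drift_fraction * w
    pos = np.cumsum(np.concatenate(([0], (d > 0).astype(int))))
    neg = np.cumsum(np.concatenate(([0], (d < 0).astype(int))))
    npos = pos[w:] - pos[:-w]
    nneg = neg[w:] - neg[:-w]
    return (npos >= need) | (nneg >= need)


def flag_size_drift(sizes_mm2, config: QCConfig = QCConfig()) -> np.ndarray:
    """Flag gradual size drift (identity slowly transferring between
    animals during prolonged contact).

    The size series is median-filtered, differenced and smoothed; windows
    in which most frames change size in the same direction are merged
    into candidate regions, which are kept only when the filtered size
    rises or falls by more than ``drift_min_delta`` across the region.
    """
    sizes = np.asarray(sizes_mm2, dtype=float)
    n = len(sizes)
    flags = np.zeros(n, dtype=bool)
    if n < 2:
        return flags
    m, d = _drift_signals(sizes, config)
    if len(d) < config.drift_window:
        logger.info("track shorter than drift window; drift stage skipped")
        return flags
    cand = drift_candidate_windows(d, config)
    w = config.drift_window
    covered = np.zeros(len(d), dtype=bool)
    for i in np.flatnonzero(cand):
        covered[i : i + w] = True
    # union of overlapping candidate windows -> candidate segments
    for start, end in _runs_of_equal(covered):
        if not covered[start]:
            continue
        # d[j] is the change m[j] -> m[j+1]; the region spans frames
        # start .. end + 1
        f0, f1 = start, end + 1
        if abs(m[f1] - m[f0]) > config.drift_min_delta:
            flags[f0 : f1 + 1] = True
    return flags


def flag_id_switch(
    sizes_mm2, flags, config: QCConfig = QCConfig()
) -> np.ndarray:
    """Flag inlier segments whose median size departs from the baseline.

    The baseline is the median size of the first inlier segment with at
    least ``baseline_min_frames`` frames; when no segment qualifies the
    stage is skipped.  Every *other* inlier segment whose median differs
    from the baseline by more than ``segment_median_delta`` is flagged in
    full.  Returns the mask of newly flagged frames.
    """
    sizes = np.asarray(sizes_mm2, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    new = np.zeros_like(flags)
    inliers = [s for s in segment_track(flags) if s.label == "inlier"]
    baseline_seg = next(
        (s for s in inliers if len(s) >= config.baseline_min_frames), None
    )
    if baseline_seg is None:
        logger.info("no inlier segment long enough for a size baseline; "
                    "identity-switch stage skipped")
        return new
    baseline = np.median(sizes[baseline_seg.start : baseline_seg.end + 1])
    for seg in inliers:
        if seg is baseline_seg:
            continue
        med = np.median(sizes[seg.start : seg.end + 1])
        if abs(med - baseline) > config.segment_median_delta:
            new[seg.start : seg.end + 1] = True
    return new


def flag_statistical_outliers(
    sizes_mm2, speeds_mm_s, flags, config: QCConfig = QCConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Flag inlier frames more than ``size_sd_limit`` size s.d. or
    ``speed_sd_limit`` speed s.d. from the mean (strict exceedance).

    Moments are estimated over the currently-inlier frames only, so
    corruption caught by earlier stages cannot inflate the spread.
    Returns ``(size_outlier_mask, speed_outlier_mask)``.
    """
    flags = np.asarray(flags, dtype=bool)
    inlier = ~flags

    def _exceed(values, limit):
        out = np.zeros_like(flags)
        v = np.asarray(values, dtype=float)[inlier]
        if len(v) == 0:
            return out
        sd = v.std()
        if sd == 0:
            return out
        dev = np.abs(np.asarray(values, dtype=float) - v.mean())
        out[inlier & (dev > limit * sd)] = True
        return out

    return (
        _exceed(sizes_mm2, config.size_sd_limit),
        _exceed(speeds_mm_s, config.speed_sd_limit),
    )


def detect_duplicates(
    tracks: dict[int, pd.DataFrame], config: QCConfig = QCConfig()
) -> tuple[list[int], dict[int, np.ndarray]]:
    """Resolve duplicate tracks (two identities on one animal).

    For every pair of tracks, frames on which the two centroids coincide
    (distance <= ``duplicate_tolerance_px``) are counted; more than
    ``duplicate_min_frames`` coincident frames marks the pair as
    duplicated.  The track with more currently-flagged frames is removed
    (tie: the higher object id, i.e. the track is assigned to the first
    object).  On each surviving partner the coincident region, dilated by
    ``infill_radius`` frames, is flagged.

    Returns ``(removed_ids, duplicate_flag_masks)`` where the masks are
    aligned with the surviving tracks' rows.
    """
    ids = sorted(tracks)
    removed: list[int] = []
    dup_masks = {i: np.zeros(len(tracks[i]), dtype=bool) for i in ids}
    for a_pos, a in enumerate(ids):
        for b in ids[a_pos + 1 :]:
            if a in removed or b in removed:
                continue
            ta, tb = tracks[a], tracks[b]
            merged = ta[["frame", "x_px", "y_px"]].merge(
                tb[["frame", "x_px", "y_px"]], on="frame", suffixes=("_a", "_b")
            )
            dist = np.hypot(
                merged.x_px_a - merged.x_px_b, merged.y_px_a - merged.y_px_b
            )
            match_frames = merged.frame.to_numpy()[
                dist.to_numpy() <= config.duplicate_tolerance_px
            ]
            if len(match_frames) <= config.duplicate_min_frames:
                continue
            n_out_a = int((ta["flag_reason"] != "none").sum())
            n_out_b = int((tb["flag_reason"] != "none").sum())
            loser = b if n_out_b >= n_out_a else a
            keeper = a if loser == b else b
            removed.append(loser)
            keep_df = tracks[keeper]
            in_region = np.isin(keep_df["frame"].to_numpy(), match_frames)
            dup_masks[keeper] |= _dilate(in_region, config.infill_radius)
    return removed, {i: dup_masks[i] for i in ids if i not in removed}


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    out = mask.copy()
    for start, end in _runs_of_equal(mask):
        if mask[start]:
            out[max(0, start - radius) : end + radius + 1] = True
    return out


# ---------------------------------------------------------------------------
# pipeline

_STAGES = ("static", "infill", "jump", "drift", "switch", "statistical")


def run_qc_pipeline(
    tracks: dict[int, pd.DataFrame], config: QCConfig = QCConfig()
) -> tuple[dict[int, pd.DataFrame], QCReport]:
    """Run the full error pipeline over calibrated tracks.

    Each track DataFrame needs ``frame``, ``x_px``, ``y_px``, ``area_px``,
    ``area_mm2`` and ``speed_mm_s`` columns.  Stages run in fixed order:
    static size, infill, size jump, size drift, identity switch,
    statistical outliers, then duplicate resolution (with infill around
    duplicate regions).  The ``flag_reason`` column is set to the first
    rule that flags a frame; duplicates are dropped from the returned
    mapping.
    """
    out: dict[int, pd.DataFrame] = {}
    report = QCReport()
    for obj_id, df in tracks.items():
        df = df.reset_index(drop=True).copy()
        reasons = np.array(["none"] * len(df), dtype=object)

        def _apply(mask, reason, reasons=reasons):
            fresh = mask & (reasons == "none")
            reasons[fresh] = reason

        _apply(flag_static_size(df["area_px"].to_numpy(), config), "static_size")
        _apply(infill_flags(reasons != "none", config), "infill")
        _apply(flag_size_jump(df["area_mm2"].to_numpy(), config), "size_jump")
        _apply(flag_size_drift(df["area_mm2"].to_numpy(), config), "size_drift")
        _apply(
            flag_id_switch(df["area_mm2"].to_numpy(), reasons != "none", config),
            "id_switch",
        )
        size_out, speed_out = flag_statistical_outliers(
            df["area_mm2"].to_numpy(),
            df["speed_mm_s"].to_numpy(),
            reasons != "none",
            config,
        )
        _apply(size_out, "size_outlier")
        _apply(speed_out, "speed_outlier")
        df["flag_reason"] = reasons
        out[obj_id] = df

    removed, dup_masks = detect_duplicates(out, config)
    for obj_id in removed:
        del out[obj_id]
    for obj_id, mask in dup_masks.items():
        reasons = out[obj_id]["flag_reason"].to_numpy(dtype=object)
        reasons[mask & (reasons == "none")] = "duplicate"
        out[obj_id]["flag_reason"] = reasons

    report.removed_duplicates = removed
    for obj_id, df in out.items():
        flagged = df["flag_reason"] != "none"
        report.flag_counts[obj_id] = Counter(
            df.loc[flagged, "flag_reason"].tolist()
        )
        report.omit_recommended[obj_id] = (
            float(flagged.mean()) > config.omit_fraction if len(df) else True
        )
        logger.info(
            "object %d: %d/%d frames flagged %s",
            obj_id, int(flagged.sum()), len(df),
            dict(report.flag_counts[obj_id]),
        )
    return out, report
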