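"""End-to-end orchestration: video -> masks -> features -> posture -> QC
-> summaries -> output tree.

The output tree per video mirrors the layout downstream analysis
expects::

    out_dir/
      raw_frames/{id}.csv                 per-frame raw observations
      good_frames/{id}.csv                rows surviving QC
      problematic_frames/{id}.csv         excised rows (only when present)
      paths/{id}.png                      state-shaded path tracing
      problematic_frames_visualisation/{id}.jpg
      output.csv                          one summary row per retained object
      tracking.mp4 (or .tif)              annotated overlay video
      run.log
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import backend as backend_mod
from . import metrics, posture, qc, trackio, viz
from .features import (
    Calibration,
    UnfittableObjectError,
    axis_ratio,
    compute_scale_factor,
    fit_object_ellipse,
    mask_to_polygon,
    polygon_centroid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "extract_tracks",
    "annotate_tracks",
    "summarise_tracks",
    "run_single",
    "run_batch",
]

VIDEO_SUFFIXES = (".mp4", ".mov", ".avi", ".tif", ".tiff", ".npy", ".npz")


@dataclass
class RunConfig:
    """Configuration of a single-video or batch run.

    Exactly one calibration source must be given: either ``scale``
    (mm/px) directly, or ``calib_points`` (two pixel points) together
    with ``calib_distance_mm``.
    """

    video: str | Path | None = None
    out_dir: str | Path = "output"
    prompts: str | Path | list | None = None
    source_fps: float = 10.0
    target_fps: float | None = None
    scale: float | None = None
    calib_points: tuple[tuple[float, float], tuple[float, float]] | None = None
    calib_distance_mm: float | None = None
    qc_config: qc.QCConfig = field(default_factory=qc.QCConfig)
    posture_config: posture.PostureConfig = field(
        default_factory=posture.PostureConfig
    )
    backend: str = "reference"
    seed: int = 0

    def calibration(self) -> Calibration:
        has_scale = self.scale is not None
        has_points = self.calib_points is not None
        if has_scale == has_points:
            raise ValueError(
                "exactly one calibration source required: scale, or "
                "calib_points + calib_distance_mm"
            )
        fps = self.target_fps or self.source_fps
        if has_scale:
            return Calibration(scale=self.scale, fps=fps)
        if self.calib_distance_mm is None:
            raise ValueError("calib_points requires calib_distance_mm")
        scale = compute_scale_factor(*self.calib_points, self.calib_distance_mm)
        return Calibration(scale=scale, fps=fps)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw:
            raw["qc_config"] = qc.QCConfig(**raw.pop("qc"))
        if "posture" in raw:
            raw["posture_config"] = posture.PostureConfig(**raw.pop("posture"))
        if "calib_points" in raw and raw["calib_points"] is not None:
            raw["calib_points"] = tuple(tuple(p) for p in raw["calib_points"])
        return cls(**raw)


def extract_tracks(
    result: backend_mod.SegmentationResult, calibration: Calibration
) -> dict[int, pd.DataFrame]:
    """Per-frame geometric observations from segmentation masks.

    Frames whose contour cannot support an ellipse fit keep their
    centroid/area but carry NaN ellipse columns (posture will mark them
    ``undefined``); frames where an id is absent produce no row.
    """
    rows: dict[int, list[dict]] = {}
    for t in range(result.n_frames):
        for obj in result.present(t):
            mask = result.mask(t, obj)
            area_px = int(mask.sum())
            if area_px == 0:
                continue
            polygon = mask_to_polygon(mask)
            cx, cy = polygon_centroid(polygon)
            try:
                ell = fit_object_ellipse(polygon)
                major, minor = ell.major, ell.minor
                ratio, angle = axis_ratio(ell), ell.angle
            except UnfittableObjectError:
                major = minor = ratio = angle = np.nan
            rows.setdefault(obj, []).append(
                {
                    "frame": t,
                    "object_id": obj,
                    "x_px": cx,
                    "y_px": cy,
                    "area_px": area_px,
                    "area_mm2": float(calibration.area_mm2(area_px)),
                    "ellipse_major_mm": float(calibration.length_mm(major)),
                    "ellipse_minor_mm": float(calibration.length_mm(minor)),
                    "ratio": ratio,
                    "angle_deg": angle,
                }
            )
    return {
        obj: pd.DataFrame(obj_rows).reset_index(drop=True)
        for obj, obj_rows in sorted(rows.items())
    }


def annotate_tracks(
    tracks: dict[int, pd.DataFrame],
    calibration: Calibration,
    posture_config: posture.PostureConfig | None = None,
) -> dict[int, pd.DataFrame]:
    """Add posture (z-score, state) and kinematics (distance, speed)
    columns to raw tracks; posture statistics use all raw frames."""
    pcfg = posture_config or posture.PostureConfig()
    out = {}
    for obj, df in tracks.items():
        df = df.reset_index(drop=True).copy()
        ratios = df["ratio"].to_numpy(dtype=float)
        finite = np.isfinite(ratios)
        z = np.full(len(df), np.nan)
        states = np.array(["undefined"] * len(df), dtype=object)
        if finite.sum() >= 2:
            z[finite] = posture.ratio_zscores(ratios[finite])
            states[finite] = posture.classify_state(z[finite], pcfg)
        df["ratio_zscore"] = z
        df["state"] = states
        dist = metrics.frame_displacement(
            df["x_px"], df["y_px"], calibration, df["frame"]
        )
        df["distance_mm"] = dist
        df["speed_mm_s"] = metrics.frame_speed(dist, calibration, df["frame"])
        if "flag_reason" not in df.columns:
            df["flag_reason"] = "none"
        out[obj] = df
    return out


def summarise_tracks(
    cleaned: dict[int, pd.DataFrame],
    report: qc.QCReport,
    calibration: Calibration,
) -> pd.DataFrame:
    """One summary row per retained object, aggregated over good frames."""
    summaries = []
    for obj, df in cleaned.items():
        good = df[df["flag_reason"] == "none"]
        summaries.append(
            metrics.aggregate_track(
                good,
                calibration,
                object_id=obj,
                frames_total=len(df),
                omit_recommended=report.omit_recommended.get(obj, False),
            )
        )
    return pd.DataFrame([vars(s) for s in summaries])


def run_single(config: RunConfig, video: np.ndarray | None = None):
    """Analyse one video end to end and write the output tree.

    ``video`` may be passed directly as an array (frames first); when
    omitted it is read from ``config.video``.  Returns the summary
    DataFrame.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("larvatrack")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_single(config, video, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_single(config: RunConfig, video, out_dir: Path) -> pd.DataFrame:
    if video is None:
        if config.video is None:
            raise ValueError("no video given")
        video = trackio.read_video(config.video)
    if isinstance(config.prompts, (str, Path)):
        prompts = trackio.read_prompts_csv(config.prompts)
    elif config.prompts is None:
        raise ValueError("no point prompts given")
    else:
        prompts = list(config.prompts)
    calibration = config.calibration()

    if config.target_fps is not None and config.target_fps < config.source_fps:
        video, eff_fps = backend_mod.downsample_fps(
            video, config.source_fps, config.target_fps
        )
        calibration = Calibration(scale=calibration.scale, fps=eff_fps)
    logger.info(
        "analysing %d frames at %.3g fps, scale %.4g mm/px",
        len(video), calibration.fps, calibration.scale,
    )

    if config.backend != "reference":
        raise ValueError(f"unknown backend {config.backend!r}")
    result = backend_mod.segment_video(video, prompts)
    contract = backend_mod.backend_contract_check(result, video, prompts)
    if not contract.ok:
        raise RuntimeError(f"backend contract violated: {contract.messages}")

    raw = annotate_tracks(
        extract_tracks(result, calibration), calibration, config.posture_config
    )
    cleaned, report = qc.run_qc_pipeline(raw, config.qc_config)
    summary = summarise_tracks(cleaned, report, calibration)

    _write_tree(out_dir, video, result, raw, cleaned, report, summary, calibration)
    return summary


def _write_tree(
    out_dir: Path, video, result, raw, cleaned, report, summary, calibration
) -> None:
    for sub in (
        "raw_frames",
        "good_frames",
        "problematic_frames",
        "paths",
        "problematic_frames_visualisation",
    ):
        (out_dir / sub).mkdir(exist_ok=True)
    for obj, df in raw.items():
        trackio.write_track_csv(
            df if obj in cleaned else df.assign(flag_reason="duplicate"),
            out_dir / "raw_frames" / f"{obj}.csv",
        )
    for obj, df in cleaned.items():
        good = df[df["flag_reason"] == "none"]
        bad = df[df["flag_reason"] != "none"]
        trackio.write_track_csv(good, out_dir / "good_frames" / f"{obj}.csv")
        if len(bad):
            trackio.write_track_csv(
                bad, out_dir / "problematic_frames" / f"{obj}.csv"
            )
        viz.render_paths_image(
            good,
            out_dir / "paths" / f"{obj}.png",
            canvas_px=video.shape[1:3],
            object_id=obj,
        )
        viz.render_problem_scatter(
            df, out_dir / "problematic_frames_visualisation" / f"{obj}.jpg"
        )
    summary.to_csv(out_dir / "output.csv", index=False, float_format="%.6f")
    viz.render_tracking_video(
        video, result, out_dir / "tracking.mp4", fps=calibration.fps
    )


def run_batch(config: RunConfig, directory=None) -> dict[str, pd.DataFrame]:
    """Analyse every supported video in a directory.

    Prompt files are resolved up front (``<video stem>.prompts.csv``
    next to each video) before any tracking starts; a failure in one
    video is logged and does not abort the rest.
    """
    directory = Path(directory or config.video)
    videos = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in VIDEO_SUFFIXES
    )
    if not videos:
        raise FileNotFoundError(f"no supported videos in {directory}")
    jobs = []
    for vid in videos:
        prompts = config.prompts or vid.with_suffix(".prompts.csv")
        jobs.append((vid, prompts))
    results: dict[str, pd.DataFrame] = {}
    for vid, prompts in jobs:
        sub = replace(
            config,
            video=vid,
            prompts=prompts,
            out_dir=Path(config.out_dir) / vid.stem,
        )
        try:
            results[vid.name] = run_single(sub)
        except Exception:
            logger.exception("analysis of %s failed; continuing batch", vid)
    return results
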