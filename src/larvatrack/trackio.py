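"""Reading and writing track CSVs, prompt files, videos and summaries."""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .backend import PointPrompt

logger = logging.getLogger(__name__)

__all__ = [
    "TRACK_COLUMNS",
    "TrackParseError",
    "write_track_csv",
    "read_track_csv",
    "read_prompts_csv",
    "write_prompts_csv",
    "read_video",
    "write_video",
]

#: canonical per-frame track schema (one CSV per object id)
TRACK_COLUMNS = [
    "frame",
    "object_id",
    "x_px",
    "y_px",
    "area_mm2",
    "ellipse_major_mm",
    "ellipse_minor_mm",
    "ratio",
    "angle_deg",
    "ratio_zscore",
    "state",
    "distance_mm",
    "speed_mm_s",
    "flag_reason",
]

_INT_COLUMNS = {"frame", "object_id"}
_STR_COLUMNS = {"state", "flag_reason"}


class TrackParseError(ValueError):
    """Raised for malformed track CSV files."""


def write_track_csv(track: pd.DataFrame, path) -> None:
    """Write a track to CSV with the canonical column set.

    Floats are written with 6 decimal places, which bounds the
    round-trip error of ``read_track_csv(write_track_csv(x))``.
    """
    df = track.loc[:, TRACK_COLUMNS]
    df.to_csv(path, index=False, float_format="%.6f")


def read_track_csv(path) -> pd.DataFrame:
    """Read a track CSV, validating the schema.

    Raises
    ------
    TrackParseError
        Naming the missing column or the first malformed line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise TrackParseError(f"{path}: {exc}") from exc
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            raise TrackParseError(f"{path}: missing column '{col}'")
    df = df.loc[:, TRACK_COLUMNS]
    for col in TRACK_COLUMNS:
        if col in _STR_COLUMNS:
            df[col] = df[col].astype(object)
            continue
        kind = int if col in _INT_COLUMNS else float
        try:
            df[col] = df[col].astype(kind)
        except (TypeError, ValueError) as exc:
            bad = df.index[
                pd.to_numeric(df[col], errors="coerce").isna()
                & df[col].notna()
            ]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise TrackParseError(
                f"{path}: non-numeric value in column '{col}' at line {line}"
            ) from exc
    return df


def read_prompts_csv(path) -> list[PointPrompt]:
    """Read point prompts from a CSV with columns object_id,x,y,frame."""
    df = pd.read_csv(path)
    required = ["object_id", "x", "y"]
    for col in required:
        if col not in df.columns:
            raise TrackParseError(f"{path}: missing column '{col}'")
    frames = df["frame"] if "frame" in df.columns else pd.Series(0, index=df.index)
    return [
        PointPrompt(int(r.object_id), float(r.x), float(r.y), int(f))
        for (_, r), f in zip(df.iterrows(), frames)
    ]


def write_prompts_csv(prompts: list[PointPrompt], path) -> None:
    pd.DataFrame(
        [
            {"object_id": p.object_id, "x": p.x, "y": p.y, "frame": p.frame_index}
            for p in prompts
        ]
    ).to_csv(path, index=False)


def read_video(path) -> np.ndarray:
    """Load a video as a (frames, height, width[, channels]) array.

    Supports .npy/.npz arrays and multi-page TIFF natively; other
    containers (MP4/MOV/AVI) are delegated to imageio and require a
    codec plugin in the environment.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        return np.load(path)
    if suffix == ".npz":
        with np.load(path) as data:
            return data[list(data.files)[0]]
    if suffix in (".tif", ".tiff"):
        return tifffile.imread(path)
    try:
        return np.asarray(iio.imread(path))
    except Exception as exc:  # pragma: no cover - codec availability varies
        raise OSError(
            f"cannot read video {path}: {exc}. MP4/MOV/AVI support needs an "
            "ffmpeg-backed imageio plugin; TIFF stacks and .npy arrays are "
            "always supported."
        ) from exc


def write_video(frames: np.ndarray, path, fps: float = 10.0) -> Path:
    """Write video frames, falling back to a TIFF stack when no MP4
    codec is available.  Returns the path actually written."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        _write_tiff(path, np.asarray(frames))
        return path
    try:  # pragma: no cover - depends on installed codecs
        iio.imwrite(path, np.asarray(frames), fps=fps)
        return path
    except Exception:
        path.unlink(missing_ok=True)  # drop any partial file
        fallback = path.with_suffix(".tif")
        logger.warning(
            "no codec available for %s; writing TIFF stack %s", path, fallback
        )
        _write_tiff(fallback, np.asarray(frames))
        return fallback


def _write_tiff(path, frames: np.ndarray) -> None:
    photometric = "rgb" if frames.ndim == 4 and frames.shape[-1] == 3 else "minisblack"
    tifffile.imwrite(path, frames, photometric=photometric)
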