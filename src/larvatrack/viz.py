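"""Path tracings, annotated video overlays and QC scatterplots."""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import to_rgb
from skimage.segmentation import find_boundaries

from .backend import SegmentationResult
from .posture import state_runs
from .trackio import write_video

__all__ = [
    "render_paths_image",
    "render_tracking_video",
    "render_problem_scatter",
]

_PALETTE = plt.get_cmap("tab10").colors


def _object_color(object_id: int):
    return _PALETTE[object_id % len(_PALETTE)]


def render_paths_image(
    track: pd.DataFrame,
    path,
    *,
    canvas_px: tuple[int, int] | None = None,
    object_id: int | None = None,
) -> None:
    """Draw the centroid path of one track, shaded by posture state.

    Elongated stretches use the object's full colour; bent stretches a
    lighter tint of the same colour.  The canvas spans the video frame
    so tracings from one arena are directly comparable.
    """
    fig, ax = plt.subplots(figsize=(5, 5))
    if len(track) == 0:
        warnings.warn("empty track; writing blank path canvas", stacklevel=2)
    else:
        obj = object_id if object_id is not None else int(track["object_id"].iloc[0])
        base = np.array(to_rgb(_object_color(obj)))
        light = 1.0 - 0.55 * (1.0 - base)  # lighter tint for bent
        x = track["x_px"].to_numpy()
        y = track["y_px"].to_numpy()
        for state, s, e in state_runs(track["state"].tolist()):
            # include the joining vertex so the polyline is continuous
            e2 = min(e + 1, len(x) - 1)
            color = light if state == "bent" else base
            ax.plot(x[s : e2 + 1], y[s : e2 + 1], color=color, lw=1.2)
    if canvas_px is not None:
        ax.set_xlim(0, canvas_px[1])
        ax.set_ylim(0, canvas_px[0])
    ax.invert_yaxis()  # image convention: y down
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_tracking_video(
    frames: np.ndarray,
    result: SegmentationResult,
    path,
    fps: float = 10.0,
) -> Path:
    """Overlay colour-coded object outlines and id labels on the video.

    Frame count is preserved; frames in which an id is absent simply
    carry no overlay for it.  Returns the file actually written (TIFF
    fallback when no MP4 codec is present).
    """
    frames = np.asarray(frames)
    out = np.empty(frames.shape[:3] + (3,), dtype=np.uint8)
    for t in range(len(frames)):
        rgb = np.stack([frames[t]] * 3, axis=-1) if frames[t].ndim == 2 else frames[t]
        rgb = rgb.copy()
        for obj in result.present(t) if t < result.n_frames else []:
            mask = result.mask(t, obj)
            outline = find_boundaries(mask, mode="outer")
            color = (np.array(_object_color(obj)) * 255).astype(np.uint8)
            rgb[outline] = color
            ys, xs = np.nonzero(mask)
            if len(ys):
                _stamp_label(rgb, int(xs.mean()), int(ys.min()) - 6, obj, color)
        out[t] = rgb
    return write_video(out, path, fps=fps)


def _stamp_label(rgb: np.ndarray, x: int, y: int, object_id: int, color) -> None:
    """Stamp a small digit label near (x, y) using a 3x5 bitmap font."""
    digits = {
        "0": "111101101101111", "1": "010110010010111", "2": "111001111100111",
        "3": "111001111001111", "4": "101101111001001", "5": "111100111001111",
        "6": "111100111101111", "7": "111001001001001", "8": "111101111101111",
        "9": "111101111001111",
    }
    h, w = rgb.shape[:2]
    for k, ch in enumerate(str(object_id)):
        bits = digits[ch]
        for i in range(5):
            for j in range(3):
                if bits[i * 3 + j] == "1":
                    yy, xx = y + i, x + k * 4 + j
                    if 0 <= yy < h and 0 <= xx < w:
                        rgb[yy, xx] = color


def render_problem_scatter(track: pd.DataFrame, path) -> None:
    """Two-panel size/speed versus time scatter with removed frames
    highlighted in red."""
    flagged = (track["flag_reason"] != "none").to_numpy()
    fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    for ax, col, label in zip(
        axes, ("area_mm2", "speed_mm_s"), ("size (mm$^2$)", "speed (mm/s)")
    ):
        frames = track["frame"].to_numpy()
        values = track[col].to_numpy()
        ax.scatter(frames[~flagged], values[~flagged], s=3, color="tab:green",
                   label="kept")
        if flagged.any():
            ax.scatter(frames[flagged], values[flagged], s=3, color="tab:red",
                       label="removed")
        ax.set_ylabel(label)
        ax.legend(loc="upper right", fontsize=7)
    axes[1].set_xlabel("frame")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
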