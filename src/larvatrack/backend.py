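"""Segmentation backends: per-frame, per-object binary masks from video.

The pipeline only requires the contract defined here — given a video and
one point prompt per object on an annotation frame, produce a binary
mask per object per frame with stable identities.  The built-in
reference backend is a classical tracker (automatic intensity threshold,
connected components, greedy nearest-centroid identity propagation) that
works on high-contrast arena videos and on the synthetic scenes used in
the test-suite.  Foundation-model video segmenters can be plugged in
behind the same contract; such adapters own their model-specific
concerns (e.g. bounded inference-state memory windows, backward-in-time
propagation), which the contract deliberately leaves open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu, threshold_triangle

__all__ = [
    "PointPrompt",
    "SegmentationResult",
    "ContractReport",
    "UnresolvablePromptError",
    "downsample_fps",
    "segment_video",
    "backend_contract_check",
]


class UnresolvablePromptError(ValueError):
    """Raised when a point prompt does not fall inside any component."""


@dataclass(frozen=True)
class PointPrompt:
    """A user-supplied (x, y) click identifying one object on one frame."""

    object_id: int
    x: float
    y: float
    frame_index: int = 0


@dataclass
class SegmentationResult:
    """Per-frame object masks, stored as label images.

    ``labels[t]`` is an integer image in which pixels of object *i* carry
    value ``codes[t][i]`` (0 is background); objects are therefore
    disjoint within a frame.  ``mask(t, i)`` materialises the boolean
    mask for one object, or returns None when the id is absent from that
    frame.
    """

    labels: list[np.ndarray]
    codes: list[dict[int, int]]
    annotation_frame: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels[0].shape if self.labels else (0, 0)

    def present(self, t: int) -> list[int]:
        return sorted(self.codes[t])

    def mask(self, t: int, object_id: int) -> np.ndarray | None:
        code = self.codes[t].get(object_id)
        if code is None:
            return None
        return self.labels[t] == code

    @classmethod
    def from_masks(
        cls, per_frame_masks: list[dict[int, np.ndarray]], annotation_frame: int = 0
    ) -> "SegmentationResult":
        """Build a result from dense per-object boolean masks (later
        masks overwrite earlier ones where they overlap)."""
        labels, codes = [], []
        for masks in per_frame_masks:
            if masks:
                shape = next(iter(masks.values())).shape
            else:
                shape = labels[-1].shape if labels else (0, 0)
            lab = np.zeros(shape, dtype=np.int32)
            code_map = {}
            for k, (obj, m) in enumerate(sorted(masks.items()), start=1):
                lab[np.asarray(m, dtype=bool)] = k
                code_map[obj] = k
            labels.append(lab)
            codes.append(code_map)
        return cls(labels, codes, annotation_frame)


@dataclass
class ContractReport:
    ok: bool
    messages: list[str] = field(default_factory=list)


def downsample_fps(
    frames: np.ndarray, source_fps: float, target_fps: float
) -> tuple[np.ndarray, float]:
    """Temporal downsampling by integer frame striding.

    Keeps every ``round(source_fps / target_fps)``-th frame starting at
    frame 0 (output length ``ceil(n / stride)``) and returns the frames
    together with the effective frame rate ``source_fps / stride``.
    """
    if source_fps <= 0 or target_fps <= 0:
        raise ValueError("frame rates must be positive")
    if target_fps > source_fps:
        raise ValueError(
            f"target fps {target_fps} exceeds source fps {source_fps}"
        )
    stride = max(1, round(source_fps / target_fps))
    return frames[::stride], source_fps / stride


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        return frame.astype(float).mean(axis=-1)
    return frame.astype(float)


def _frame_components(
    frame: np.ndarray,
    threshold: str,
    min_area_px: int,
    max_area_px: float,
):
    gray = _to_gray(frame)
    if gray.max() == gray.min():
        return np.zeros(gray.shape, dtype=np.int32), []
    thr = (
        threshold_triangle(gray)
        if threshold == "triangle"
        else threshold_otsu(gray)
    )
    labels = measure.label(gray > thr, connectivity=2)
    props = [
        p
        for p in measure.regionprops(labels)
        if min_area_px <= p.area <= max_area_px
    ]
    return labels, props


def segment_video(
    frames: np.ndarray,
    prompts: list[PointPrompt],
    *,
    threshold: str = "triangle",
    min_area_px: int = 15,
    max_area_frac: float = 0.02,
    max_match_dist_px: float | None = None,
) -> SegmentationResult:
    """Reference segmentation backend.

    Each frame is thresholded with an automatic bimodal split (triangle
    method by default — robust when bright objects cover a small image
    fraction), connected components are filtered to a plausible area
    range, identities are seeded on the annotation frame by
    prompt-in-component lookup, and then propagated forward frame to
    frame by greedy nearest-centroid matching under a maximum match
    distance (default: 5x the mean blob radius on the annotation frame).
    An identity that finds no match within range is simply absent from
    that frame; downstream QC deals with the consequences.
    """
    frames = np.asarray(frames)
    n, h, w = frames.shape[:3]
    ann = {p.frame_index for p in prompts}
    if len(ann) != 1:
        raise ValueError("all prompts must lie on a single annotation frame")
    t0 = ann.pop()
    if not (0 <= t0 < n):
        raise ValueError(f"annotation frame {t0} outside video of {n} frames")
    max_area_px = max_area_frac * h * w

    labels0, props0 = _frame_components(
        frames[t0], threshold, min_area_px, max_area_px
    )
    prop_by_label = {p.label: p for p in props0}
    assigned: dict[int, int] = {}
    for p in prompts:
        xi, yi = int(round(p.x)), int(round(p.y))
        if not (0 <= xi < w and 0 <= yi < h):
            raise UnresolvablePromptError(
                f"prompt for object {p.object_id} at ({p.x}, {p.y}) "
                "is outside the frame"
            )
        lab = int(labels0[yi, xi])
        if lab == 0 or lab not in prop_by_label:
            raise UnresolvablePromptError(
                f"prompt for object {p.object_id} at ({p.x}, {p.y}) "
                "does not fall inside any detected component"
            )
        if lab in assigned.values():
            raise UnresolvablePromptError(
                f"prompt for object {p.object_id} lands in a component "
                "already claimed by another prompt"
            )
        assigned[p.object_id] = lab

    if max_match_dist_px is None:
        radii = [
            np.sqrt(prop_by_label[lab].area / np.pi)
            for lab in assigned.values()
        ]
        max_match_dist_px = 5.0 * float(np.mean(radii))

    result_labels: list[np.ndarray] = []
    result_codes: list[dict[int, int]] = []
    # last known centroid per id, (x, y); persists across absent frames so
    # a lost identity can be re-acquired
    last_centroid = {
        obj: (prop_by_label[lab].centroid[1], prop_by_label[lab].centroid[0])
        for obj, lab in assigned.items()
    }

    for t in range(t0, n):
        if t == t0:
            labels, props = labels0, props0
        else:
            labels, props = _frame_components(
                frames[t], threshold, min_area_px, max_area_px
            )
        if t == t0:
            codes = dict(assigned)
        else:
            codes = _greedy_match(last_centroid, props, max_match_dist_px)
        for obj, lab in codes.items():
            p = next(pp for pp in props if pp.label == lab)
            last_centroid[obj] = (p.centroid[1], p.centroid[0])
        result_labels.append(labels.astype(np.int32))
        result_codes.append(codes)

    # reference backend propagates forward only; frames before the
    # annotation frame carry no objects
    for _ in range(t0):
        result_labels.insert(0, np.zeros((h, w), dtype=np.int32))
        result_codes.insert(0, {})
    return SegmentationResult(result_labels, result_codes, annotation_frame=t0)


def _greedy_match(
    last_centroid: dict[int, tuple[float, float]],
    props,
    max_dist: float,
) -> dict[int, int]:
    """Greedily pair identities with components, nearest pair first."""
    pairs = []
    for obj, (x, y) in last_centroid.items():
        for p in props:
            d = float(np.hypot(p.centroid[1] - x, p.centroid[0] - y))
            if d <= max_dist:
                pairs.append((d, obj, p.label))
    pairs.sort()
    codes: dict[int, int] = {}
    used_labels: set[int] = set()
    for _, obj, lab in pairs:
        if obj in codes or lab in used_labels:
            continue
        codes[obj] = lab
        used_labels.add(lab)
    return codes


def backend_contract_check(
    result: SegmentationResult,
    frames: np.ndarray,
    prompts: list[PointPrompt],
) -> ContractReport:
    """Validate any backend's output against the segmentation contract:
    one output per video frame, shapes agree, every prompted id is
    present on the annotation frame, masks are binary."""
    messages = []
    frames = np.asarray(frames)
    if result.n_frames != len(frames):
        messages.append(
            f"frame count mismatch: {result.n_frames} != {len(frames)}"
        )
    elif result.n_frames and result.shape != frames.shape[1:3]:
        messages.append(
            f"mask shape {result.shape} != frame shape {frames.shape[1:3]}"
        )
    t0 = result.annotation_frame
    if result.n_frames > t0:
        present = set(result.present(t0))
        for p in prompts:
            if p.object_id not in present:
                messages.append(
                    f"object {p.object_id} missing on annotation frame {t0}"
                )
        for obj in present:
            m = result.mask(t0, obj)
            if m.dtype != bool:
                messages.append(f"mask for object {obj} is not binary")
    return ContractReport(ok=not messages, messages=messages)
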