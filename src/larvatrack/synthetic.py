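"""Synthetic larval-arena scenes with known ground truth.

The generator emulates the standard crawling assay this package targets:
a handful of third-instar-sized larvae in a 60 mm circular arena,
recorded at 10 fps for 3 minutes.  Each animal follows a first-order
Markov state machine over *run* (fast, elongated), *pause* (stationary,
elongated) and *head-cast* (slow, bent) states, with per-state ellipse
axes whose major/minor ratios are well separated between the elongated
and bent modes.  Scenes can be rendered to video frames (bright ellipses
on a dark arena disc) or converted directly to feature-level tracks, and
the six characteristic tracking-failure signatures can be injected with
exact per-frame ground-truth annotations for scoring error detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .backend import SegmentationResult
from .features import Calibration

__all__ = [
    "SceneSpec",
    "SceneData",
    "FailureInjection",
    "simulate_scene",
    "render_scene",
    "scene_tracks",
    "inject_failures",
    "score_detection",
]

RUN, PAUSE, CAST = 0, 1, 2
STATE_NAMES = ("run", "pause", "cast")

#: failure modes and the QC rule each one exercises
FAILURE_MODES = (
    "detachment",      # static_size
    "collision_merge",  # size_jump (+ id_switch on the merged segment)
    "size_drift",      # size_drift
    "id_switch",       # id_switch (boundary created by the drift stage)
    "jump",            # speed_outlier
    "duplicate",       # duplicate-track resolution
)


@dataclass(frozen=True)
class SceneSpec:
    """Study conditions for a synthetic arena recording.

    Defaults mirror the standard larval crawling assay: five animals in
    a 60 mm circular arena filmed for 180 s at 10 fps.  Larvae are
    ~4 x 1 mm ellipses when elongated (R = 4) and fold to ~2.8 x 1.4 mm
    when head-casting (R = 2), giving the posture classifier two well
    separated R modes.  Run speed of 1 mm/s is a typical third-instar
    crawl.
    """

    arena_diameter_mm: float = 60.0
    n_objects: int = 5
    fps: float = 10.0
    duration_s: float = 180.0
    scale: float = 0.15  # mm per pixel
    blob_major_mm: float = 4.0
    blob_minor_mm: float = 1.0
    bent_major_mm: float = 2.8
    bent_minor_mm: float = 1.4
    run_speed_mm_s: float = 1.0
    cast_speed_mm_s: float = 0.2
    p_run_to_cast: float = 0.02
    p_run_to_pause: float = 0.02
    p_cast_to_run: float = 0.12
    p_pause_to_run: float = 0.08
    heading_noise_sd: float = 0.15  # rad per frame while running
    cast_heading_sd: float = 0.5   # rad per frame while casting
    position_noise_sd_mm: float = 0.02
    axis_noise_sd_mm: float = 0.05
    area_noise_sd_mm2: float = 0.03
    min_separation_mm: float | None = None  # steer-away distance; None = off
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def arena_radius_mm(self) -> float:
        return self.arena_diameter_mm / 2

    def transition_matrix(self) -> np.ndarray:
        p = np.zeros((3, 3))
        p[RUN, CAST] = self.p_run_to_cast
        p[RUN, PAUSE] = self.p_run_to_pause
        p[CAST, RUN] = self.p_cast_to_run
        p[PAUSE, RUN] = self.p_pause_to_run
        for s in range(3):
            p[s, s] = 1.0 - p[s].sum()
        if (p < 0).any():
            raise ValueError("transition probabilities exceed 1")
        return p


@dataclass
class SceneData:
    """Ground truth of a simulated scene.

    Arrays are shaped ``(n_objects, n_frames)``; positions are mm in
    image convention with the arena centred in the frame.
    """

    spec: SceneSpec
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    state: np.ndarray  # int: RUN / PAUSE / CAST
    major: np.ndarray  # full axis lengths, mm
    minor: np.ndarray
    center_mm: tuple[float, float] = (0.0, 0.0)

    @property
    def n_objects(self) -> int:
        return self.x.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x.shape[1]

    def bent(self) -> np.ndarray:
        """Boolean ground-truth bent (head-cast) state per object/frame."""
        return self.state == CAST

    def path_length_mm(self, obj: int) -> float:
        return float(
            np.hypot(np.diff(self.x[obj]), np.diff(self.y[obj])).sum()
        )


def simulate_scene(spec: SceneSpec) -> SceneData:
    """Simulate ground-truth trajectories and posture states.

    Deterministic given ``spec.seed``.  Animals reflect off the arena
    wall; with ``min_separation_mm`` set they also steer away from each
    other, which keeps scenes collision-free.
    """
    rng = np.random.default_rng(spec.seed)
    n, T = spec.n_objects, spec.n_frames
    trans = spec.transition_matrix()
    wall = spec.arena_radius_mm - spec.blob_major_mm / 2
    c = spec.arena_radius_mm * 1.12  # frame centre, mm
    center = (c, c)

    # spawn well separated on a ring
    spawn_angles = 2 * np.pi * (np.arange(n) + rng.uniform(0, 1)) / max(n, 1)
    r0 = 0.55 * wall
    x = np.zeros((n, T))
    y = np.zeros((n, T))
    heading = np.zeros((n, T))
    state = np.zeros((n, T), dtype=np.int8)
    pos = np.stack(
        [c + r0 * np.cos(spawn_angles), c + r0 * np.sin(spawn_angles)], axis=1
    )
    phi = rng.uniform(0, 2 * np.pi, size=n)
    st = np.full(n, RUN, dtype=np.int8)
    speeds = np.array(
        [spec.run_speed_mm_s, 0.0, spec.cast_speed_mm_s]
    ) / spec.fps

    for t in range(T):
        for i in range(n):
            if t > 0:
                st[i] = rng.choice(3, p=trans[st[i]])
                if st[i] == RUN:
                    phi[i] += rng.normal(0, spec.heading_noise_sd)
                elif st[i] == CAST:
                    phi[i] += rng.normal(0, spec.cast_heading_sd)
                if spec.min_separation_mm is not None:
                    for j in range(n):
                        if j == i:
                            continue
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        if np.hypot(dx, dy) < spec.min_separation_mm:
                            phi[i] = np.arctan2(dy, dx)
                step = speeds[st[i]]
                nxt = pos[i] + step * np.array([np.cos(phi[i]), np.sin(phi[i])])
                if np.hypot(nxt[0] - c, nxt[1] - c) > wall:
                    # reflect heading off the (locally straight) wall
                    normal = np.arctan2(pos[i, 1] - c, pos[i, 0] - c)
                    phi[i] = 2 * normal + np.pi - phi[i]
                    nxt = pos[i] + step * np.array(
                        [np.cos(phi[i]), np.sin(phi[i])]
                    )
                pos[i] = nxt
            x[i, t], y[i, t] = pos[i]
            heading[i, t] = phi[i]
            state[i, t] = st[i]

    x += rng.normal(0, spec.position_noise_sd_mm, size=x.shape)
    y += rng.normal(0, spec.position_noise_sd_mm, size=y.shape)

    bent = state == CAST
    major = np.where(bent, spec.bent_major_mm, spec.blob_major_mm)
    minor = np.where(bent, spec.bent_minor_mm, spec.blob_minor_mm)
    major = major + rng.normal(0, spec.axis_noise_sd_mm, size=major.shape)
    minor = minor + rng.normal(0, spec.axis_noise_sd_mm / 2, size=minor.shape)
    return SceneData(spec, x, y, heading, state, major, minor, center)


def render_scene(
    scene: SceneData,
) -> tuple[np.ndarray, SegmentationResult]:
    """Rasterise a scene into grayscale video frames plus truth masks.

    Frames are uint8, with intensities 10 (outside), 30 (arena disc) and
    220 (animals); the returned :class:`SegmentationResult` holds the
    exact rendered masks with ground-truth identities.
    """
    spec = scene.spec
    size = int(np.ceil(2 * scene.center_mm[0] / spec.scale))
    frames = np.empty((scene.n_frames, size, size), dtype=np.uint8)
    bg = np.full((size, size), 10, dtype=np.uint8)
    rr, cc = draw_disk(
        (scene.center_mm[1] / spec.scale, scene.center_mm[0] / spec.scale),
        spec.arena_radius_mm / spec.scale,
        shape=bg.shape,
    )
    bg[rr, cc] = 30
    labels: list[np.ndarray] = []
    codes: list[dict[int, int]] = []
    for t in range(scene.n_frames):
        frame = bg.copy()
        lab = np.zeros((size, size), dtype=np.int32)
        code = {}
        for i in range(scene.n_objects):
            rr, cc = draw_ellipse(
                scene.y[i, t] / spec.scale,
                scene.x[i, t] / spec.scale,
                max(scene.minor[i, t], 0.2) / 2 / spec.scale,
                max(scene.major[i, t], 0.4) / 2 / spec.scale,
                # skimage rotates row-ward; negate to orient the major
                # axis along the heading in (x, y-down) convention
                rotation=-scene.heading[i, t],
                shape=frame.shape,
            )
            frame[rr, cc] = 220
            lab[rr, cc] = i + 1
            code[i] = i + 1
        frames[t] = frame
        labels.append(lab)
        codes.append(code)
    return frames, SegmentationResult(labels, codes)


def scene_tracks(
    scene: SceneData, calibration: Calibration | None = None
) -> dict[int, pd.DataFrame]:
    """Convert scene ground truth to feature-level track DataFrames.

    Bypasses rendering/segmentation: areas come from the analytic
    ellipse area plus measurement noise.  Useful for exercising posture,
    QC and metrics at scale.
    """
    spec = scene.spec
    cal = calibration or Calibration(scale=spec.scale, fps=spec.fps)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    tracks = {}
    for i in range(scene.n_objects):
        area = (
            np.pi / 4 * scene.major[i] * scene.minor[i]
            + rng.normal(0, spec.area_noise_sd_mm2, size=scene.n_frames)
        )
        area_px = np.maximum(np.round(area / cal.scale**2), 1).astype(int)
        tracks[i] = pd.DataFrame(
            {
                "frame": np.arange(scene.n_frames),
                "object_id": i,
                "x_px": scene.x[i] / cal.scale,
                "y_px": scene.y[i] / cal.scale,
                "area_px": area_px,
                "area_mm2": area_px * cal.scale**2,
                "ellipse_major_mm": scene.major[i],
                "ellipse_minor_mm": scene.minor[i],
                "ratio": scene.major[i] / np.maximum(scene.minor[i], 1e-6),
                "angle_deg": np.rad2deg(scene.heading[i]) % 180.0,
            }
        )
    return tracks


# ---------------------------------------------------------------------------
# failure injection


@dataclass(frozen=True)
class FailureInjection:
    """One injected tracking failure.

    ``start``/``end`` are inclusive frame indices of the *event* (the
    frames a QC pipeline ought to excise).  ``magnitude`` is
    mode-specific: mm^2 size offset for collision/drift/switch modes, mm
    displacement for jumps, unused for detachment; ``source_id`` names
    the track whose centroids a duplicate copies.
    """

    mode: str
    object_id: int
    start: int
    end: int
    magnitude: float = 0.0
    source_id: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in FAILURE_MODES:
            raise ValueError(f"unknown failure mode {self.mode!r}")
        if not (0 <= self.start <= self.end):
            raise ValueError("invalid event frame span")
        # the injected signature must satisfy the matching QC trigger
        if self.mode == "collision_merge" and self.magnitude <= 1.5:
            raise ValueError("collision step must exceed 1.5 mm^2")
        if self.mode in ("size_drift", "id_switch") and self.magnitude <= 1.0:
            raise ValueError(f"{self.mode} magnitude must exceed 1 mm^2")
        if self.mode == "detachment" and self.end - self.start < 20:
            raise ValueError("frozen run must exceed 20 frames")
        if self.mode == "duplicate" and self.source_id is None:
            raise ValueError("duplicate injection needs a source_id")


def inject_failures(
    tracks: dict[int, pd.DataFrame],
    injections: list[FailureInjection],
    calibration: Calibration,
) -> tuple[dict[int, pd.DataFrame], dict[int, np.ndarray]]:
    """Corrupt tracks with failure signatures; return truth annotations.

    Returns ``(corrupted_tracks, truth)`` where ``truth[object_id]`` is
    the boolean per-frame ground-truth "erroneous" mask.  Overlapping
    injections on one object are rejected.
    """
    out = {i: df.copy().reset_index(drop=True) for i, df in tracks.items()}
    truth = {i: np.zeros(len(df), dtype=bool) for i, df in tracks.items()}
    seen: dict[int, list[tuple[int, int]]] = {}
    for inj in injections:
        df = out[inj.object_id]
        n = len(df)
        s, e = inj.start, min(inj.end, n - 1)
        for (s0, e0) in seen.setdefault(inj.object_id, []):
            if s <= e0 and e >= s0:
                raise ValueError(
                    f"overlapping injections on object {inj.object_id}"
                )
        seen[inj.object_id].append((s, e))
        sl = slice(s, e)  # label-based, inclusive
        if inj.mode == "detachment":
            for col in ("x_px", "y_px", "area_px", "area_mm2"):
                df.loc[sl, col] = df.at[s, col]
        elif inj.mode == "collision_merge":
            _shift_area(df, sl, inj.magnitude, calibration)
        elif inj.mode == "size_drift":
            ramp = np.linspace(0.0, inj.magnitude, e - s + 1)
            _shift_area(df, sl, ramp, calibration)
            if e + 1 < n:  # identity stays on the wrong animal afterwards
                _shift_area(df, slice(e + 1, n - 1), inj.magnitude, calibration)
        elif inj.mode == "id_switch":
            _shift_area(df, sl, inj.magnitude, calibration)
        elif inj.mode == "jump":
            df.loc[sl, "x_px"] += inj.magnitude / calibration.scale
        elif inj.mode == "duplicate":
            src = out[inj.source_id]
            df.loc[sl, "x_px"] = src.loc[sl, "x_px"].to_numpy()
            df.loc[sl, "y_px"] = src.loc[sl, "y_px"].to_numpy()
        truth[inj.object_id][s : e + 1] = True
    return out, truth


def _shift_area(df: pd.DataFrame, sl: slice, delta, calibration: Calibration):
    """Add a mm^2 offset to the size signal, keeping px/mm^2 consistent."""
    area = df.loc[sl, "area_mm2"].to_numpy() + delta
    area_px = np.maximum(np.round(area / calibration.scale**2), 1).astype(int)
    df.loc[sl, "area_px"] = area_px
    df.loc[sl, "area_mm2"] = area_px * calibration.scale**2


def score_detection(
    qc_flags: dict[int, np.ndarray],
    injections: list[FailureInjection],
    removed_ids: tuple[int, ...] | list[int] = (),
    *,
    min_overlap: float = 0.5,
) -> tuple[float, list[bool]]:
    """Event-level detection rate of a QC run against injected truth.

    An injected event counts as detected when at least ``min_overlap``
    of its frames carry any QC flag; a track removed outright (duplicate
    resolution) counts as fully flagged.  Returns the rate and the
    per-event outcomes in injection order.
    """
    outcomes = []
    for inj in injections:
        if inj.object_id in removed_ids:
            outcomes.append(True)
            continue
        flags = np.asarray(qc_flags[inj.object_id], dtype=bool)
        e = min(inj.end, len(flags) - 1)
        event = flags[inj.start : e + 1]
        outcomes.append(float(event.mean()) >= min_overlap)
    rate = float(np.mean(outcomes)) if outcomes else 0.0
    return rate, outcomes


# ---------------------------------------------------------------------------
# canned injection experiment (used by the validation suite)


def default_injection_plan(
    n_tracks: int,
    n_frames: int,
    rng: np.random.Generator,
    modes: tuple[str, ...] = (
        "detachment",
        "collision_merge",
        "size_drift",
        "id_switch",
        "jump",
    ),
) -> list[FailureInjection]:
    """One failure event per track, cycling through ``modes``, with
    magnitudes that satisfy each QC rule's trigger condition and onsets
    placed after a clean >= 300-frame baseline."""
    plan = []
    for i in range(n_tracks):
        mode = modes[i % len(modes)]
        if mode == "detachment":
            s = int(rng.integers(320, n_frames - 400))
            plan.append(FailureInjection(mode, i, s, s + 59))
        elif mode == "collision_merge":
            s = int(rng.integers(320, n_frames - 400))
            plan.append(FailureInjection(mode, i, s, s + 119, magnitude=2.0))
        elif mode == "size_drift":
            s = int(rng.integers(320, n_frames - 500))
            plan.append(FailureInjection(mode, i, s, s + 249, magnitude=2.0))
        elif mode == "id_switch":
            s = int(rng.integers(320, n_frames - 600))
            plan.append(
                FailureInjection(mode, i, s, n_frames - 1, magnitude=1.2)
            )
        elif mode == "jump":
            s = int(rng.integers(320, n_frames - 400))
            plan.append(FailureInjection(mode, i, s, s, magnitude=15.0))
        else:
            raise ValueError(f"mode {mode} not supported in the default plan")
    return plan


def run_injection_experiment(
    n_tracks: int = 100,
    n_frames: int = 1800,
    seed: int = 0,
    qc_config=None,
    posture_config=None,
) -> dict:
    """Simulate single-animal tracks, inject one failure event per track
    and score QC detection.  Returns a dict with the detection rate, the
    per-event outcomes and the injection plan."""
    from .pipeline import annotate_tracks
    from .qc import QCConfig, run_qc_pipeline

    qc_config = qc_config or QCConfig()
    rng = np.random.default_rng(seed)
    all_tracks: dict[int, pd.DataFrame] = {}
    spec0 = SceneSpec(duration_s=n_frames / 10.0, fps=10.0)
    cal = Calibration(scale=spec0.scale, fps=spec0.fps)
    for i in range(n_tracks):
        spec = replace(spec0, n_objects=1, seed=int(rng.integers(2**31)))
        scene = simulate_scene(spec)
        all_tracks[i] = scene_tracks(scene, cal)[0].assign(object_id=i)

    plan = default_injection_plan(n_tracks, n_frames, rng)
    corrupted, truth = inject_failures(all_tracks, plan, cal)
    annotated = annotate_tracks(corrupted, cal, posture_config)
    # QC each track independently: these are single-animal simulations,
    # not co-recorded objects, so no duplicate resolution applies
    flags: dict[int, np.ndarray] = {}
    for i, df in annotated.items():
        cleaned, _ = run_qc_pipeline({i: df}, qc_config)
        flags[i] = (cleaned[i]["flag_reason"] != "none").to_numpy()
    rate, outcomes = score_detection(flags, plan)
    return {
        "rate": rate,
        "outcomes": outcomes,
        "plan": plan,
        "truth": truth,
        "flags": flags,
    }
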