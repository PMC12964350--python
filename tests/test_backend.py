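import numpy as np
import pytest

from larvatrack.backend import (
    PointPrompt,
    SegmentationResult,
    UnresolvablePromptError,
    backend_contract_check,
    downsample_fps,
    segment_video,
)
from larvatrack.features import Calibration
from larvatrack.pipeline import annotate_tracks, extract_tracks
from larvatrack.qc import run_qc_pipeline
from larvatrack.synthetic import SceneData, SceneSpec, render_scene, simulate_scene


class TestDownsample:
    def test_stride_three(self):
        frames = np.arange(90)
        out, fps = downsample_fps(frames, 30.0, 10.0)
        assert len(out) == 30
        assert list(out[:4]) == [0, 3, 6, 9]
        assert fps == pytest.approx(10.0)

    def test_identity_when_target_equals_source(self):
        frames = np.arange(50)
        out, fps = downsample_fps(frames, 30.0, 30.0)
        assert np.array_equal(out, frames)
        assert fps == 30.0

    def test_ceil_frame_count(self):
        out, _ = downsample_fps(np.arange(91), 30.0, 10.0)
        assert len(out) == 31

    def test_target_above_source_rejected(self):
        with pytest.raises(ValueError):
            downsample_fps(np.arange(10), 10.0, 30.0)


def _scene_prompts(scene):
    spec = scene.spec
    return [
        PointPrompt(i, scene.x[i, 0] / spec.scale, scene.y[i, 0] / spec.scale)
        for i in range(scene.n_objects)
    ]


class TestReferenceBackend:
    @pytest.fixture(scope="class")
    def tracked(self, ):
        spec = SceneSpec(
            n_objects=5, duration_s=10.0, seed=3, min_separation_mm=8.0
        )
        scene = simulate_scene(spec)
        frames, _ = render_scene(scene)
        prompts = _scene_prompts(scene)
        return scene, frames, prompts, segment_video(frames, prompts)

    def test_recovered_centroids_match_ground_truth(self, tracked):
        scene, frames, prompts, result = tracked
        spec = scene.spec
        cal = Calibration(spec.scale, spec.fps)
        tracks = extract_tracks(result, cal)
        for i in range(scene.n_objects):
            df = tracks[i]
            assert len(df) == scene.n_frames  # no dropped frames
            dx = df["x_px"].to_numpy() - scene.x[i] / spec.scale
            dy = df["y_px"].to_numpy() - scene.y[i] / spec.scale
            assert np.hypot(dx, dy).max() < 1.0

    def test_no_id_switches_on_collision_free_scene(self, tracked):
        scene, frames, prompts, result = tracked
        # identity of each mask centroid stays closest to the matching
        # ground-truth trajectory on every frame
        spec = scene.spec
        for t in range(scene.n_frames):
            for obj in result.present(t):
                mask = result.mask(t, obj)
                ys, xs = np.nonzero(mask)
                cx, cy = xs.mean(), ys.mean()
                d = np.hypot(
                    scene.x[:, t] / spec.scale - cx,
                    scene.y[:, t] / spec.scale - cy,
                )
                assert int(np.argmin(d)) == obj

    def test_deterministic(self, tracked):
        scene, frames, prompts, result = tracked
        again = segment_video(frames, prompts)
        assert all(
            np.array_equal(a, b) for a, b in zip(result.labels, again.labels)
        )
        assert result.codes == again.codes

    def test_prompt_in_background_rejected(self, tracked):
        scene, frames, prompts, _ = tracked
        bad = [PointPrompt(0, 2.0, 2.0)]  # dark corner
        with pytest.raises(UnresolvablePromptError):
            segment_video(frames, bad)

    def test_contract_check_passes(self, tracked):
        scene, frames, prompts, result = tracked
        assert backend_contract_check(result, frames, prompts).ok


class TestCollisionScenario:
    def test_touching_blobs_leave_qc_signature(self):
        """Two animals steered into sustained contact are merged by the
        backend; the surviving identity's size series must trip the
        collision-family QC rules downstream."""
        spec = SceneSpec(n_objects=2, duration_s=60.0, seed=0)
        n = spec.n_frames
        c = spec.arena_radius_mm * 1.12
        t_axis = np.arange(n) / spec.fps
        # object 0 stationary at centre; object 1 approaches, overlaps
        # for ~20 s, then leaves
        x1 = c + np.interp(t_axis, [0, 15, 35, 60], [20.0, 1.0, 1.0, 20.0])
        scene = SceneData(
            spec=spec,
            x=np.stack([np.full(n, c), x1]),
            y=np.full((2, n), c),
            heading=np.zeros((2, n)),
            state=np.zeros((2, n), dtype=np.int8),
            major=np.full((2, n), spec.blob_major_mm),
            minor=np.full((2, n), spec.blob_minor_mm),
            center_mm=(c, c),
        )
        frames, _ = render_scene(scene)
        prompts = _scene_prompts(scene)
        result = segment_video(frames, prompts)
        cal = Calibration(spec.scale, spec.fps)
        tracks = annotate_tracks(extract_tracks(result, cal), cal)
        cleaned, report = run_qc_pipeline(tracks)
        reasons = set()
        for counts in report.flag_counts.values():
            reasons |= set(counts)
        assert reasons & {"size_jump", "size_drift", "id_switch", "size_outlier"}


class TestContractCheck:
    def test_missing_annotation_id_fails(self):
        masks = [{1: np.zeros((5, 5), dtype=bool)}]
        result = SegmentationResult.from_masks(masks)
        report = backend_contract_check(
            result, np.zeros((1, 5, 5)), [PointPrompt(0, 1, 1), PointPrompt(1, 3, 3)]
        )
        assert not report.ok
        assert any("missing" in m for m in report.messages)

    def test_non_binary_mask_fails(self):
        result = SegmentationResult(
            labels=[np.ones((5, 5), dtype=np.int32)], codes=[{0: 1}]
        )
        result.mask = lambda t, obj: np.ones((5, 5), dtype=np.uint8)  # defective backend
        report = backend_contract_check(
            result, np.zeros((1, 5, 5)), [PointPrompt(0, 1, 1)]
        )
        assert not report.ok
        assert any("binary" in m for m in report.messages)

    def test_frame_count_mismatch_fails(self):
        result = SegmentationResult.from_masks(
            [{0: np.zeros((5, 5), dtype=bool)}]
        )
        report = backend_contract_check(
            result, np.zeros((3, 5, 5)), [PointPrompt(0, 1, 1)]
        )
        assert not report.ok
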