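import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import median_filter, uniform_filter1d

from larvatrack.features import Calibration
from larvatrack.pipeline import annotate_tracks
from larvatrack.qc import (
    QCConfig,
    Segment,
    detect_duplicates,
    flag_id_switch,
    flag_size_drift,
    flag_size_jump,
    flag_static_size,
    flag_statistical_outliers,
    infill_flags,
    run_qc_pipeline,
    segment_track,
)
from larvatrack.synthetic import (
    FailureInjection,
    SceneSpec,
    inject_failures,
    scene_tracks,
    simulate_scene,
)

CFG = QCConfig()


def drift_oracle(sizes, config=CFG):
    """Brute-force drift detector: counts signs in every window with an
    explicit O(n*W) loop, merges overlapping candidate windows by frame
    painting, and applies the start/end delta test."""
    sizes = np.asarray(sizes, dtype=float)
    n = len(sizes)
    flags = np.zeros(n, dtype=bool)
    if n < 2:
        return flags
    k = min(config.drift_median_kernel, n if n % 2 == 1 else n - 1)
    m = median_filter(sizes, size=k, mode="reflect")
    d = uniform_filter1d(np.diff(m), size=config.drift_smooth_kernel,
                         mode="reflect")
    w = config.drift_window
    if len(d) < w:
        return flags
    covered = np.zeros(len(d), dtype=bool)
    for i in range(len(d) - w + 1):
        window = d[i : i + w]
        npos = int((window > 0).sum())
        nneg = int((window < 0).sum())
        if npos >= config.drift_fraction * w or nneg >= config.drift_fraction * w:
            covered[i : i + w] = True
    # walk covered runs manually
    j = 0
    while j < len(covered):
        if not covered[j]:
            j += 1
            continue
        start = j
        while j < len(covered) and covered[j]:
            j += 1
        end = j - 1
        if abs(m[end + 1] - m[start]) > config.drift_min_delta:
            flags[start : end + 2] = True
    return flags


class TestStaticSize:
    def test_run_longer_than_cut_flagged(self):
        sizes = [5] * 25 + list(range(6, 20))
        flags = flag_static_size(np.array(sizes))
        assert flags[:25].all() and not flags[25:].any()

    def test_short_run_unflagged(self):
        sizes = [5] * 15 + list(range(6, 20))
        assert not flag_static_size(np.array(sizes)).any()

    def test_strictly_increasing_unflagged(self):
        assert not flag_static_size(np.arange(100)).any()

    def test_boundary_exact_run_length(self):
        # 20 == static_run_min is not "more than 20"; 21 is
        assert not flag_static_size(np.array([3] * 20 + [4, 5, 6])).any()
        assert flag_static_size(np.array([3] * 21 + [4, 5, 6]))[:21].all()


class TestSegmentsAndInfill:
    def test_segment_example(self):
        segs = segment_track([0, 0, 1, 1, 0])
        assert segs == [
            Segment(0, 1, "inlier"),
            Segment(2, 3, "outlier"),
            Segment(4, 4, "inlier"),
        ]

    def test_all_unflagged_single_segment(self):
        assert segment_track([0] * 10) == [Segment(0, 9, "inlier")]

    def test_all_flagged_single_segment(self):
        assert segment_track([1] * 10) == [Segment(0, 9, "outlier")]

    def test_segments_cover_track(self):
        rng = np.random.default_rng(0)
        flags = rng.random(200) < 0.3
        segs = segment_track(flags)
        assert segs[0].start == 0 and segs[-1].end == 199
        for a, b in zip(segs, segs[1:]):
            assert b.start == a.end + 1 and b.label != a.label

    def test_short_gap_fully_infilled(self):
        flags = np.zeros(30, dtype=bool)
        flags[0:10] = True
        flags[20:30] = True
        new = infill_flags(flags)
        assert new[10:20].all()
        assert not new[flags].any()  # only inlier frames are re-flagged

    def test_wide_gap_not_infilled(self):
        flags = np.zeros(140, dtype=bool)
        flags[0:10] = True
        flags[110:120] = True
        new = infill_flags(flags)
        # frames within 20 of BOTH neighbours: none (gap of 100)
        assert not new.any()

    def test_leading_inlier_segment_never_infilled(self):
        flags = np.zeros(50, dtype=bool)
        flags[30:40] = True
        assert not infill_flags(flags)[:30].any()


class TestSizeJump:
    def test_step_above_threshold_flagged(self):
        flags = flag_size_jump(np.array([2.0, 3.6]))
        assert list(flags) == [False, True]

    def test_step_below_threshold_unflagged(self):
        assert not flag_size_jump(np.array([2.0, 3.4])).any()

    def test_constant_series_unflagged(self):
        assert not flag_size_jump(np.full(50, 2.0)).any()

    def test_lowering_threshold_never_unflags(self):
        rng = np.random.default_rng(3)
        sizes = np.cumsum(rng.normal(0, 0.8, size=300)) + 5
        loose = flag_size_jump(sizes, QCConfig(jump_threshold=2.0))
        tight = flag_size_jump(sizes, QCConfig(jump_threshold=1.0))
        assert (tight | loose).sum() == tight.sum()  # loose subset of tight


class TestSizeDrift:
    def test_ramp_flagged_flat_not(self):
        rng = np.random.default_rng(5)
        sizes = np.concatenate(
            [3 + 0.02 * np.arange(300), np.full(700, 9.0)]
        ) + rng.normal(0, 0.05, 1000)
        flags = flag_size_drift(sizes)
        assert np.array_equal(flags, drift_oracle(sizes))
        assert flags[:300].mean() > 0.8  # ramp mostly flagged
        # flat region far from the smeared boundary stays clean
        assert not flags[450:].any()

    def test_iid_noise_unflagged(self):
        rng = np.random.default_rng(6)
        sizes = 3 + rng.normal(0, 0.2, size=1000)
        flags = flag_size_drift(sizes)
        assert not flags.any()
        assert not drift_oracle(sizes).any()

    def test_small_total_rise_rejected_by_delta_test(self):
        # monotone ramp whose total rise stays below drift_min_delta
        sizes = 3 + np.linspace(0, 0.5, 600)
        assert not flag_size_drift(sizes).any()

    def test_track_shorter_than_window_skipped(self):
        assert not flag_size_drift(np.linspace(0, 5, 50)).any()

    def test_oracle_equivalence_random_tracks(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            sizes = _random_size_track(rng, 1200)
            assert np.array_equal(flag_size_drift(sizes), drift_oracle(sizes))


def _random_size_track(rng, n):
    """Noise plus occasional ramps and steps, exercising all branches."""
    sizes = 3 + rng.normal(0, 0.1, size=n)
    for _ in range(rng.integers(0, 4)):
        s = int(rng.integers(0, n - 200))
        length = int(rng.integers(100, 400))
        e = min(s + length, n)
        kind = rng.integers(0, 2)
        mag = float(rng.uniform(0.3, 3.0)) * (1 if rng.random() < 0.5 else -1)
        if kind == 0:
            sizes[s:e] += np.linspace(0, mag, e - s)
            sizes[e:] += mag
        else:
            sizes[s:e] += mag
    return sizes


class TestIdSwitch:
    def _flags_for(self, sizes, outliers):
        return flag_id_switch(np.asarray(sizes, float), outliers)

    def test_shifted_segment_flagged(self):
        sizes = [2.0] * 300 + [0.0] * 10 + [3.5] * 150
        outliers = np.array([False] * 300 + [True] * 10 + [False] * 150)
        new = self._flags_for(sizes, outliers)
        assert new[310:].all() and not new[:310].any()

    def test_small_median_shift_unflagged(self):
        sizes = [2.0] * 300 + [0.0] * 10 + [2.5] * 150
        outliers = np.array([False] * 300 + [True] * 10 + [False] * 150)
        assert not self._flags_for(sizes, outliers).any()

    def test_no_long_baseline_skips_stage(self):
        sizes = [2.0] * 150 + [9.0] * 150
        outliers = np.zeros(300, dtype=bool)
        outliers[150] = True
        assert not self._flags_for(sizes, outliers).any()

    @pytest.mark.parametrize("delta,expect", [(0.5, False), (1.5, True)])
    def test_median_delta_boundary(self, delta, expect):
        sizes = [2.0] * 250 + [0.0] * 5 + [2.0 + delta] * 100
        outliers = np.array([False] * 250 + [True] * 5 + [False] * 100)
        assert self._flags_for(sizes, outliers)[255:].all() == expect


class TestStatisticalOutliers:
    def test_speed_spike_flagged(self):
        rng = np.random.default_rng(8)
        speeds = rng.normal(1.0, 0.1, size=500)
        speeds[250] = 2.0
        sizes = np.full(500, 3.0)
        flags = np.zeros(500, dtype=bool)
        _, speed_out = flag_statistical_outliers(sizes, speeds, flags)
        # independent check of the exceedance
        inl = np.delete(np.arange(500), [])
        mean, sd = speeds[inl].mean(), speeds[inl].std()
        assert abs(speeds[250] - mean) > 5 * sd
        assert speed_out[250]
        assert speed_out.sum() == 1

    def test_constant_series_never_flagged(self):
        sizes = np.full(100, 2.0)
        speeds = np.full(100, 1.0)
        s, p = flag_statistical_outliers(sizes, speeds, np.zeros(100, bool))
        assert not s.any() and not p.any()

    def test_exact_four_sd_boundary_not_flagged(self):
        # 16 zeros and one 17: the 17 sits exactly 4 population s.d.
        # from the mean (all quantities exact in binary floating point)
        sizes = np.array([0.0] * 16 + [17.0])
        speeds = np.zeros(17)
        s, _ = flag_statistical_outliers(sizes, speeds, np.zeros(17, bool))
        assert not s.any()

    def test_moments_use_inlier_frames_only(self):
        sizes = np.full(400, 3.0)
        sizes[:50] = 50.0  # corrupt but already flagged
        flags = np.zeros(400, dtype=bool)
        flags[:50] = True
        sizes[200] = 3.5
        s, _ = flag_statistical_outliers(sizes, np.zeros(400), flags)
        # inlier sd is tiny, so the 3.5 bump is an outlier; had the
        # flagged frames leaked into the moments it would pass unnoticed
        assert s[200]


def _toy_track(obj, n, x=None, y=None, flagged=0):
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "object_id": obj,
            "x_px": x if x is not None else np.linspace(0, 100, n),
            "y_px": y if y is not None else np.full(n, float(obj) * 50),
            "area_px": 300 + (np.arange(n) % 7),
            "flag_reason": ["none"] * n,
        }
    )
    df.loc[: flagged - 1, "flag_reason"] = "size_jump"
    df["area_mm2"] = df["area_px"] * 0.01
    df["speed_mm_s"] = 1.0
    return df


class TestDuplicates:
    def test_long_overlap_removes_noisier_track(self):
        a = _toy_track(0, 400, flagged=5)
        b = _toy_track(1, 400, flagged=30)
        b.loc[100:249, ["x_px", "y_px"]] = a.loc[100:249, ["x_px", "y_px"]].values
        removed, masks = detect_duplicates({0: a, 1: b})
        assert removed == [1]
        # kept track flagged over the coincident region, dilated
        assert masks[0][100:250].all()
        assert masks[0][80] and masks[0][269]
        assert not masks[0][50]

    def test_short_overlap_keeps_both(self):
        a = _toy_track(0, 400)
        b = _toy_track(1, 400)
        b.loc[100:189, ["x_px", "y_px"]] = a.loc[100:189, ["x_px", "y_px"]].values
        removed, _ = detect_duplicates({0: a, 1: b})
        assert removed == []

    def test_outlier_tie_assigns_to_first_object(self):
        a = _toy_track(0, 400, flagged=10)
        b = _toy_track(1, 400, flagged=10)
        b.loc[0:149, ["x_px", "y_px"]] = a.loc[0:149, ["x_px", "y_px"]].values
        removed, _ = detect_duplicates({0: a, 1: b})
        assert removed == [1]


class TestPipeline:
    @pytest.fixture(scope="class")
    def clean_tracks(self):
        spec = SceneSpec(n_objects=3, duration_s=90.0, seed=13,
                         min_separation_mm=8.0)
        scene = simulate_scene(spec)
        cal = Calibration(spec.scale, spec.fps)
        return annotate_tracks(scene_tracks(scene, cal), cal), cal

    def test_clean_tracks_unflagged(self, clean_tracks):
        tracks, _ = clean_tracks
        cleaned, report = run_qc_pipeline(tracks)
        for obj, df in cleaned.items():
            assert (df["flag_reason"] == "none").all()
            assert not report.omit_recommended[obj]

    def test_partition_and_report_consistency(self, clean_tracks):
        tracks, cal = clean_tracks
        plan = [FailureInjection("detachment", 0, 300, 360)]
        corrupted, _ = inject_failures(tracks, plan, cal)
        corrupted = annotate_tracks(corrupted, cal)
        cleaned, report = run_qc_pipeline(corrupted)
        for obj, df in cleaned.items():
            good = df["flag_reason"] == "none"
            assert good.sum() + (~good).sum() == len(df)
            assert report.flagged_frames(obj) == int((~good).sum())

    def test_injected_frozen_run_excised(self, clean_tracks):
        tracks, cal = clean_tracks
        plan = [FailureInjection("detachment", 1, 400, 449)]
        corrupted, truth = inject_failures(tracks, plan, cal)
        cleaned, _ = run_qc_pipeline(annotate_tracks(corrupted, cal))
        flagged = (cleaned[1]["flag_reason"] != "none").to_numpy()
        assert flagged[400:450].all()  # the injected run is caught
        # nothing far from the event (beyond infill radius) is excised
        assert not flagged[:370].any() and not flagged[480:].any()

    def test_heavy_corruption_triggers_omit_recommendation(self, clean_tracks):
        tracks, cal = clean_tracks
        n = len(tracks[2])
        bad = tracks[2].copy()
        # freeze 40% of the track
        s = int(0.3 * n)
        e = s + int(0.4 * n)
        for col in ("x_px", "y_px", "area_px", "area_mm2"):
            bad.loc[s : e - 1, col] = bad.at[s, col]
        cleaned, report = run_qc_pipeline(
            annotate_tracks({2: bad}, cal)
        )
        assert report.omit_recommended[2]

    def test_rerun_on_good_output_flags_little(self, clean_tracks):
        tracks, cal = clean_tracks
        cleaned, _ = run_qc_pipeline(tracks)
        good = {
            obj: df[df["flag_reason"] == "none"].reset_index(drop=True)
            for obj, df in cleaned.items()
        }
        recleaned, _ = run_qc_pipeline(good)
        for obj, df in recleaned.items():
            assert (df["flag_reason"] != "none").mean() < 0.01
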