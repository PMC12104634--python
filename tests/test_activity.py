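import numpy as np
import pytest

from orpose.activity import (
    ActivityParams,
    classify_frame,
    classify_track,
    displacement,
    head_point,
    zone_test,
)
from orpose.simulate import SceneConfig, simulate_scene, tracks_from_truth
from orpose.tracking import Track

from conftest import full_pose, make_pose, random_track
from oracle import brute_force_classify


class TestHeadPoint:
    def test_single_point_centroid(self):
        pose = make_pose(0, {"nose": (50, 40)})
        np.testing.assert_allclose(head_point(pose, 0.3), (50, 40))

    def test_two_point_centroid(self):
        pose = make_pose(0, {"nose": (50, 40), "left_eye": (54, 36)})
        np.testing.assert_allclose(head_point(pose, 0.3), (52, 38))

    def test_all_below_confidence_gives_none(self):
        pose = make_pose(0, {"nose": (1, 1), "left_ear": (2, 2)}, confidence=0.1)
        assert head_point(pose, min_confidence=0.3) is None

    def test_non_head_keypoints_ignored(self):
        pose = make_pose(0, {"nose": (50, 40), "left_wrist": (0, 0)})
        np.testing.assert_allclose(head_point(pose, 0.3), (50, 40))


def _table_pose(frame=0, anchor=(500.0, 271.0), confidence=0.9):
    return full_pose(frame, anchor, confidence)


class TestZoneTest:
    def test_all_inside_passes(self, zones):
        assert zone_test(_table_pose(), zones) == "pass"

    def test_wrist_just_outside_fails(self, zones):
        pose = _table_pose()
        from orpose.io import KEYPOINT_INDEX

        # left wrist 1 px above the wrist-zone top edge (y = 300)
        pose.keypoints[KEYPOINT_INDEX["left_wrist"], 1] = 299.0
        assert zone_test(pose, zones) == "fail"

    def test_boundary_counts_as_inside(self, zones):
        pose = _table_pose()
        from orpose.io import KEYPOINT_INDEX

        pose.keypoints[KEYPOINT_INDEX["left_wrist"], 1] = 300.0
        assert zone_test(pose, zones) == "pass"

    def test_passerby_wrists_without_shoulders_fails(self, zones):
        # wrists reach over the table but the shoulders stay outside their
        # area: must not count as table work
        pose = make_pose(
            0,
            {
                "left_wrist": (490, 350),
                "right_wrist": (510, 350),
                "left_shoulder": (490, 250),
                "right_shoulder": (510, 250),
                "nose": (500, 230),
            },
        )
        assert zone_test(pose, zones) == "fail"

    def test_missing_wrist_is_undetermined(self, zones):
        pose = _table_pose()
        from orpose.io import KEYPOINT_INDEX

        pose.keypoints[KEYPOINT_INDEX["right_wrist"]] = np.nan
        assert zone_test(pose, zones) == "undetermined"


class TestDisplacement:
    def _track(self, offsets):
        tr = Track(track_id=0)
        tr.poses[0] = _table_pose(0)
        kp = _table_pose(5).keypoints.copy()
        for name, (dx, dy) in offsets.items():
            from orpose.io import KEYPOINT_INDEX

            kp[KEYPOINT_INDEX[name], 0] += dx
            kp[KEYPOINT_INDEX[name], 1] += dy
        from orpose.io import PoseFrame

        tr.poses[5] = PoseFrame(frame_index=5, keypoints=kp)
        return tr

    def test_stationary_zero(self):
        assert displacement(self._track({}), 5) == 0.0

    def test_three_four_five_translation(self):
        names = ["left_shoulder", "right_shoulder", "nose", "left_eye",
                 "right_eye", "left_ear", "right_ear"]
        tr = self._track({n: (3, 4) for n in names})
        assert displacement(tr, 5) == pytest.approx(5.0)

    def test_mean_aggregation_over_shoulders_and_head(self):
        # shoulders move 10 px, head moves 25 px -> mean (10+10+25)/3 = 15
        head = ["nose", "left_eye", "right_eye", "left_ear", "right_ear"]
        offsets = {n: (25, 0) for n in head}
        offsets["left_shoulder"] = (10, 0)
        offsets["right_shoulder"] = (10, 0)
        tr = self._track(offsets)
        assert displacement(tr, 5) == pytest.approx(15.0)

    def test_warmup_gives_none(self):
        assert displacement(self._track({}), 3) is None

    def test_wrist_motion_never_enters(self):
        tr = self._track({"left_wrist": (100, 100), "right_wrist": (100, 100)})
        assert displacement(tr, 5) == 0.0

    def test_leg_motion_never_enters(self):
        tr = self._track({n: (100, 100) for n in
                          ("left_knee", "right_knee", "left_ankle", "right_ankle",
                           "left_hip", "right_hip")})
        assert displacement(tr, 5) == 0.0


class TestClassifyFrame:
    def _still_track(self, n=10):
        tr = Track(track_id=0)
        for t in range(n):
            tr.poses[t] = _table_pose(t)
        return tr

    def test_in_zone_stationary_active(self, zones):
        assert classify_frame(self._still_track(), 6, zones) == "active"

    @pytest.mark.parametrize(
        "shift,expected",
        [
            (17.5, "active"),  # threshold must be strictly exceeded
            (17.6, "inactive"),
        ],
    )
    def test_threshold_boundary(self, zones, shift, expected):
        tr = self._still_track(6)
        # translate the whole frame-6 pose so shoulders and head move by
        # exactly `shift` px relative to frame 1; keep it in-zone
        tr.poses[6] = _table_pose(6, anchor=(500.0, 271.0 + shift))
        # widen zones so the shifted pose stays inside
        from orpose.simulate import default_zones

        assert classify_frame(tr, 6, default_zones(), ActivityParams()) == expected

    def test_warmup_undetermined(self, zones):
        assert classify_frame(self._still_track(), 2, zones) == "undetermined"

    def test_zone_fail_beats_missing_displacement(self, zones):
        tr = Track(track_id=0)
        tr.poses[2] = _table_pose(2, anchor=(100.0, 100.0))  # far outside
        assert classify_frame(tr, 2, zones) == "inactive"


class TestClassifyTrack:
    def test_never_in_zone_has_no_active_interval(self, zones):
        tr = Track(track_id=0)
        for t in range(20):
            tr.poses[t] = _table_pose(t, anchor=(100.0, 100.0))
        series = classify_track(tr, zones)
        assert series.intervals == []
        assert not (series.status == "active").any()

    def test_scheduled_bout_recovered_exactly(self, zones):
        cfg = SceneConfig(
            n_staff=1,
            fps=10,
            phase_durations=(10, 20, 10),
            activity_schedule=[[(2, 0.0, 1.0)]],
            seed=1,
        )
        detections, truth = simulate_scene(cfg)
        track = tracks_from_truth(detections, 1)[0]
        series = classify_track(track, zones, ActivityParams(min_confidence=0.3))
        # phase 2 spans frames [100, 300)
        assert series.intervals == [(100, 300)]

    def test_intervals_cover_exactly_the_active_frames(self, zones):
        rng = np.random.default_rng(5)
        tr = random_track(rng, 0, 150)
        series = classify_track(tr, zones)
        covered = set()
        for start, end in series.intervals:
            covered.update(range(start, end))
        active = {int(f) for f, s in zip(series.frames, series.status) if s == "active"}
        assert covered == active

    def test_empty_track_rejected(self, zones):
        with pytest.raises(ValueError):
            classify_track(Track(track_id=0), zones)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_scene_matches_brute_force(self, zones, seed):
        rng = np.random.default_rng(seed)
        n_persons = int(rng.integers(1, 6))
        n_frames = int(rng.integers(20, 120))
        params = ActivityParams()
        for p in range(n_persons):
            tr = random_track(rng, p, n_frames)
            series = classify_track(tr, zones, params)
            expected = brute_force_classify(tr, zones)
            got = {int(f): str(s) for f, s in zip(series.frames, series.status)}
            assert got == expected

    def test_simulated_scene_matches_brute_force(self, zones):
        cfg = SceneConfig(
            n_staff=3,
            fps=10,
            phase_durations=(8, 15, 8),
            activity_schedule=[[(2, 0.1, 0.8)], [], [(1, 0.3, 1.0)]],
            jitter_sd=2.0,
            dropout_rate=0.1,
            seed=11,
        )
        detections, _ = simulate_scene(cfg)
        for tr in tracks_from_truth(detections, 3):
            series = classify_track(tr, zones)
            expected = brute_force_classify(tr, zones)
            got = {int(f): str(s) for f, s in zip(series.frames, series.status)}
            assert got == expected


class TestMonotonicity:
    def test_raising_threshold_never_decreases_active(self, zones):
        rng = np.random.default_rng(7)
        tr = random_track(rng, 0, 200)
        counts = []
        for thr in (5.0, 17.5, 40.0):
            series = classify_track(tr, zones, ActivityParams(displacement_threshold=thr))
            counts.append(int((series.status == "active").sum()))
        assert counts == sorted(counts)

    def test_dropout_never_increases_active(self, zones):
        base_cfg = dict(
            n_staff=2,
            fps=10,
            phase_durations=(10, 20, 10),
            activity_schedule=[[(2, 0.0, 1.0)], [(2, 0.2, 0.7)]],
            jitter_sd=0.0,
            seed=3,
        )
        counts = []
        for rate in (0.0, 0.1, 0.3):
            detections, _ = simulate_scene(SceneConfig(dropout_rate=rate, **base_cfg))
            total = 0
            for tr in tracks_from_truth(detections, 2):
                series = classify_track(tr, zones)
                total += int((series.status == "active").sum())
            counts.append(total)
        assert counts[0] >= counts[1] >= counts[2]

    def test_zone_shrinkage_never_increases_active(self, zones):
        from orpose.io import ZoneSet

        rng = np.random.default_rng(13)
        tracks = [random_track(rng, p, 150) for p in range(3)]

        def active_count(zs):
            return sum(
                int((classify_track(tr, zs).status == "active").sum()) for tr in tracks
            )

        shrunk = ZoneSet(
            wrist_zone=zones.wrist_zone.buffer(-10),
            shoulder_zone=zones.shoulder_zone.buffer(-10),
            head_zone=zones.head_zone.buffer(-10),
        )
        assert active_count(shrunk) <= active_count(zones)
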