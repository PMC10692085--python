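"""Tests of detection I/O and trajectory preprocessing."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import strangertest as st
from strangertest.trajio import (
    Calibration,
    DetectionValidationError,
    TrialDetections,
    build_dataset,
    detection_coverage,
    fill_gaps,
    quality_filter,
    read_detections,
    resample,
)


def make_trial(n=100, fps=24.0, dog_mask=None, person_mask=None, trial_id="t0"):
    t = np.arange(n, dtype=float)
    dog = np.column_stack([0.01 * t + 1.0, 4.0 - 0.02 * t])
    person = np.tile([2.35, 2.35], (n, 1))
    return TrialDetections(
        trial_id=trial_id, fps=fps, dog_xy=dog,
        dog_detected=np.ones(n, bool) if dog_mask is None else dog_mask,
        person_xy=person,
        person_detected=np.ones(n, bool) if person_mask is None else person_mask,
    )


class TestDetectionIO:
    def test_round_trip(self, tmp_path):
        mask = np.ones(50, bool)
        mask[[3, 17, 40]] = False
        trial = make_trial(50, dog_mask=mask)
        path = tmp_path / "t0.json"
        trial.to_json(path)
        back = read_detections(path)
        assert back.trial_id == trial.trial_id
        assert back.fps == trial.fps
        np.testing.assert_array_equal(back.dog_detected, trial.dog_detected)
        np.testing.assert_allclose(back.dog_xy[mask], trial.dog_xy[mask], atol=1e-5)
        np.testing.assert_allclose(back.person_xy, trial.person_xy, atol=1e-5)

    def test_round_trip_with_pixel_calibration(self, tmp_path):
        trial = make_trial(20)
        trial.calibration = Calibration(px_per_m=96.0, origin=(12.0, 8.0))
        path = tmp_path / "t0.json"
        trial.to_json(path)
        back = read_detections(path)
        np.testing.assert_allclose(back.dog_xy, trial.dog_xy, atol=1e-5)

    def test_missing_frame_becomes_undetected(self, tmp_path):
        trial = make_trial(10)
        path = tmp_path / "t.json"
        trial.to_json(path)
        doc = json.loads(path.read_text())
        doc["frames"] = [f for f in doc["frames"] if f["i"] != 4]
        path.write_text(json.dumps(doc))
        back = read_detections(path)
        assert back.n_frames == 10
        assert not back.dog_detected[4] and not back.person_detected[4]

    def test_frame_lacking_dog_entry(self, tmp_path):
        trial = make_trial(5)
        path = tmp_path / "t.json"
        trial.to_json(path)
        doc = json.loads(path.read_text())
        doc["frames"][2]["dog"] = None
        path.write_text(json.dumps(doc))
        back = read_detections(path)
        assert not back.dog_detected[2] and back.person_detected[2]

    def test_inverted_bbox_rejected_naming_frame(self, tmp_path):
        trial = make_trial(5)
        path = tmp_path / "t.json"
        trial.to_json(path)
        doc = json.loads(path.read_text())
        doc["frames"][3]["dog"]["bbox"] = [5, 5, 3, 9]
        path.write_text(json.dumps(doc))
        with pytest.raises(DetectionValidationError, match="frame 3.*x_min"):
            read_detections(path)


class TestCoverageAndFilter:
    def test_full_coverage(self):
        assert detection_coverage(make_trial(50)) == 1.0

    def test_partial_joint_coverage(self):
        dog_mask = np.ones(50, bool)
        dog_mask[:10] = False
        assert detection_coverage(make_trial(50, dog_mask=dog_mask)) == 0.8

    def test_boundary_inclusive(self):
        trials = []
        for i, cov in enumerate([0.79, 0.80, 0.81]):
            mask = np.ones(100, bool)
            mask[: 100 - int(cov * 100)] = False
            trials.append(make_trial(100, dog_mask=mask, trial_id=f"t{i}"))
        retained, report = quality_filter(trials, threshold=0.8)
        assert [t.trial_id for t in retained] == ["t1", "t2"]
        assert report["retained"].tolist() == [False, True, True]

    def test_threshold_one_excludes_any_gap(self):
        mask = np.ones(100, bool)
        mask[50] = False
        retained, _ = quality_filter([make_trial(100, dog_mask=mask)], threshold=1.0)
        assert retained == []

    @given(t1=hst.floats(0.05, 1.0), t2=hst.floats(0.05, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, t1, t2):
        t1, t2 = min(t1, t2), max(t1, t2)
        trials = []
        for i, frac in enumerate([0.1, 0.5, 0.82, 0.95, 1.0]):
            mask = np.ones(100, bool)
            mask[: 100 - int(frac * 100)] = False
            trials.append(make_trial(100, dog_mask=mask, trial_id=f"t{i}"))
        loose = {t.trial_id for t in quality_filter(trials, t1)[0]}
        tight = {t.trial_id for t in quality_filter(trials, t2)[0]}
        assert tight <= loose


class TestFillGaps:
    def test_interior_gap_linear_midpoint(self):
        n = 20
        dog = np.zeros((n, 2))
        dog[10] = [0.0, 0.0]
        dog[12] = [2.0, 2.0]
        mask = np.zeros(n, bool)
        mask[[10, 12]] = True
        trial = TrialDetections(
            trial_id="t", fps=24, dog_xy=dog, dog_detected=mask,
            person_xy=np.tile([2.35, 2.35], (n, 1)),
            person_detected=np.ones(n, bool))
        filled = fill_gaps(trial, smooth_window=1)
        np.testing.assert_allclose(filled.dog_xy[11], [1.0, 1.0])

    def test_post_fill_coverage_is_one(self, small_cohort):
        for trial in small_cohort.trials:
            filled = fill_gaps(trial)
            assert detection_coverage(filled) == 1.0

    def test_constant_series_unchanged_by_smoothing(self):
        n = 30
        trial = TrialDetections(
            trial_id="t", fps=24, dog_xy=np.tile([1.5, 2.5], (n, 1)),
            dog_detected=np.ones(n, bool),
            person_xy=np.tile([2.35, 2.35], (n, 1)),
            person_detected=np.ones(n, bool))
        filled = fill_gaps(trial, smooth_window=7)
        np.testing.assert_allclose(filled.dog_xy, trial.dog_xy)

    def test_idempotent(self, small_cohort):
        trial = small_cohort.trials[0]
        once = fill_gaps(trial)
        twice = fill_gaps(once)
        np.testing.assert_array_equal(once.dog_xy, twice.dog_xy)
        np.testing.assert_array_equal(once.person_xy, twice.person_xy)

    def test_observed_points_kept_when_unsmoothed(self):
        mask = np.ones(40, bool)
        mask[5:15] = False
        trial = make_trial(40, dog_mask=mask)
        filled = fill_gaps(trial, smooth_window=1)
        np.testing.assert_allclose(filled.dog_xy[mask], trial.dog_xy[mask])

    def test_never_detected_object_rejected(self):
        trial = make_trial(10, dog_mask=np.zeros(10, bool))
        with pytest.raises(ValueError, match="dog never detected"):
            fill_gaps(trial)


class TestResample:
    def test_already_at_target_identical(self):
        trial = make_trial(48, fps=24.0)
        out = resample(trial, 24.0)
        assert out.n_frames == 48
        np.testing.assert_allclose(out.dog_xy, trial.dog_xy)

    def test_exact_on_linear_signal(self):
        n = 90
        t = np.arange(n) / 30.0
        trial = TrialDetections(
            trial_id="t", fps=30.0,
            dog_xy=np.column_stack([t, 2 * t]),
            dog_detected=np.ones(n, bool),
            person_xy=np.tile([2.35, 2.35], (n, 1)),
            person_detected=np.ones(n, bool))
        out = resample(trial, 24.0)
        t_new = np.arange(out.n_frames) / 24.0
        np.testing.assert_allclose(out.dog_xy[:, 0], t_new, atol=1e-12)

    def test_frame_count_60s_30fps_to_24fps(self):
        trial = make_trial(1800, fps=30.0)
        assert resample(trial, 24.0).n_frames == 1440

    def test_round_trip_linear_signal(self):
        n = 120
        t = np.arange(n) / 24.0
        trial = TrialDetections(
            trial_id="t", fps=24.0,
            dog_xy=np.column_stack([t, 1 + t]),
            dog_detected=np.ones(n, bool),
            person_xy=np.tile([2.35, 2.35], (n, 1)),
            person_detected=np.ones(n, bool))
        back = resample(resample(trial, 30.0), 24.0)
        # the final frame may be edge-held (the intermediate grid ends
        # just short of the original duration); all others are exact
        m = min(back.n_frames, n) - 1
        np.testing.assert_allclose(back.dog_xy[:m], trial.dog_xy[:m], atol=1e-9)

    def test_nonpositive_fps_rejected(self):
        with pytest.raises(ValueError, match="target_fps"):
            resample(make_trial(10), 0.0)


class TestBuildDataset:
    def test_truncation_to_shortest(self):
        trials = [make_trial(int(s * 24), trial_id=f"t{s}") for s in (58, 60, 62)]
        ds = build_dataset(trials)
        assert ds.m_time == 58 * 24 == 1392
        assert all(s.m_time == 1392 for s in ds.samples)

    def test_matrix_shape_and_flattening_order(self):
        trials = [make_trial(50, trial_id=f"t{i}") for i in range(3)]
        ds = build_dataset(trials)
        assert ds.matrix.shape == (3, 200)
        # first frame: dog_x, dog_y, person_x, person_y
        np.testing.assert_allclose(ds.matrix[0, :4], [1.0, 4.0, 2.35, 2.35])
        X = ds.as_channels()
        assert X.shape == (3, 4, 50)
        np.testing.assert_allclose(X[0, :, 0], ds.matrix[0, :4])

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_dataset([make_trial(50)])

    def test_sub_second_trial_rejected(self):
        with pytest.raises(ValueError, match="shorter than 1 s"):
            build_dataset([make_trial(10), make_trial(50)])

    def test_gappy_trial_rejected(self):
        mask = np.ones(50, bool)
        mask[4] = False
        with pytest.raises(ValueError, match="gaps remain"):
            build_dataset([make_trial(50, dog_mask=mask), make_trial(50)])
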