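"""Detection I/O and trajectory preprocessing.

Turns per-frame tracker output (dog and test-person bounding boxes, some
frames missed) into the fixed-rate, fixed-length, gap-free coordinate
dataset the downstream embedding and clustering stages require:

1. quality gating -- keep only trials where both objects are detected in
   at least 80% of frames;
2. gap filling -- linear interpolation of interior gaps, edge values held
   at the boundaries, followed by centered moving-average smoothing;
3. FPS standardization -- linear resampling to 24 frames per second;
4. duration standardization -- truncation of every trial to the shortest
   trial's frame count.

Each preprocessed trial is a sample ``s = (d, p)`` concatenating the dog
and person series; the cohort is a matrix ``D`` of shape
``n x (4 * m_time)`` flattened time-major with channel order
(dog_x, dog_y, person_x, person_y).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CHANNELS = ("dog_x", "dog_y", "person_x", "person_y")


class DetectionValidationError(ValueError):
    """Malformed detection record; message names the frame and field."""


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-meter mapping: meters = (pixels - origin) / px_per_m."""

    px_per_m: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def to_meters(self, xy_px: np.ndarray) -> np.ndarray:
        return (np.asarray(xy_px, dtype=float) - np.asarray(self.origin)) / self.px_per_m

    def to_pixels(self, xy_m: np.ndarray) -> np.ndarray:
        return np.asarray(xy_m, dtype=float) * self.px_per_m + np.asarray(self.origin)


@dataclass
class TrialDetections:
    """Per-frame dog/person detections for one trial.

    Coordinates are object centers in meters (already calibrated).
    ``*_detected`` flags mark frames where the tracker produced a box;
    after :func:`fill_gaps` the ``*_imputed`` masks record which frames
    were filled rather than observed.
    """

    trial_id: str
    fps: float
    dog_xy: np.ndarray
    dog_detected: np.ndarray
    person_xy: np.ndarray
    person_detected: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)
    dog_box: float = 0.4
    person_box: float = 0.6
    dog_imputed: np.ndarray | None = None
    person_imputed: np.ndarray | None = None
    postprocessed: bool = False

    def __post_init__(self) -> None:
        self.dog_xy = np.asarray(self.dog_xy, dtype=float)
        self.person_xy = np.asarray(self.person_xy, dtype=float)
        self.dog_detected = np.asarray(self.dog_detected, dtype=bool)
        self.person_detected = np.asarray(self.person_detected, dtype=bool)
        n = len(self.dog_xy)
        if not (len(self.person_xy) == len(self.dog_detected) == len(self.person_detected) == n):
            raise ValueError("per-object arrays must share one frame count")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.dog_xy)

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    def to_json(self, path) -> None:
        """Write the per-trial detection JSON (bboxes in pixels)."""
        frames = []
        for i in range(self.n_frames):
            rec: dict = {"i": i}
            for obj, xy, det, box in (
                ("dog", self.dog_xy, self.dog_detected, self.dog_box),
                ("person", self.person_xy, self.person_detected, self.person_box),
            ):
                if det[i]:
                    c = self.calibration.to_pixels(xy[i])
                    h = box * self.calibration.px_per_m / 2.0
                    rec[obj] = {
                        "bbox": [round(float(v), 6) for v in
                                 (c[0] - h, c[1] - h, c[0] + h, c[1] + h)],
                        "conf": 1.0,
                    }
                else:
                    rec[obj] = None
            frames.append(rec)
        doc = {
            "trial_id": self.trial_id,
            "fps": self.fps,
            "calibration": {"px_per_m": self.calibration.px_per_m,
                            "origin": list(self.calibration.origin)},
            "frames": frames,
        }
        Path(path).write_text(json.dumps(doc))


def read_detections(path) -> TrialDetections:
    """Parse a per-trial detection JSON into calibrated meter coordinates.

    Frames absent from the file (within [0, last frame index]) become
    undetected records; malformed boxes raise
    :class:`DetectionValidationError` naming frame and field.
    """
    doc = json.loads(Path(path).read_text())
    calib = Calibration(
        px_per_m=float(doc["calibration"]["px_per_m"]),
        origin=tuple(doc["calibration"]["origin"]),
    )
    frames = doc["frames"]
    if not frames:
        raise DetectionValidationError(f"{path}: no frames")
    by_index: dict[int, dict] = {}
    for rec in frames:
        i = int(rec["i"])
        if i < 0:
            raise DetectionValidationError(f"frame {i}: negative frame index")
        if i in by_index:
            raise DetectionValidationError(f"frame {i}: duplicate frame index")
        by_index[i] = rec
    n = max(by_index) + 1

    out = {}
    for obj in ("dog", "person"):
        xy = np.zeros((n, 2))
        det = np.zeros(n, dtype=bool)
        for i in range(n):
            entry = by_index.get(i, {}).get(obj)
            if entry is None:
                continue
            x0, y0, x1, y1 = (float(v) for v in entry["bbox"])
            if x0 > x1:
                raise DetectionValidationError(
                    f"frame {i}, {obj}.bbox: x_min {x0} > x_max {x1}")
            if y0 > y1:
                raise DetectionValidationError(
                    f"frame {i}, {obj}.bbox: y_min {y0} > y_max {y1}")
            center_px = np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])
            xy[i] = calib.to_meters(center_px)
            det[i] = True
        out[obj] = (xy, det)

    return TrialDetections(
        trial_id=str(doc["trial_id"]),
        fps=float(doc["fps"]),
        dog_xy=out["dog"][0],
        dog_detected=out["dog"][1],
        person_xy=out["person"][0],
        person_detected=out["person"][1],
        calibration=calib,
    )


def detection_coverage(trial: TrialDetections) -> float:
    """Fraction of frames where BOTH the dog and the person are detected."""
    if trial.n_frames == 0:
        raise ValueError("trial has no frames")
    return float((trial.dog_detected & trial.person_detected).mean())


def quality_filter(
    trials: list[TrialDetections], threshold: float = 0.80
) -> tuple[list[TrialDetections], pd.DataFrame]:
    """Keep trials with joint coverage >= threshold ("at least 80%").

    Returns the retained trials and an exclusion report listing every
    trial's coverage and whether it was retained.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    rows, retained = [], []
    for t in trials:
        cov = detection_coverage(t)
        keep = cov >= threshold
        rows.append({"trial_id": t.trial_id, "coverage": cov, "retained": keep})
        if keep:
            retained.append(t)
    return retained, pd.DataFrame(rows)


def _fill_series(xy: np.ndarray, detected: np.ndarray) -> np.ndarray:
    """Linear interpolation over gaps; edge gaps hold the nearest value."""
    idx = np.flatnonzero(detected)
    t = np.arange(len(xy))
    out = np.empty_like(xy)
    for c in range(xy.shape[1]):
        out[:, c] = np.interp(t, idx, xy[idx, c])
    return out


def _smooth(xy: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average of odd-or-even width; edges shrunk."""
    if window <= 1:
        return xy.copy()
    return (
        pd.DataFrame(xy).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def fill_gaps(trial: TrialDetections, smooth_window: int = 5) -> TrialDetections:
    """Fill missed frames and smooth, reaching 100% coverage.

    Interior gaps are linearly interpolated between flanking detections;
    leading/trailing gaps hold the nearest detected value; a centered
    moving average of width ``smooth_window`` is then applied.  Idempotent:
    an already post-processed trial is returned unchanged.
    """
    if trial.postprocessed:
        return trial
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    for name, det in (("dog", trial.dog_detected), ("person", trial.person_detected)):
        if not det.any():
            raise ValueError(f"trial {trial.trial_id}: {name} never detected")
    dog = _smooth(_fill_series(trial.dog_xy, trial.dog_detected), smooth_window)
    person = _smooth(_fill_series(trial.person_xy, trial.person_detected), smooth_window)
    n = trial.n_frames
    return replace(
        trial,
        dog_xy=dog,
        person_xy=person,
        dog_detected=np.ones(n, dtype=bool),
        person_detected=np.ones(n, dtype=bool),
        dog_imputed=~trial.dog_detected,
        person_imputed=~trial.person_detected,
        postprocessed=True,
    )


def resample(trial: TrialDetections, target_fps: float = 24.0) -> TrialDetections:
    """Linearly resample a gap-free trial to ``target_fps``.

    The trial duration is preserved to within one frame period; a trial
    already at the target rate is returned with identical coordinates.
    """
    if target_fps <= 0:
        raise ValueError("target_fps must be positive")
    if not (trial.dog_detected.all() and trial.person_detected.all()):
        raise ValueError(f"trial {trial.trial_id}: resample requires a gap-free trial")
    n = trial.n_frames
    n_new = max(int(round(trial.duration * target_fps)), 2)
    t_old = np.arange(n) / trial.fps
    t_new = np.arange(n_new) / target_fps
    dog = np.column_stack(
        [np.interp(t_new, t_old, trial.dog_xy[:, c]) for c in range(2)])
    person = np.column_stack(
        [np.interp(t_new, t_old, trial.person_xy[:, c]) for c in range(2)])

    def _mask(mask: np.ndarray | None) -> np.ndarray | None:
        if mask is None:
            return None
        # a resampled frame counts as imputed if its nearest source frame was
        src = np.clip(np.round(t_new * trial.fps).astype(int), 0, n - 1)
        return mask[src]

    return replace(
        trial,
        fps=target_fps,
        dog_xy=dog,
        person_xy=person,
        dog_detected=np.ones(n_new, dtype=bool),
        person_detected=np.ones(n_new, dtype=bool),
        dog_imputed=_mask(trial.dog_imputed),
        person_imputed=_mask(trial.person_imputed),
    )


@dataclass
class TrajectorySample:
    """One preprocessed trial: dog series d and person series p (meters),
    m_time frames each at the dataset fps; together the sample
    s = (d, p)."""

    trial_id: str
    dog: np.ndarray
    person: np.ndarray
    fps: float
    imputed_mask: np.ndarray | None = None  # (m_time, 2): dog, person

    @property
    def m_time(self) -> int:
        return len(self.dog)

    def flatten(self) -> np.ndarray:
        """Time-major row, channel order dog_x, dog_y, person_x, person_y."""
        return np.column_stack([self.dog, self.person]).ravel()


@dataclass
class TrajectoryDataset:
    """Aligned cohort of trajectory samples with a matrix view."""

    samples: list[TrajectorySample]

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def m_time(self) -> int:
        return self.samples[0].m_time

    @property
    def fps(self) -> float:
        return self.samples[0].fps

    @property
    def trial_ids(self) -> list[str]:
        return [s.trial_id for s in self.samples]

    @property
    def matrix(self) -> np.ndarray:
        """D: n x (4 * m_time), time-major flattening."""
        return np.stack([s.flatten() for s in self.samples])

    def as_channels(self) -> np.ndarray:
        """(n, 4, m_time) channel-major view for the convolutional encoder."""
        return np.stack(
            [np.column_stack([s.dog, s.person]).T for s in self.samples])


def build_dataset(trials: list[TrialDetections]) -> TrajectoryDataset:
    """Truncate gap-free same-fps trials to the shortest duration and stack.

    Truncation keeps the start of each trial (the test phase begins at
    arena entry).  Requires at least two trials, each at least 1 s long.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials to build a dataset")
    fps = trials[0].fps
    for t in trials:
        if t.fps != fps:
            raise ValueError(f"trial {t.trial_id}: fps {t.fps} != dataset fps {fps}")
        if not (t.dog_detected.all() and t.person_detected.all()):
            raise ValueError(f"trial {t.trial_id}: gaps remain; run fill_gaps first")
        if t.n_frames < fps:
            raise ValueError(f"trial {t.trial_id}: shorter than 1 s")
    m = min(t.n_frames for t in trials)
    samples = []
    for t in trials:
        mask = None
        if t.dog_imputed is not None and t.person_imputed is not None:
            mask = np.column_stack([t.dog_imputed[:m], t.person_imputed[:m]])
        samples.append(TrajectorySample(
            trial_id=t.trial_id, dog=t.dog_xy[:m].copy(),
            person=t.person_xy[:m].copy(), fps=fps, imputed_mask=mask))
    return TrajectoryDataset(samples=samples)


def preprocess(
    trials: list[TrialDetections],
    min_coverage: float = 0.80,
    target_fps: float = 24.0,
    smooth_window: int = 5,
) -> tuple[TrajectoryDataset, pd.DataFrame]:
    """Quality gate, fill, smooth, resample and truncate in one call."""
    retained, report = quality_filter(trials, min_coverage)
    if len(retained) < 2:
        raise ValueError("fewer than 2 trials pass the quality gate")
    processed = [resample(fill_gaps(t, smooth_window), target_fps) for t in retained]
    return build_dataset(processed), report
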