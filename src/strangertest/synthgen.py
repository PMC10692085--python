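"""Synthetic arena-cohort generation.

Emulates the Stranger Test recording setup: a dog moving freely in a
4.7 x 4.7 m fenced arena for ~40 s at 24 fps, with a static test person
(the stranger, TP) seated at the arena center and a familiar person in a
corner.  The dog's center-of-mass path follows a discrete-time
Ornstein-Uhlenbeck-like walk whose attractor geometry depends on the
dog's coping style:

* ``towards`` -- pulled close to the TP (small preferred distance),
* ``neutral`` -- weakly held at a mid-range distance, high exploration,
* ``away``    -- held far from the TP, near the walls.

On top of the clean paths the generator produces the imperfect-detection
regime of a real tracker (missed frames, center jitter), three-expert
ordinal ratings with a controlled unanimity structure, and eight C-BARQ
category scores statistically coupled to coping style and to trajectory
activity covariates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajio import Calibration, TrialDetections

STYLES = ("towards", "neutral", "away")
#: collapsed expert-score symbol for each coping style
STYLE_SYMBOL = {"towards": "+", "neutral": "0", "away": "-"}
SYMBOL_STYLE = {v: k for k, v in STYLE_SYMBOL.items()}

CBARQ_CATEGORIES = ("SDA", "ODA", "SDF", "NSF", "SRB", "ASB", "EXC", "PS")


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry and timing of the testing arena.

    Distances in meters; the test person (TP) sits at the arena center,
    the familiar person (FP) in a corner.  ``duration_jitter`` is the
    half-width of the uniform per-trial duration jitter in seconds.
    """

    side_length: float = 4.7
    tp_position: tuple[float, float] = (2.35, 2.35)
    fp_position: tuple[float, float] = (0.4, 0.4)
    fps: float = 24.0
    duration: float = 40.0
    duration_jitter: float = 2.0

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name in ("tp_position", "fp_position"):
            x, y = getattr(self, name)
            if not (0 <= x <= self.side_length and 0 <= y <= self.side_length):
                raise ValueError(f"{name} must lie inside the arena")


@dataclass(frozen=True)
class MotionParams:
    """Style-specific parameters of the OU-like walk.

    attraction:      pull strength toward the preferred-distance shell
                     around the TP (1/s)
    noise_scale:     exploration noise sigma (m / sqrt(s))
    wall_avoidance:  inward drift strength inside ``wall_buffer`` of a wall
    preferred_tp_distance:  radius of the attractor shell around TP (m)
    """

    attraction: float
    noise_scale: float
    wall_avoidance: float
    preferred_tp_distance: float
    fp_attraction: float = 0.0
    wall_buffer: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.preferred_tp_distance < 0:
            raise ValueError("preferred_tp_distance must be >= 0")


#: Style-dependent defaults.  Dogs reacting towards the stranger hover
#: close to the TP and largely ignore the familiar person; neutral dogs
#: explore at mid-range and regularly check in with the FP in the
#: corner; dogs reacting away keep their distance from the TP and stay
#: near the FP / periphery.  The FP pull breaks the radial symmetry
#: around the TP, as in the real arena where the owner sits in a corner.
DEFAULT_MOTION: dict[str, MotionParams] = {
    "towards": MotionParams(attraction=0.9, noise_scale=0.35,
                            wall_avoidance=1.0, preferred_tp_distance=0.5,
                            fp_attraction=0.02),
    "neutral": MotionParams(attraction=0.25, noise_scale=0.55,
                            wall_avoidance=1.0, preferred_tp_distance=2.0,
                            fp_attraction=0.15),
    "away": MotionParams(attraction=0.9, noise_scale=0.30,
                         wall_avoidance=0.5, preferred_tp_distance=3.1,
                         fp_attraction=0.35),
}

#: per-category C-BARQ coupling: score = clip(intercept
#:   + style_effect[style] + speed_coef*speed_norm + near_coef*near_frac
#:   + N(0, noise_sd), 0, 4)
#: SDF carries the style signal (printed medians 0.00 neutral / 0.42 towards);
#: EXC tracks trajectory activity; the rest are weakly coupled background.
@dataclass(frozen=True)
class CbarqCoupling:
    intercept: float
    style_effect: dict[str, float]
    speed_coef: float
    near_coef: float
    noise_sd: float


DEFAULT_CBARQ: dict[str, CbarqCoupling] = {
    "SDA": CbarqCoupling(0.4, {"towards": 0.1, "neutral": 0.0, "away": 0.3}, 0.0, 0.0, 0.3),
    "ODA": CbarqCoupling(0.2, {"towards": 0.0, "neutral": 0.0, "away": 0.0}, 0.0, 0.0, 0.2),
    "SDF": CbarqCoupling(0.0, {"towards": 0.42, "neutral": 0.0, "away": 1.2}, 0.0, 0.0, 0.15),
    "NSF": CbarqCoupling(0.8, {"towards": 0.0, "neutral": 0.0, "away": 0.4}, 0.0, 0.0, 0.35),
    "SRB": CbarqCoupling(0.6, {"towards": 0.1, "neutral": 0.0, "away": 0.0}, 0.0, 0.0, 0.3),
    "ASB": CbarqCoupling(1.5, {"towards": 0.2, "neutral": 0.0, "away": -0.2}, 0.0, 0.0, 0.35),
    "EXC": CbarqCoupling(0.3, {"towards": 0.0, "neutral": 0.0, "away": 0.0}, 1.0, 1.4, 0.10),
    "PS": CbarqCoupling(1.0, {"towards": 0.0, "neutral": 0.0, "away": 0.2}, 0.0, 0.0, 0.35),
}

#: dog-TP distance below which a frame counts as "near" for the
#: near_frac activity covariate
NEAR_TP_RADIUS = 1.5
#: mean-speed normalization scale (m/s); speed_norm = clip(speed/scale, 0, 1)
SPEED_SCALE = 0.8


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``style_proportions`` must sum to 1 over the three coping styles;
    per-style trial counts are assigned by largest remainder so the
    realized counts are deterministic (28 neutral / 18 towards at the
    default n=46).
    """

    n_trials: int = 46
    style_proportions: dict[str, float] = field(
        default_factory=lambda: {"towards": 18 / 46, "neutral": 28 / 46, "away": 0.0}
    )
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    motion: dict[str, MotionParams] = field(default_factory=lambda: dict(DEFAULT_MOTION))
    miss_rate: float = 0.05
    noise_sd: float = 0.05
    unanimity_fraction: float = 0.76
    cbarq: dict[str, CbarqCoupling] = field(default_factory=lambda: dict(DEFAULT_CBARQ))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        total = sum(self.style_proportions.get(s, 0.0) for s in STYLES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("style_proportions must sum to 1")
        for name in ("miss_rate", "unanimity_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_trajectory(
    style: str,
    arena: ArenaSpec,
    params: MotionParams | None = None,
    seed: int = 0,
    n_frames: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one trial: dog path and (static) person path in meters.

    The dog follows ``x_{t+1} = x_t + a*(target - x_t)*dt + wall_drift*dt
    + sigma*sqrt(dt)*eps`` with reflecting arena walls, where ``target``
    is the point at the style's preferred distance from the TP along the
    dog-TP line.  Returns ``(dog, person)``, each of shape (n_frames, 2).
    """
    if style not in STYLES:
        raise ValueError(f"unknown coping style {style!r}; expected one of {STYLES}")
    if params is None:
        params = DEFAULT_MOTION[style]
    rng = np.random.default_rng(seed)
    dt = 1.0 / arena.fps
    if n_frames is None:
        duration = arena.duration + rng.uniform(-arena.duration_jitter, arena.duration_jitter)
        n_frames = max(int(round(duration * arena.fps)), 2)
    tp = np.asarray(arena.tp_position, dtype=float)
    fp = np.asarray(arena.fp_position, dtype=float)
    side = arena.side_length

    # dogs enter through the gate on the front fence
    x = np.array([side / 2.0, 0.5]) + rng.normal(0.0, 0.15, size=2)
    x = np.clip(x, 0.05, side - 0.05)

    dog = np.empty((n_frames, 2))
    dog[0] = x
    noise = rng.normal(0.0, 1.0, size=(n_frames - 1, 2))
    sqdt = np.sqrt(dt)
    for t in range(1, n_frames):
        rel = x - tp
        dist = np.hypot(rel[0], rel[1])
        if dist < 1e-9:
            direction = np.array([1.0, 0.0])
            dist = 1e-9
        else:
            direction = rel / dist
        target = tp + params.preferred_tp_distance * direction
        drift = params.attraction * (target - x) + params.fp_attraction * (fp - x)
        # soft inward push near walls, before the hard reflection
        low = x < params.wall_buffer
        high = x > side - params.wall_buffer
        drift = drift + params.wall_avoidance * (
            low * (params.wall_buffer - x) + high * (side - params.wall_buffer - x)
        )
        x = x + drift * dt + params.noise_scale * sqdt * noise[t - 1]
        # reflecting boundary
        x = np.abs(x)
        over = x > side
        x[over] = 2 * side - x[over]
        x = np.clip(x, 0.0, side)
        dog[t] = x

    person = np.tile(tp, (n_frames, 1))
    return dog, person


def corrupt_detections(
    dog: np.ndarray,
    person: np.ndarray,
    miss_rate: float,
    noise_sd: float,
    seed: int = 0,
    trial_id: str = "trial",
    fps: float = 24.0,
    dog_box: float = 0.4,
    person_box: float = 0.6,
) -> TrialDetections:
    """Corrupt clean paths into tracker-style detections.

    Each frame is independently marked undetected (per object) with
    probability ``miss_rate``; detected centers get isotropic Gaussian
    noise of sd ``noise_sd`` (meters).  Bounding boxes are fixed-size
    squares around the (noisy) center.  Identity calibration: 1 px = 1 m.
    """
    if not 0 <= miss_rate <= 1:
        raise ValueError("miss_rate must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    dog = np.asarray(dog, dtype=float)
    person = np.asarray(person, dtype=float)
    if dog.shape != person.shape or dog.ndim != 2 or dog.shape[1] != 2:
        raise ValueError("dog and person paths must both have shape (n_frames, 2)")
    n = dog.shape[0]
    rng = np.random.default_rng(seed)
    dog_det = rng.random(n) >= miss_rate
    person_det = rng.random(n) >= miss_rate
    dog_xy = dog + rng.normal(0.0, noise_sd, size=(n, 2)) if noise_sd > 0 else dog.copy()
    person_xy = person + rng.normal(0.0, noise_sd, size=(n, 2)) if noise_sd > 0 else person.copy()
    return TrialDetections(
        trial_id=trial_id,
        fps=fps,
        dog_xy=dog_xy,
        dog_detected=dog_det,
        person_xy=person_xy,
        person_detected=person_det,
        calibration=Calibration(px_per_m=1.0, origin=(0.0, 0.0)),
        dog_box=dog_box,
        person_box=person_box,
    )


def _style_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n trials over the styles."""
    quotas = {s: n * proportions.get(s, 0.0) for s in STYLES}
    counts = {s: int(np.floor(q)) for s, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(STYLES, key=lambda s: quotas[s] - counts[s], reverse=True)
    for s in order[:short]:
        counts[s] += 1
    return counts


def generate_ratings(
    true_styles: list[str],
    unanimity_fraction: float = 0.76,
    seed: int = 0,
    unanimous_mask: np.ndarray | None = None,
    trial_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Three collapsed {-,0,+} expert ratings per trial.

    A trial is unanimous with probability ``unanimity_fraction``;
    otherwise two raters give the true class and one rater an adjacent
    class ('0' neighbours both extremes; the extremes neighbour '0'), so
    the majority label always equals the true style.  Pass
    ``unanimous_mask`` to fix the unanimity pattern exactly.
    """
    rng = np.random.default_rng(seed)
    n = len(true_styles)
    if trial_ids is None:
        trial_ids = [f"trial{i:03d}" for i in range(n)]
    if unanimous_mask is None:
        unanimous_mask = rng.random(n) < unanimity_fraction
    unanimous_mask = np.asarray(unanimous_mask, dtype=bool)
    rows = []
    for i, style in enumerate(true_styles):
        true = STYLE_SYMBOL[style]
        votes = [true, true, true]
        if not unanimous_mask[i]:
            adjacent = ["+", "-"] if true == "0" else ["0"]
            dissent = adjacent[rng.integers(len(adjacent))]
            votes[rng.integers(3)] = dissent
        rows.append({"trial_id": trial_ids[i], "rater1": votes[0],
                     "rater2": votes[1], "rater3": votes[2]})
    return pd.DataFrame(rows)


def activity_covariates(dog: np.ndarray, tp: np.ndarray, fps: float) -> dict[str, float]:
    """Trajectory activity covariates feeding the C-BARQ coupling.

    near_frac:  fraction of frames with dog-TP distance < NEAR_TP_RADIUS
    speed_norm: mean speed / SPEED_SCALE, clipped to [0, 1]
    mean_tp_distance: mean dog-TP distance (m), reported for reference
    """
    dist = np.hypot(dog[:, 0] - tp[0], dog[:, 1] - tp[1])
    step = np.hypot(*np.diff(dog, axis=0).T)
    mean_speed = float(step.mean() * fps) if len(step) else 0.0
    return {
        "near_frac": float((dist < NEAR_TP_RADIUS).mean()),
        "speed_norm": float(np.clip(mean_speed / SPEED_SCALE, 0.0, 1.0)),
        "mean_tp_distance": float(dist.mean()),
        "mean_speed": mean_speed,
    }


def generate_cbarq(
    true_styles: list[str],
    covariates: pd.DataFrame,
    coupling: dict[str, CbarqCoupling] | None = None,
    seed: int = 0,
    trial_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Eight C-BARQ category scores per trial, clipped to [0, 4].

    ``covariates`` must provide ``near_frac`` and ``speed_norm`` columns
    aligned with ``true_styles``.
    """
    if coupling is None:
        coupling = DEFAULT_CBARQ
    rng = np.random.default_rng(seed)
    n = len(true_styles)
    if trial_ids is None:
        trial_ids = [f"trial{i:03d}" for i in range(n)]
    out = {"trial_id": trial_ids}
    near = covariates["near_frac"].to_numpy(dtype=float)
    speed = covariates["speed_norm"].to_numpy(dtype=float)
    for cat in CBARQ_CATEGORIES:
        c = coupling[cat]
        base = (
            c.intercept
            + np.array([c.style_effect.get(s, 0.0) for s in true_styles])
            + c.speed_coef * speed
            + c.near_coef * near
        )
        if c.noise_sd > 0:
            base = base + rng.normal(0.0, c.noise_sd, size=n)
        out[cat] = np.clip(base, 0.0, 4.0)
    return pd.DataFrame(out)


@dataclass
class Cohort:
    """In-memory synthetic cohort: detections plus ground truth tables."""

    config: CohortConfig
    trials: list[TrialDetections]
    clean_dog: list[np.ndarray]
    clean_person: list[np.ndarray]
    truth: pd.DataFrame      # trial_id, style, covariates
    ratings: pd.DataFrame    # trial_id, rater1..3
    cbarq: pd.DataFrame      # trial_id, 8 categories


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    counts = _style_counts(config.n_trials, config.style_proportions)
    styles = [s for s in STYLES for _ in range(counts[s])]
    rng.shuffle(styles)
    trial_ids = [f"trial{i:03d}" for i in range(config.n_trials)]
    tp = np.asarray(config.arena.tp_position)

    trials, clean_dog, clean_person, truth_rows = [], [], [], []
    for i, style in enumerate(styles):
        traj_seed = int(rng.integers(2**31))
        corrupt_seed = int(rng.integers(2**31))
        dog, person = generate_trajectory(style, config.arena,
                                          config.motion[style], seed=traj_seed)
        det = corrupt_detections(dog, person, config.miss_rate, config.noise_sd,
                                 seed=corrupt_seed, trial_id=trial_ids[i],
                                 fps=config.arena.fps)
        cov = activity_covariates(dog, tp, config.arena.fps)
        trials.append(det)
        clean_dog.append(dog)
        clean_person.append(person)
        truth_rows.append({"trial_id": trial_ids[i], "style": style, **cov})

    truth = pd.DataFrame(truth_rows)
    ratings = generate_ratings(styles, config.unanimity_fraction,
                               seed=int(rng.integers(2**31)), trial_ids=trial_ids)
    cbarq = generate_cbarq(styles, truth, config.cbarq,
                           seed=int(rng.integers(2**31)), trial_ids=trial_ids)
    return Cohort(config=config, trials=trials, clean_dog=clean_dog,
                  clean_person=clean_person, truth=truth, ratings=ratings,
                  cbarq=cbarq)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort to disk: one detection JSON per trial, ratings.csv,
    cbarq.csv, truth.csv and a manifest carrying the seed."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for det in cohort.trials:
        det.to_json(out / f"{det.trial_id}.json")
    cohort.ratings.to_csv(out / "ratings.csv", index=False)
    cohort.cbarq.to_csv(out / "cbarq.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    cfg = dataclasses.asdict(cohort.config)
    cfg["arena"]["tp_position"] = list(cfg["arena"]["tp_position"])
    cfg["arena"]["fp_position"] = list(cfg["arena"]["fp_position"])
    (out / "manifest.json").write_text(
        json.dumps({"seed": cohort.config.seed, "n_trials": cohort.config.n_trials,
                    "config": cfg}, indent=2, default=float)
    )
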