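"""Tests of the synthetic arena-cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import strangertest as st
from strangertest.synthgen import (
    ArenaSpec,
    CohortConfig,
    MotionParams,
    activity_covariates,
    corrupt_detections,
    generate_cbarq,
    generate_cohort,
    generate_ratings,
    generate_trajectory,
)

ARENA = ArenaSpec()


class TestGenerateTrajectory:
    @pytest.mark.parametrize("style", ["towards", "neutral", "away"])
    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_dog_stays_inside_arena(self, style, seed):
        dog, _ = generate_trajectory(style, ARENA, seed=seed)
        assert dog.min() >= 0.0
        assert dog.max() <= ARENA.side_length

    def test_person_static_at_arena_center(self):
        _, person = generate_trajectory("neutral", ARENA, seed=5)
        assert np.all(person == np.array([2.35, 2.35]))

    def test_invalid_style_rejected(self):
        with pytest.raises(ValueError, match="coping style"):
            generate_trajectory("sideways", ARENA, seed=0)

    def test_reproducible_given_seed(self):
        a, _ = generate_trajectory("towards", ARENA, seed=11)
        b, _ = generate_trajectory("towards", ARENA, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_style_distance_ordering_monte_carlo(self):
        """Mean dog-TP distance orders towards < neutral < away in >= 95
        of 100 seeds."""
        tp = np.array(ARENA.tp_position)
        wins = 0
        for seed in range(100):
            means = {}
            for style in ("towards", "neutral", "away"):
                dog, _ = generate_trajectory(style, ARENA, seed=seed,
                                             n_frames=400)
                means[style] = np.hypot(*(dog - tp).T).mean()
            wins += means["towards"] < means["neutral"] < means["away"]
        assert wins >= 95

    def test_separation_monotone_in_attraction(self):
        """Stronger towards-attraction strictly shrinks mean TP distance
        (sign test over 100 seeds)."""
        weak = MotionParams(attraction=0.4, noise_scale=0.35,
                            wall_avoidance=1.0, preferred_tp_distance=0.5)
        strong = MotionParams(attraction=1.2, noise_scale=0.35,
                              wall_avoidance=1.0, preferred_tp_distance=0.5)
        tp = np.array(ARENA.tp_position)
        closer = 0
        for seed in range(100):
            d_weak, _ = generate_trajectory("towards", ARENA, weak, seed=seed,
                                            n_frames=400)
            d_strong, _ = generate_trajectory("towards", ARENA, strong, seed=seed,
                                              n_frames=400)
            closer += (np.hypot(*(d_strong - tp).T).mean()
                       < np.hypot(*(d_weak - tp).T).mean())
        # one-sided sign test: P(X >= closer | p=0.5) < 0.01
        assert binom.sf(closer - 1, 100, 0.5) < 0.01


class TestCorruptDetections:
    def _paths(self, n=200, seed=0):
        return generate_trajectory("neutral", ARENA, seed=seed, n_frames=n)

    def test_no_op_corruption(self):
        dog, person = self._paths()
        det = corrupt_detections(dog, person, miss_rate=0.0, noise_sd=0.0, seed=1)
        assert st.trajio.detection_coverage(det) == 1.0
        np.testing.assert_array_equal(det.dog_xy, dog)

    def test_full_miss(self):
        dog, person = self._paths()
        det = corrupt_detections(dog, person, miss_rate=1.0, noise_sd=0.0, seed=1)
        assert st.trajio.detection_coverage(det) == 0.0

    def test_miss_fraction_within_binomial_interval(self):
        dog, person = self._paths(n=1000)
        det = corrupt_detections(dog, person, miss_rate=0.2, noise_sd=0.0, seed=9)
        missed = int((~det.dog_detected).sum())
        lo, hi = binom.ppf([0.005, 0.995], 1000, 0.2)
        assert lo <= missed <= hi

    def test_negative_noise_rejected(self):
        dog, person = self._paths()
        with pytest.raises(ValueError, match="noise_sd"):
            corrupt_detections(dog, person, miss_rate=0.1, noise_sd=-0.1)


class TestGenerateRatings:
    def test_printed_breakdown_majority_counts(self):
        """26 unanimous-0 + 6 majority-0 and 12 unanimous-+ + 6 majority-+
        vote to 32 trials '0' and 18 trials '+'."""
        styles = ["neutral"] * 32 + ["towards"] * 18
        unanimous = np.array([True] * 26 + [False] * 6 + [True] * 12 + [False] * 6)
        ratings = generate_ratings(styles, seed=0, unanimous_mask=unanimous)
        labels = st.stats.majority_labels(ratings)["label"]
        assert (labels == "0").sum() == 32
        assert (labels == "+").sum() == 18

    def test_full_unanimity_gives_perfect_agreement(self):
        ratings = generate_ratings(["neutral"] * 20, unanimity_fraction=1.0, seed=4)
        po = st.stats.percent_agreement(
            ratings[["rater1", "rater2", "rater3"]].to_numpy())
        assert po == 1.0

    def test_pairwise_agreement_of_known_split(self):
        """38 unanimous + 12 two-one splits over 50 -> Po = (38 + 12/3)/50."""
        styles = ["neutral"] * 50
        unanimous = np.array([True] * 38 + [False] * 12)
        ratings = generate_ratings(styles, seed=2, unanimous_mask=unanimous)
        po = st.stats.percent_agreement(
            ratings[["rater1", "rater2", "rater3"]].to_numpy())
        assert po == pytest.approx((38 + 12 / 3) / 50)

    def test_majority_always_equals_true_style(self):
        styles = (["towards"] * 10 + ["neutral"] * 10 + ["away"] * 10)
        ratings = generate_ratings(styles, unanimity_fraction=0.3, seed=8)
        labels = st.stats.majority_labels(ratings)["label"]
        expected = [st.synthgen.STYLE_SYMBOL[s] for s in styles]
        assert list(labels) == expected


class TestGenerateCbarq:
    def _cov(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"near_frac": rng.random(n), "speed_norm": rng.random(n)})

    def test_scores_lie_in_range(self):
        styles = ["towards", "neutral", "away"] * 40
        df = generate_cbarq(styles, self._cov(120), seed=1)
        vals = df[list(st.synthgen.CBARQ_CATEGORIES)].to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 4.0

    def test_sdf_medians_match_style_effects(self):
        """Large n: median SDF ~ 0.00 for neutral and ~ 0.42 for towards."""
        n = 4000
        styles = ["neutral"] * n + ["towards"] * n
        df = generate_cbarq(styles, self._cov(2 * n), seed=3)
        med_neutral = df["SDF"][:n].median()
        med_towards = df["SDF"][n:].median()
        assert med_neutral == pytest.approx(0.00, abs=0.02)
        assert med_towards == pytest.approx(0.42, abs=0.02)

    def test_noiseless_exc_is_deterministic_in_covariates(self):
        """With noise_sd = 0 the EXC score is an exact linear function of
        the activity covariates; refitting recovers R^2 = 1."""
        from sklearn.linear_model import LinearRegression

        coupling = dict(st.synthgen.DEFAULT_CBARQ)
        c = coupling["EXC"]
        coupling["EXC"] = st.synthgen.CbarqCoupling(
            c.intercept, c.style_effect, c.speed_coef, c.near_coef, 0.0)
        cov = self._cov(60, seed=5)
        df = generate_cbarq(["neutral"] * 60, cov, coupling, seed=5)
        fit = LinearRegression().fit(cov[["near_frac", "speed_norm"]], df["EXC"])
        assert fit.score(cov[["near_frac", "speed_norm"]], df["EXC"]) == pytest.approx(1.0)


class TestCohort:
    def test_reproducible_given_config(self, tmp_path):
        cfg = CohortConfig(n_trials=6, seed=11,
                           arena=ArenaSpec(duration=8, duration_jitter=0.5))
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        st.synthgen.write_cohort(a, tmp_path / "a")
        st.synthgen.write_cohort(b, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_default_cohort_class_counts(self, study_cohort):
        counts = study_cohort.truth["style"].value_counts()
        assert counts["neutral"] == 28 and counts["towards"] == 18

    def test_three_ratings_and_majority_per_trial(self, small_cohort):
        maj = st.stats.majority_labels(small_cohort.ratings)
        assert len(maj) == small_cohort.config.n_trials
        assert maj["label"].notna().all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortConfig(style_proportions={"towards": 0.5, "neutral": 0.2, "away": 0.0})
        with pytest.raises(ValueError, match="miss_rate"):
            CohortConfig(miss_rate=1.5)
        with pytest.raises(ValueError, match="side_length"):
            ArenaSpec(side_length=-1)

    def test_activity_covariates_of_static_dog(self):
        dog = np.tile([1.0, 1.0], (100, 1))
        cov = activity_covariates(dog, np.array([2.35, 2.35]), fps=24)
        assert cov["speed_norm"] == 0.0
        assert cov["near_frac"] == 0.0  # distance 1.909 > 1.5
        assert cov["mean_tp_distance"] == pytest.approx(np.hypot(1.35, 1.35))
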