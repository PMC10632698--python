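import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import puzzletrain as pt
from puzzletrain.adaptive import (
    AdaptiveConfig,
    AttemptRecord,
    ConstantTimeModel,
    adjusted_r2,
    attempts_to_features,
    decide_next_level,
    level_sd,
    pretest_composite,
)
from puzzletrain.ladder import Game, build_ladder

LADDER = build_ladder("match3")


def linear_attempts(n=100, participant="P1"):
    """Noiseless world: t_m is exactly 20 + 15 * (level_index - 1)."""
    out = []
    for i in range(n):
        level = LADDER[i % 25 + 1]
        out.append(
            AttemptRecord(
                participant_id=participant,
                game=Game.MATCH3,
                level=level,
                t_m=20.0 + 15.0 * (level.index - 1),
                solved=True,
                session_index=i // 25 + 1,
            )
        )
    return out


class TestLadder:
    def test_full_ranges_give_25_levels(self):
        assert len(build_ladder("numberlink")) == 25

    def test_single_combination_gives_one_level(self):
        ladder = build_ladder("match3", s_range={4}, g_range={4})
        assert len(ladder) == 1 and ladder[1].index == 1

    def test_board_growth_dominates_order(self):
        # all object counts at size 4 precede size 5
        assert LADDER[5].board_size == 4 and LADDER[5].num_objects == 8
        assert LADDER[6].board_size == 5 and LADDER[6].num_objects == 4

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            build_ladder("match3", s_range=set(), g_range={4})


class TestAdjustedR2:
    @pytest.mark.parametrize(
        "r2, n, p, expected",
        [(1.0, 50, 3, 1.0), (0.0, 11, 1, -1.0 / 9.0), (0.8, 21, 4, 0.75)],
    )
    def test_direct_arithmetic(self, r2, n, p, expected):
        assert adjusted_r2(r2, n, p) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_sample_size_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 5, 4)


class TestLevelPredictor:
    @pytest.mark.parametrize(
        "t_m, expected",
        [(10.0, 0), (11.0, 0), (11.01, -1), (9.0, 0), (8.99, 1), (8.9, 1), (600.0, -1)],
    )
    def test_piecewise_rule_with_strict_boundaries(self, t_m, expected):
        assert decide_next_level(t_m, t_p=10.0, sigma=2.0, c=0.5) == expected

    @given(
        t_p=st.floats(1, 500),
        delta=st.floats(0.01, 400),
        sigma=st.floats(0, 100),
        c=st.floats(0.01, 0.99),
    )
    @settings(max_examples=300, derandomize=True)
    def test_decision_symmetry(self, t_p, delta, sigma, c):
        """Advancing at t_p − δ must mirror retreating at t_p + δ."""
        if delta > c * sigma + 1e-6 and t_p - delta > 0:
            assert decide_next_level(t_p - delta, t_p, sigma, c) == 1
            assert decide_next_level(t_p + delta, t_p, sigma, c) == -1

    @given(
        t_m=st.floats(1, 500),
        t_p=st.floats(1, 500),
        sigma=st.floats(0, 100),
        c_lo=st.floats(0.01, 0.98),
        c_hi=st.floats(0.01, 0.98),
    )
    @settings(max_examples=300, derandomize=True)
    def test_widening_the_band_never_flips_stay_to_move(self, t_m, t_p, sigma, c_lo, c_hi):
        lo, hi = sorted((c_lo, c_hi + 0.01))
        if decide_next_level(t_m, t_p, sigma, lo) == 0:
            assert decide_next_level(t_m, t_p, sigma, hi) == 0

    def test_ladder_clamps(self):
        assert pt.next_level(LADDER, LADDER[1], -1).index == 1
        assert pt.next_level(LADDER, LADDER[25], +1).index == 25
        assert pt.next_level(LADDER, LADDER[7], +1).index == 8


class TestLevelSd:
    def make(self, times, index=3):
        return [
            AttemptRecord("P", Game.MATCH3, LADDER[index], t, True, 1) for t in times
        ]

    def test_sample_sd(self):
        assert level_sd(self.make([10, 12, 14]), LADDER[3]) == pytest.approx(2.0)

    def test_single_attempt_uses_fallback(self):
        config = AdaptiveConfig(sigma_floor=2.0, min_attempts_for_sigma=3)
        assert level_sd(self.make([10]), LADDER[3], config, t_p=50.0) == pytest.approx(10.0)
        assert level_sd(self.make([10]), LADDER[3], config) == pytest.approx(2.0)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        times = rng.lognormal(3, 0.4, size=40)
        mean = sum(times) / len(times)
        two_pass = (sum((t - mean) ** 2 for t in times) / (len(times) - 1)) ** 0.5
        assert level_sd(self.make(times), LADDER[3]) == pytest.approx(two_pass, rel=1e-12)


class TestTimeModel:
    def test_noiseless_linear_world_selects_linear_with_unit_score(self):
        model = pt.fit_time_model(linear_attempts())
        assert model.selected == "linear"
        assert model.scores["linear"] == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_candidate_never_wins_on_noiseless_data(self):
        from sklearn.dummy import DummyRegressor

        candidates = pt.adaptive.default_candidates(n_samples=100)
        candidates.append(("noise_floor", DummyRegressor(strategy="mean")))
        model = pt.fit_time_model(linear_attempts(), candidates=candidates)
        assert model.selected == "linear"
        assert model.scores["noise_floor"] < 0.1

    def test_simulator_data_is_learnable(self, training_attempts):
        attempts = [a for a in training_attempts if a.game == Game.MATCH3][:200]
        model = pt.fit_time_model(attempts, seed=0)
        assert max(model.scores.values()) >= 0.5

    def test_requires_enough_attempts_and_levels(self):
        with pytest.raises(ValueError, match="20 attempts"):
            pt.fit_time_model(linear_attempts(10))
        flat = [
            AttemptRecord("P", Game.MATCH3, LADDER[1], 20.0, True, 1) for _ in range(25)
        ]
        with pytest.raises(ValueError):
            pt.fit_time_model(flat)

    def test_prediction_recovers_the_generating_line(self):
        model = pt.fit_time_model(linear_attempts())
        for index in (1, 5, 13, 25):
            level = LADDER[index]
            expected = 20.0 + 15.0 * (index - 1)
            history = {"session_index": 2, "running_mean_time": expected}
            assert pt.predict_time(model, level, history) == pytest.approx(expected, rel=1e-6)

    def test_prediction_nondecreasing_in_level_in_monotone_world(self):
        model = pt.fit_time_model(linear_attempts())
        history = {"session_index": 2, "running_mean_time": 100.0}
        preds = [pt.predict_time(model, LADDER[i], history) for i in range(1, 26)]
        assert all(b >= a - 1e-9 for a, b in zip(preds, preds[1:]))

    def test_prediction_depends_only_on_history_summary(self):
        model = pt.fit_time_model(linear_attempts())
        h = {"session_index": 3, "running_mean_time": 80.0}
        assert pt.predict_time(model, LADDER[7], h) == pt.predict_time(model, LADDER[7], dict(h))

    def test_extrapolation_warns(self):
        attempts = [a for a in linear_attempts() if a.level.index <= 10]
        model = pt.fit_time_model(attempts + attempts[:0] if len(attempts) >= 20 else attempts)
        with pytest.warns(UserWarning, match="extrapolation"):
            pt.predict_time(model, LADDER[25])

    def test_bootstrap_model_follows_base_curve(self):
        model = ConstantTimeModel()
        assert pt.predict_time(model, LADDER[1]) == 20.0
        assert pt.predict_time(model, LADDER[25]) == 20.0 + 15.0 * 24

    def test_running_mean_never_leaks_current_attempt(self):
        attempts = linear_attempts(30)
        frame = attempts_to_features(attempts)
        # first row uses the neutral prior, not its own (known) time
        assert frame.loc[0, "running_mean_time"] != frame.loc[0, "t_m"]


class TestInitialLevel:
    def test_median_composite_starts_mid_ladder(self, reference_pretests):
        composites = sorted(pretest_composite(p, reference_pretests) for p in reference_pretests)
        median_like = min(
            reference_pretests,
            key=lambda p: abs(pretest_composite(p, reference_pretests) - np.median(composites)),
        )
        level = pt.assign_initial_level(median_like, LADDER, reference_pretests)
        assert level.index == 11  # lowest index of the middle band

    def test_best_composite_starts_at_top_band(self, reference_pretests):
        best = max(reference_pretests, key=lambda p: pretest_composite(p, reference_pretests))
        level = pt.assign_initial_level(best, LADDER, reference_pretests)
        assert level.index == 21  # highest of the designated starting indices

    def test_rank_order_preserved_over_random_pretests(self, reference_pretests):
        rng = np.random.default_rng(5)
        pretests = [
            pt.PretestScores(
                moca=float(rng.integers(24, 31)),
                tmt_a=float(rng.uniform(15, 60)),
                tmt_b=float(rng.uniform(40, 280)),
                smt=float(rng.uniform(8, 40)),
            )
            for _ in range(100)
        ]
        pairs = [
            (pretest_composite(p, reference_pretests),
             pt.assign_initial_level(p, LADDER, reference_pretests).index)
            for p in pretests
        ]
        pairs.sort()
        indices = [idx for _, idx in pairs]
        assert all(b >= a for a, b in zip(indices, indices[1:]))
        assert all(idx in (1, 6, 11, 16, 21) for idx in indices)
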