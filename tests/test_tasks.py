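"""Task battery: structure, parameters and determinism of every schedule."""

import numpy as np
import pytest

from volstoch.tasks import (
    label_switch_window,
    make_changepoint_task,
    make_conditioned_suppression,
    make_constant_2x2,
    make_partial_reinforcement,
    make_reversal_task,
    make_serial_prediction,
    make_switching_task,
    make_two_choice_task,
)

ALL_CTORS = [
    lambda rng: make_constant_2x2(0.5, 1.0, rng=rng),
    lambda rng: make_switching_task(rng=rng),
    lambda rng: make_conditioned_suppression("omission", rng=rng),
    lambda rng: make_partial_reinforcement("partial", rng=rng),
    lambda rng: make_serial_prediction("shift", rng=rng),
    lambda rng: make_reversal_task("stochastic_60_40", rng=rng),
    lambda rng: make_changepoint_task("small", rng=rng),
    lambda rng: make_two_choice_task(rng=rng),
]


@pytest.mark.parametrize("ctor", ALL_CTORS)
def test_deterministic_given_seed(ctor):
    a = ctor(np.random.default_rng(7))
    b = ctor(np.random.default_rng(7))
    assert np.array_equal(a.outcomes, b.outcomes)
    assert np.array_equal(a.phase, b.phase)


@pytest.mark.parametrize("ctor", ALL_CTORS)
def test_episode_alignment_and_metadata(ctor):
    ep = ctor(np.random.default_rng(1))
    assert ep.outcomes.shape[0] == ep.reward_rate_true.shape[0] == ep.phase.shape[0]
    assert "task" in ep.meta
    frame = ep.to_frame()
    assert len(frame) == ep.n_trials * ep.n_channels


class TestConstant2x2:
    def test_single_trial_episode_valid(self):
        ep = make_constant_2x2(0.5, 1.0, n_trials=1, rng=0)
        assert ep.n_trials == 1

    def test_larger_noise_gives_larger_outcome_variance(self):
        small = [np.var(make_constant_2x2(0.5, 1.0, rng=i).outcomes) for i in range(100)]
        large = [np.var(make_constant_2x2(1.5, 3.0, rng=i).outcomes) for i in range(100)]
        assert np.mean(large) > np.mean(small)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            make_constant_2x2(0.0, 1.0)


class TestSwitchingTask:
    def test_stable_block_rate_constant(self):
        ep = make_switching_task(rng=0)
        assert np.allclose(ep.reward_rate_true[ep.phase == "stable"], 0.8)

    def test_volatile_block_alternates(self):
        ep = make_switching_task(rng=0)
        vol = ep.reward_rate_true[ep.phase == "volatile"]
        assert set(np.unique(vol)) == {0.25, 0.75}
        assert len(ep.meta["switch_trials"]) >= 1

    def test_noiseless_limit(self):
        ep = make_switching_task(rng=0, outcome_var=0.0)
        assert np.array_equal(ep.outcomes, ep.reward_rate_true)

    def test_bad_block_kind_rejected(self):
        with pytest.raises(ValueError):
            make_switching_task(rng=0, block_lengths=(10,), block_order=("odd",))


class TestLabelSwitchWindow:
    def test_window_labels(self):
        labels = label_switch_window([5], 12, window=3)
        assert list(labels) == ["stable"] * 5 + ["volatile"] * 4 + ["stable"] * 3


class TestConditionedSuppression:
    def test_omission_has_five_zero_trials_at_end_of_pretraining(self):
        ep = make_conditioned_suppression("omission", rng=0)
        omission = ep.reward_rate_true[ep.phase == "omission"]
        assert omission.size == 5 and np.allclose(omission, 0.0)
        assert ep.meta["first_retraining_trial"] == 100

    def test_control_has_no_omissions(self):
        ep = make_conditioned_suppression("control", rng=0)
        pre = ep.reward_rate_true[:100]
        assert np.allclose(pre, 0.3)

    def test_retraining_is_strong_outcome(self):
        ep = make_conditioned_suppression("control", rng=0)
        assert np.allclose(ep.reward_rate_true[ep.phase == "retraining"], 1.0)

    def test_unknown_condition(self):
        with pytest.raises(ValueError):
            make_conditioned_suppression("bogus", rng=0)


class TestPartialReinforcement:
    def test_full_condition_rewards_every_pretraining_trial(self):
        ep = make_partial_reinforcement("full", rng=0)
        assert np.allclose(ep.reward_rate_true[ep.phase == "pretraining"], 1.0)

    def test_partial_condition_rewards_half(self):
        ep = make_partial_reinforcement("partial", rng=0)
        pre = ep.reward_rate_true[ep.phase == "pretraining"]
        assert pre.sum() == 50 and set(np.unique(pre)) == {0.0, 1.0}

    def test_extinction_outcomes_near_zero(self):
        ep = make_partial_reinforcement("full", rng=0)
        ext = ep.outcomes[ep.phase == "extinction"]
        assert np.all(np.abs(ext) < 0.1)


class TestSerialPrediction:
    def test_two_channels(self):
        ep = make_serial_prediction("consistent", rng=0)
        assert ep.n_channels == 2

    def test_consistent_tone_contingency_unchanged(self):
        ep = make_serial_prediction("consistent", rng=0)
        assert np.allclose(ep.reward_rate_true[:, 0], 1.0)

    def test_shift_drops_tone_contingency_in_phase2(self):
        ep = make_serial_prediction("shift", rng=0)
        p2 = ep.phase == "phase2"
        assert np.allclose(ep.reward_rate_true[p2, 0], 0.5)
        assert np.allclose(ep.reward_rate_true[~p2, 0], 1.0)
        assert np.allclose(ep.reward_rate_true[:, 1], 0.5)

    def test_phase2_shorter_and_probe_is_last_trial(self):
        ep = make_serial_prediction("shift", rng=0)
        n2 = int((ep.phase == "phase2").sum())
        assert n2 < int((ep.phase == "phase1").sum())
        assert ep.meta["probe_trial"] == ep.n_trials - 1


class TestReversalTask:
    def test_eighty_trials_and_reversal_in_range(self):
        for seed in range(30):
            ep = make_reversal_task("deterministic_100_0", rng=seed)
            assert ep.n_trials == 80
            assert 30 <= ep.meta["reversal_trial"] <= 50

    def test_deterministic_prereversal_contingencies(self):
        ep = make_reversal_task("deterministic_100_0", rng=1)
        rev = ep.meta["reversal_trial"]
        assert np.allclose(ep.reward_rate_true[:rev, 0], 1.0)
        assert np.allclose(ep.reward_rate_true[:rev, 1], 0.0)
        assert np.all(ep.correct_option[:rev] == 0)
        assert np.all(ep.correct_option[rev:] == 1)

    def test_unknown_schedule_lists_options(self):
        with pytest.raises(ValueError, match="available"):
            make_reversal_task("bogus", rng=0)

    @pytest.mark.parametrize("schedule,p_hi", [
        ("stochastic_60_40", 0.6), ("stochastic_70_30", 0.7), ("stochastic_80_20", 0.8),
    ])
    def test_stochastic_schedules(self, schedule, p_hi):
        ep = make_reversal_task(schedule, rng=2)
        rev = ep.meta["reversal_trial"]
        assert np.allclose(ep.reward_rate_true[:rev, 0], p_hi)


class TestChangepointTask:
    def test_runs_last_at_least_five_trials(self):
        # intervals between successive change points; the final segment is
        # censored by the episode end and may be shorter
        for seed in range(20):
            ep = make_changepoint_task("small", n_trials=300, rng=seed)
            cps = [0] + ep.meta["changepoints"]
            assert np.all(np.diff(cps) >= 5)

    def test_rates_within_range(self):
        ep = make_changepoint_task("large", n_trials=500, rng=3)
        assert np.all((ep.reward_rate_true >= 0) & (ep.reward_rate_true <= 10))

    @pytest.mark.parametrize("level,var", [("small", 1.0), ("large", 9.0)])
    def test_noise_variance_matches_level(self, level, var):
        resid = []
        for seed in range(30):
            ep = make_changepoint_task(level, n_trials=200, rng=seed)
            resid.append(np.var(ep.outcomes - ep.reward_rate_true, ddof=1))
        assert np.isclose(np.mean(resid), var, rtol=0.1)


class TestTwoChoiceTask:
    def test_two_options_with_complementary_switching_rates(self):
        ep = make_two_choice_task(rng=0)
        assert ep.n_channels == 2
        assert np.allclose(ep.reward_rate_true.sum(axis=1), 1.0)
        assert len(ep.meta["switch_trials"]) == ep.meta["n_blocks"] - 1

    def test_outcomes_are_binary_plus_noise(self):
        ep = make_two_choice_task(rng=1)
        rounded = np.round(ep.outcomes)
        resid = ep.outcomes - rounded
        assert set(np.unique(rounded)) <= {0.0, 1.0}
        assert np.isclose(np.var(resid), 0.01, rtol=0.3)
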