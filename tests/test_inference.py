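"""Learner core: Kalman recursion, particle prediction/weighting/resampling,
and the full filter including lesions and determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from volstoch import (
    ModelParams,
    ParticleEnsemble,
    effective_sample_size,
    filter_trial,
    kalman_step,
    predict_particles,
    run_filter,
    systematic_resample,
    weight_particles,
)


def reference_kalman(outcomes, v, s, m0=0.0, w0=100.0):
    """Independent closed-form Kalman recursion (the oracle)."""
    m, w = m0, w0
    out = []
    for o in outcomes:
        delta = o - m
        alpha = (w + v) / (w + v + s)
        m = m + alpha * delta
        w = (1.0 - alpha) * (w + v)
        out.append((m, w, alpha, delta))
    return np.array(out)


class TestKalmanStep:
    def test_hand_computed_example(self):
        m, w, alpha, delta = kalman_step(m=0.0, w=1.0, v=1.0, s=2.0, o=4.0)
        assert (alpha, delta, m, w) == (0.5, 4.0, 2.0, 1.0)

    def test_noiseless_observation_fully_trusted(self):
        m, w, alpha, _ = kalman_step(m=1.0, w=2.0, v=0.5, s=0.0, o=7.0)
        assert alpha == 1.0 and m == 7.0 and w == 0.0

    def test_known_static_value_ignores_outcome(self):
        m, w, alpha, _ = kalman_step(m=3.0, w=0.0, v=0.0, s=1.0, o=100.0)
        assert alpha == 0.0 and m == 3.0 and w == 0.0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            kalman_step(0.0, 0.0, 0.0, 0.0, 1.0)

    @given(
        w=st.floats(1e-6, 1e3), v=st.floats(1e-6, 1e3),
        s=st.floats(1e-6, 1e3), o=st.floats(-100, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_gain_bounds_and_contraction(self, w, v, s, o):
        m_next, w_next, alpha, _ = kalman_step(0.0, w, v, s, o)
        assert 0.0 < alpha < 1.0
        assert w_next < s and w_next < w + v
        # the two algebraic forms of the posterior variance agree
        assert np.isclose(w_next, (1 - alpha) * (w + v), rtol=1e-9, atol=1e-12)

    def test_gain_monotone_in_v_and_s(self):
        vs = np.linspace(0.1, 5, 30)
        alphas_v = [kalman_step(0, 1.0, v, 1.0, 0.0)[2] for v in vs]
        alphas_s = [kalman_step(0, 1.0, 1.0, s, 0.0)[2] for s in vs]
        assert np.all(np.diff(alphas_v) > 0)
        assert np.all(np.diff(alphas_s) < 0)


def _ensemble(weights, z=None, y=None, m=None, w=None):
    weights = np.asarray(weights, dtype=float)
    n = weights.size
    return ParticleEnsemble(
        z=np.ones(n) if z is None else np.asarray(z, float),
        y=np.ones(n) if y is None else np.asarray(y, float),
        m=np.zeros(n) if m is None else np.asarray(m, float),
        w=np.ones(n) if w is None else np.asarray(w, float),
        weights=weights,
    )


class TestEffectiveSampleSize:
    def test_uniform_weights(self):
        assert np.isclose(effective_sample_size(np.full(100, 0.01)), 100.0)

    def test_degenerate_weights(self):
        w = np.zeros(10)
        w[3] = 1.0
        assert np.isclose(effective_sample_size(w), 1.0)

    def test_hand_computed_value(self):
        # 1 / (0.25 + 0.0625 + 0.0625) = 8/3
        assert np.isclose(effective_sample_size([0.5, 0.25, 0.25]), 8.0 / 3.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size([0.5, 0.2])


class TestWeightParticles:
    def test_single_particle_gets_weight_one(self):
        ens = _ensemble([1.0])
        assert np.allclose(weight_particles(ens, 0.3), [1.0])

    def test_identical_particles_share_weight(self):
        ens = _ensemble([0.5, 0.5])
        assert np.allclose(weight_particles(ens, 1.7), [0.5, 0.5])

    def test_density_ratio_matches_standard_normal(self):
        # particle 0: predictive N(0, 1) at o=0 has density 1/sqrt(2*pi)
        ens = _ensemble([0.5, 0.5], z=[1e12, 1e12], y=[1.0, 1.0],
                        w=[1e-12, 1e-12], m=[0.0, 1.0])
        w = weight_particles(ens, 0.0)
        expected_ratio = 1.0 / np.exp(-0.5)  # N(0|0,1) / N(0|1,1)
        assert np.isclose(w[0] / w[1], expected_ratio)

    def test_underflow_falls_back_to_uniform(self):
        ens = _ensemble([0.5, 0.5], w=[1e-12, 1e-12], z=[1e12, 1e12],
                        y=[1e12, 1e12], m=[0.0, 0.0])
        with pytest.warns(UserWarning, match="underflow"):
            w = weight_particles(ens, 1e200)
        assert np.allclose(w, [0.5, 0.5])


class TestSystematicResample:
    def test_uniform_weights_copy_each_particle_once(self, rng):
        n = 16
        ens = _ensemble(np.full(n, 1.0 / n), z=np.arange(1, n + 1))
        out = systematic_resample(ens, rng)
        assert np.array_equal(np.sort(out.z), ens.z)
        assert np.allclose(out.weights, 1.0 / n)

    def test_offspring_counts_within_one_of_expectation(self, rng):
        weights = np.array([0.4, 0.3, 0.2, 0.05, 0.05])
        ens = _ensemble(weights, z=np.arange(1, 6))
        for _ in range(200):
            out = systematic_resample(ens, rng)
            counts = np.array([(out.z == k).sum() for k in ens.z])
            assert np.all(np.abs(counts - len(weights) * weights) < 1.0)

    def test_degenerate_weight_clones_winner(self, rng):
        w = np.zeros(8)
        w[5] = 1.0
        ens = _ensemble(w, z=np.arange(1, 9))
        out = systematic_resample(ens, rng)
        assert np.all(out.z == 6)

    def test_two_equal_weights_give_one_copy_each(self):
        ens = _ensemble([0.5, 0.5], z=[1.0, 2.0])
        for seed in range(50):
            out = systematic_resample(ens, np.random.default_rng(seed))
            assert sorted(out.z) == [1.0, 2.0]


class TestPredictParticles:
    def test_zero_update_rates_leave_ensemble_unchanged(self, rng):
        params = ModelParams(lambda_v=0.0, lambda_s=0.0)
        ens = ParticleEnsemble.initial(params)
        out = predict_particles(ens, params, rng)
        assert np.array_equal(out.z, ens.z) and np.array_equal(out.y, ens.y)

    def test_lesioned_variable_stays_pinned(self, rng):
        params = ModelParams(lambda_v=0.2, lambda_s=0.2,
                             lesion="fix_stochasticity", lesion_value=0.04)
        ens = ParticleEnsemble.initial(params)
        out = predict_particles(ens, params, rng)
        assert np.allclose(out.y, 1.0 / 0.04)
        assert not np.array_equal(out.z, ens.z)  # free variable diffused

    def test_martingale_on_inverse_volatility(self, rng):
        params = ModelParams(lambda_v=0.1, lambda_s=0.1, n_particles=100_000)
        ens = ParticleEnsemble.initial(params)
        out = predict_particles(ens, params, rng)
        se = out.z.std() / np.sqrt(out.z.size)
        assert abs(out.z.mean() - ens.z.mean()) < 3 * se


class TestFilterTrial:
    def test_collapses_to_kalman_with_zero_update_rates(self, rng):
        v, s = 0.7, 1.3
        params = ModelParams(lambda_v=0.0, lambda_s=0.0, v0=v, s0=s,
                             prior_mean=0.0, prior_var=100.0)
        outcomes = rng.normal(0, 1, 30)
        trace = run_filter(outcomes, params, seed=5)
        ref = reference_kalman(outcomes, v, s)
        assert np.allclose(trace.m, ref[:, 0], atol=1e-12)
        assert np.allclose(trace.w, ref[:, 1], atol=1e-12)
        assert np.allclose(trace.alpha, ref[:, 2], atol=1e-12)

    def test_resampling_fires_on_degenerate_ensemble(self, rng):
        params = ModelParams(n_particles=3, ess_ratio_threshold=0.5,
                             lambda_v=0.0, lambda_s=0.0)
        ens = _ensemble([0.9, 0.05, 0.05], m=[0.0, 50.0, -50.0])
        _, rec = filter_trial(ens, 0.0, params, rng)
        assert rec["resampled"]

    def test_lesioned_volatility_estimate_constant(self):
        params = ModelParams(lambda_v=0.2, lambda_s=0.2,
                             lesion="fix_volatility", lesion_value=0.3)
        trace = run_filter(np.sin(np.arange(60)), params, seed=1)
        assert np.allclose(trace.v_hat, 0.3)


class TestRunFilter:
    def test_constant_outcomes_converge(self):
        # fixed hyperparameters: the gain decays monotonically toward its
        # fixed point and the mean converges to the constant outcome
        params = ModelParams(lambda_v=0.0, lambda_s=0.0, v0=0.5, s0=1.0)
        trace = run_filter(np.full(300, 2.0), params, seed=0)
        assert abs(trace.m[-1] - 2.0) < 1e-6
        assert np.all(np.diff(trace.alpha) <= 1e-12)
        # adaptive hyperparameters still converge in mean
        adaptive = ModelParams(lambda_v=0.05, lambda_s=0.05, v0=0.5, s0=1.0)
        trace2 = run_filter(np.full(300, 2.0), adaptive, seed=0)
        assert abs(trace2.m[-1] - 2.0) < 0.05

    def test_trace_lengths_and_bounds(self, rng):
        params = ModelParams()
        outcomes = rng.normal(0, 1, 80)
        trace = run_filter(outcomes, params, seed=3)
        assert len(trace) == 80
        assert np.all((trace.alpha > 0) & (trace.alpha < 1))
        assert np.all((trace.ess >= 1) & (trace.ess <= params.n_particles + 1e-9))
        assert np.all(trace.v_hat > 0) and np.all(trace.s_hat > 0)

    def test_bit_identical_reruns(self, rng):
        params = ModelParams(lambda_v=0.1, lambda_s=0.1)
        outcomes = rng.normal(0, 1, 50)
        t1 = run_filter(outcomes, params, seed=11)
        t2 = run_filter(outcomes, params, seed=11)
        for field in ("m", "w", "alpha", "v_hat", "s_hat", "ess"):
            assert np.array_equal(getattr(t1, field), getattr(t2, field))

    def test_empty_and_nonfinite_outcomes_rejected(self):
        params = ModelParams()
        with pytest.raises(ValueError):
            run_filter([], params, seed=0)
        with pytest.raises(ValueError, match="trial 3"):
            run_filter([1.0, 2.0, np.nan, 4.0], params, seed=0)

    def test_trace_csv_roundtrip(self, rng, tmp_path):
        import pandas as pd
        trace = run_filter(rng.normal(0, 1, 20), ModelParams(), seed=2)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "trial", "outcome", "m", "w", "alpha", "delta",
            "v_hat", "s_hat", "ess", "resampled",
        ]
        assert len(df) == 20 and df["trial"].iloc[0] == 1


class TestModelParams:
    @pytest.mark.parametrize("kwargs", [
        {"lambda_v": 1.0}, {"lambda_s": -0.1}, {"v0": 0.0},
        {"n_particles": 0}, {"lesion": "bogus"},
        {"ess_ratio_threshold": 0.0}, {"lesion_value": -1.0},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_dict_roundtrip(self):
        p = ModelParams(lambda_v=0.2, lesion="fix_volatility", lesion_value=0.01)
        assert ModelParams.from_dict(p.to_dict()) == p

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelParams.from_dict({"lambda_x": 0.1})

    def test_lesion_value_defaults_to_initial(self):
        p = ModelParams(v0=0.7, lesion="fix_volatility")
        assert p.fixed_v == 0.7
        q = ModelParams(s0=2.5, lesion="fix_stochasticity", lesion_value=0.1)
        assert q.fixed_s == 0.1
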