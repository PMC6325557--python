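import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbgt.learning import (CriticState, LearningParams, PlasticWeights,
                           bounded_update, corticostriatal_delta, critic_update,
                           end_of_trial_learning, hebbian_delta,
                           reward_prediction_error)

P = LearningParams()


class TestCritic:
    @pytest.mark.parametrize("r,v,expected", [(1, 0.0, 1.0), (0, 1.0, -1.0), (1, 0.6, 0.4)])
    def test_rpe(self, r, v, expected):
        assert reward_prediction_error(r, v) == pytest.approx(expected)

    def test_update_touches_only_chosen_cue(self):
        s = CriticState.initial()
        critic_update(s, 0, 1.0, 0.025)
        assert s.values[0] == pytest.approx(0.025)
        assert np.all(s.values[1:] == 0.0)

    def test_zero_rpe_is_noop(self):
        s = CriticState.initial()
        critic_update(s, 2, 0.0, 0.025)
        assert np.all(s.values == 0.0)

    def test_unknown_cue(self):
        with pytest.raises(ValueError):
            critic_update(CriticState.initial(), 7, 0.5, 0.025)

    def test_constant_reward_closed_form(self):
        # V after k unit-reward updates follows 1 - (1-alpha)^k
        s = CriticState.initial()
        for _ in range(100):
            rpe = reward_prediction_error(1, s.values[0])
            critic_update(s, 0, rpe, 0.025)
        assert s.values[0] == pytest.approx(1 - (1 - 0.025) ** 100, abs=1e-12)

    def test_convergence_to_reward_probability(self):
        """2000 draws at p=0.65 drive the value to p within +/-0.05
        (stochastic approximation; the sample mean is the oracle)."""
        rng = np.random.default_rng(5)
        p_true = 0.65
        s = CriticState.initial()
        draws = rng.random(2000) < p_true
        tail = []
        for r in draws:
            critic_update(s, 0, reward_prediction_error(int(r), s.values[0]), 0.025)
            tail.append(s.values[0])
        v_hat = np.mean(tail[-500:])  # time-averaged iterate
        assert abs(v_hat - draws.mean()) <= 0.05
        assert abs(v_hat - p_true) <= 0.05


class TestDeltas:
    @pytest.mark.parametrize("rpe,u,expected", [
        (0.0, 10.0, 0.0),
        (0.5, 10.0, 0.25),     # LTP side: 0.050 x 0.5 x 10
        (-0.5, 10.0, -0.15),   # LTD side: 0.030 x (-0.5) x 10
    ])
    def test_corticostriatal(self, rpe, u, expected):
        assert corticostriatal_delta(rpe, u, P) == pytest.approx(expected)

    def test_ltp_ltd_asymmetry_ratio(self):
        up = corticostriatal_delta(0.3, 7.0, P)
        down = corticostriatal_delta(-0.3, 7.0, P)
        assert up / abs(down) == pytest.approx(0.050 / 0.030)

    def test_hebbian(self):
        assert hebbian_delta(0.0, 50.0, P) == 0.0
        assert hebbian_delta(10.0, 10.0, P) == pytest.approx(0.5)

    @given(st.floats(0, 50), st.floats(0, 50), st.floats(0.01, 50))
    @settings(max_examples=100)
    def test_hebbian_monotone_nonnegative(self, a, b, inc):
        assert hebbian_delta(a, b, P) >= 0
        assert hebbian_delta(a + inc, b, P) >= hebbian_delta(a, b, P)


class TestBoundedUpdate:
    def test_bounds_are_fixed_points(self):
        assert bounded_update(0.75, 99.0, P) == 0.75
        assert bounded_update(0.25, -99.0, P) == 0.25

    def test_midrange_example(self):
        # 0.5 + 0.08 x (0.75-0.5) x (0.5-0.25) = 0.505
        assert bounded_update(0.5, 0.08, P) == pytest.approx(0.505)

    def test_out_of_range_weight_rejected(self):
        with pytest.raises(ValueError):
            bounded_update(0.9, 0.01, P)

    @given(st.floats(0.25, 0.75), st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=50))
    @settings(max_examples=100)
    def test_always_stays_in_bounds(self, w, deltas):
        for dw in deltas:
            w = float(bounded_update(w, dw, P))
            assert 0.25 <= w <= 0.75


class TestEndOfTrial:
    def _state(self, rng):
        return PlasticWeights.initial(rng), CriticState.initial()

    def test_failed_trial_changes_nothing(self, rng):
        w, c = self._state(rng)
        w0, cc0, v0 = w.cortico_striatal.copy(), w.cortico_cortical.copy(), c.values.copy()
        end_of_trial_learning(
            chosen_cue=None, reward=None,
            u_ctx_cog=np.zeros(4), u_ctx_ass=np.zeros((4, 4)),
            u_str_cog=np.zeros(4), weights=w, critic=c, params=P,
            move_initiated=False,
        )
        assert np.array_equal(w.cortico_striatal, w0)
        assert np.array_equal(w.cortico_cortical, cc0)
        assert np.array_equal(c.values, v0)

    def test_rewarded_trial_potentiates_chosen_cue(self, rng):
        w, c = self._state(rng)
        w0 = w.cortico_striatal.copy()
        end_of_trial_learning(
            chosen_cue=1, reward=1,
            u_ctx_cog=np.array([0, 3.0, 0, 0]),
            u_ctx_ass=np.zeros((4, 4)),
            u_str_cog=np.array([0, 2.0, 0, 0]),
            weights=w, critic=c, params=P, move_initiated=True,
        )
        assert w.cortico_striatal[1] > w0[1]
        assert np.array_equal(np.delete(w.cortico_striatal, 1), np.delete(w0, 1))
        assert c.values[1] == pytest.approx(0.025)

    def test_decided_trial_strengthens_active_binding(self, rng):
        w, c = self._state(rng)
        cc0 = w.cortico_cortical.copy()
        u_ass = np.zeros((4, 4)); u_ass[1, 2] = 4.0
        end_of_trial_learning(
            chosen_cue=1, reward=0,
            u_ctx_cog=np.array([0, 5.0, 0, 0]), u_ctx_ass=u_ass,
            u_str_cog=np.zeros(4), weights=w, critic=c, params=P,
            move_initiated=True,
        )
        assert w.cortico_cortical[1, 2] > cc0[1, 2]
        mask = np.ones((4, 4), bool); mask[1, 2] = False
        assert np.allclose(w.cortico_cortical[mask], cc0[mask])

    def test_hebbian_path_ignores_rewards(self, rng):
        """Shuffling the reward sequence leaves the cortico-cortical weight
        trajectory unchanged for fixed choices and activities."""
        activities = [(np.abs(rng.normal(2, 1, 4)), np.abs(rng.normal(2, 1, (4, 4))))
                      for _ in range(30)]
        rewards = [int(r) for r in rng.random(30) < 0.5]
        shuffled = list(rewards); rng.shuffle(shuffled)

        def run(reward_seq):
            w = PlasticWeights(np.full(4, 0.5), np.full((4, 4), 0.5))
            c = CriticState.initial()
            for (ucog, uass), r in zip(activities, reward_seq):
                end_of_trial_learning(
                    chosen_cue=0, reward=r, u_ctx_cog=ucog, u_ctx_ass=uass,
                    u_str_cog=np.full(4, 1.0), weights=w, critic=c, params=P,
                    move_initiated=True,
                )
            return w.cortico_cortical

        assert np.array_equal(run(rewards), run(shuffled))

    def test_weights_stay_bounded_over_many_trials(self, rng):
        w, c = self._state(rng)
        for k in range(500):
            end_of_trial_learning(
                chosen_cue=int(rng.integers(4)), reward=int(rng.integers(2)),
                u_ctx_cog=np.abs(rng.normal(0, 20, 4)),
                u_ctx_ass=np.abs(rng.normal(0, 20, (4, 4))),
                u_str_cog=np.abs(rng.normal(0, 20, 4)),
                weights=w, critic=c, params=P, move_initiated=True,
            )
        assert np.all((w.cortico_striatal >= 0.25) & (w.cortico_striatal <= 0.75))
        assert np.all((w.cortico_cortical >= 0.25) & (w.cortico_cortical <= 0.75))
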