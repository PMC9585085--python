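"""Likelihood core: latent updates, choice rule, sequence log-likelihoods.

The deep check is against ``naive_log_likelihood``, an independently
coded per-trial recomputation of the update and choice equations using
plain dicts, kept deliberately free of any shared code with the package
implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avoidrl import (
    ModelParams,
    action_probability,
    initial_state,
    random_log_likelihood,
    sequence_log_likelihood,
    update_values,
)
from avoidrl.models import simulate_rl_choices

from conftest import make_dataset, random_dataset


# ---------------------------------------------------------------- oracle
def naive_log_likelihood(trials, alpha, alpha_hab, beta, w, counterfactual):
    """Step-by-step trace of the model equations on (choice, feedback, valid)."""
    Q = {"left": 0.5, "right": 0.5}
    H = {"left": 0.0, "right": 0.0}
    D = {"left": 0.5, "right": 0.5}
    ll = 0.0
    for choice, feedback, valid in trials:
        if not valid:
            continue
        other = "left" if choice == "right" else "right"
        p = 1.0 / (1.0 + math.exp((D[other] - D[choice]) * beta))
        ll += math.log(p)
        r = 1.0 if feedback == "avoidance" else 0.0
        Q[choice] = Q[choice] + alpha * (r - Q[choice])
        if counterfactual:
            Q[other] = Q[other] + alpha * ((1.0 - r) - Q[other])
        H[choice] = H[choice] + alpha_hab * (1.0 - H[choice])
        H[other] = H[other] + alpha_hab * (0.0 - H[other])
        for s in ("left", "right"):
            D[s] = w * H[s] + (1.0 - w) * Q[s]
    return ll


param_floats = st.floats(0.01, 0.99)


class TestInitialState:
    def test_values(self):
        s = initial_state(ModelParams(alpha=0.3, alpha_hab=0.2, beta=2.0, w=0.7))
        assert s.q == (0.5, 0.5)
        assert s.h == (0.0, 0.0)
        assert s.d == (0.5, 0.5)

    def test_first_choice_is_equiprobable_for_any_beta(self):
        for beta in (0.0, 1.0, 30.0):
            p = ModelParams(alpha=0.5, alpha_hab=0.5, beta=beta, w=0.5)
            assert action_probability(initial_state(p), p, "left") == pytest.approx(0.5)


class TestActionProbability:
    def test_hand_value(self):
        from avoidrl import LatentState

        s = LatentState(q=(0.75, 0.25), h=(0.0, 0.0), d=(0.75, 0.25))
        p = ModelParams(alpha=0.5, alpha_hab=0.0, beta=1.0, w=0.0)
        assert action_probability(s, p, "left") == pytest.approx(1 / (1 + math.exp(-0.5)), abs=1e-12)

    def test_beta_zero_is_coin_flip(self):
        from avoidrl import LatentState

        s = LatentState(q=(0.9, 0.1), h=(0.0, 0.0), d=(0.9, 0.1))
        p = ModelParams(alpha=0.5, alpha_hab=0.0, beta=0.0, w=0.0)
        assert action_probability(s, p, "left") == 0.5
        assert action_probability(s, p, "right") == 0.5

    @given(dl=st.floats(0, 1), dr=st.floats(0, 1), beta=st.floats(0, 30))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_probabilities_normalize(self, dl, dr, beta):
        from avoidrl import LatentState

        s = LatentState(q=(dl, dr), h=(0.0, 0.0), d=(dl, dr))
        p = ModelParams(alpha=0.5, alpha_hab=0.0, beta=beta, w=0.0)
        total = action_probability(s, p, "left") + action_probability(s, p, "right")
        assert total == pytest.approx(1.0, abs=1e-12)


class TestUpdateValues:
    def test_simple_leaves_unchosen_q(self):
        p = ModelParams(alpha=0.5, alpha_hab=0.1, beta=1.0, w=0.3)
        s, _ = update_values(initial_state(p), "left", "avoidance", p, "simple")
        assert s.q[1] == 0.5

    def test_counterfactual_hand_case(self):
        p = ModelParams(alpha=0.5, alpha_hab=0.0, beta=1.0, w=0.0)
        s, upd = update_values(initial_state(p), "left", "avoidance", p, "counterfactual")
        assert s.q == pytest.approx((0.75, 0.25))
        assert upd.reward_chosen == 1.0 and upd.reward_unchosen == 0.0
        assert upd.delta_chosen == pytest.approx(0.5)

    def test_habit_hand_case(self):
        p = ModelParams(alpha=0.0, alpha_hab=0.1, beta=1.0, w=1.0)
        s, _ = update_values(initial_state(p), "left", "approach", p, "simple")
        assert s.h == pytest.approx((0.1, 0.0))

    def test_d_recomputed_from_q_and_h(self):
        p = ModelParams(alpha=0.4, alpha_hab=0.2, beta=1.0, w=0.6)
        s, _ = update_values(initial_state(p), "right", "avoidance", p, "counterfactual")
        for i in (0, 1):
            assert s.d[i] == pytest.approx(p.w * s.h[i] + (1 - p.w) * s.q[i], abs=1e-15)

    def test_missing_feedback_is_flagged_noop(self):
        p = ModelParams(alpha=0.5, alpha_hab=0.1, beta=1.0, w=0.3)
        s0 = initial_state(p)
        s, upd = update_values(s0, "left", "none", p, "simple")
        assert s == s0 and not upd.updated


class TestSequenceLogLikelihood:
    def test_matches_naive_oracle_on_random_short_datasets(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            ds = random_dataset(rng, n_trials=10)
            params = ModelParams(
                alpha=float(rng.uniform(0.01, 0.99)),
                alpha_hab=float(rng.uniform(0.01, 0.99)),
                beta=float(rng.uniform(0.0, 10.0)),
                w=float(rng.uniform(0.01, 0.99)),
            )
            trials = list(zip(ds.trials["choice_side"], ds.trials["feedback"],
                              ds.trials["valid"]))
            for kind, cf in (("simple", False), ("counterfactual", True)):
                expected = naive_log_likelihood(
                    trials, params.alpha, params.alpha_hab, params.beta, params.w, cf
                )
                got, _ = sequence_log_likelihood(ds, params, kind)
                assert got == pytest.approx(expected, abs=1e-12)

    def test_beta_zero_gives_chance_likelihood(self, learner_dataset):
        p = ModelParams(alpha=0.5, alpha_hab=0.5, beta=0.0, w=0.5)
        ll, _ = sequence_log_likelihood(learner_dataset, p, "simple")
        assert ll == pytest.approx(learner_dataset.n_valid * math.log(0.5), abs=1e-9)

    def test_invalid_trials_contribute_nothing(self):
        valid = [True] * 10
        for i in (2, 5, 8):
            valid[i] = False
        ds = make_dataset(["left"] * 10, ["avoidance"] * 10, valid=valid)
        p = ModelParams(alpha=0.3, alpha_hab=0.1, beta=2.0, w=0.4)
        ll, probs = sequence_log_likelihood(ds, p, "counterfactual")
        assert np.isnan(probs).sum() == 3
        assert ll == pytest.approx(np.log(probs[~np.isnan(probs)]).sum(), abs=1e-12)

    def test_zero_valid_trials_warns(self):
        ds = make_dataset(["left"] * 3, ["avoidance"] * 3, valid=[False] * 3)
        p = ModelParams(alpha=0.3, alpha_hab=0.1, beta=2.0, w=0.4)
        with pytest.warns(UserWarning, match="no valid trials"):
            ll, _ = sequence_log_likelihood(ds, p, "simple")
        assert ll == 0.0

    def test_side_relabeling_symmetry(self):
        rng = np.random.default_rng(13)
        ds = random_dataset(rng, n_trials=30)
        swap = {"left": "right", "right": "left", "": ""}
        df = ds.trials.copy()
        df["choice_side"] = df["choice_side"].map(swap)
        df["optimal_side"] = df["optimal_side"].map(swap)
        mirrored = type(ds)(subject_id="M", trials=df)
        p = ModelParams(alpha=0.4, alpha_hab=0.2, beta=3.0, w=0.5)
        for kind in ("simple", "counterfactual"):
            a, _ = sequence_log_likelihood(ds, p, kind)
            b, _ = sequence_log_likelihood(mirrored, p, kind)
            assert a == pytest.approx(b, abs=1e-12)

    @given(alpha=param_floats, ahab=param_floats, w=param_floats,
           seed=st.integers(0, 1000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_q_and_h_stay_bounded(self, alpha, ahab, w, seed):
        """With rewards in {0,1} and rates in [0,1], Q and H never leave [0,1]."""
        rng = np.random.default_rng(seed)
        p = ModelParams(alpha=alpha, alpha_hab=ahab, beta=2.0, w=w)
        state = initial_state(p)
        for _ in range(200):
            side = ("left", "right")[rng.integers(2)]
            fb = ("approach", "avoidance")[rng.integers(2)]
            kind = ("simple", "counterfactual")[rng.integers(2)]
            state, _ = update_values(state, side, fb, p, kind)
            assert all(0.0 <= v <= 1.0 for v in state.q)
            assert all(0.0 <= v <= 1.0 for v in state.h)

    def test_counterfactual_conserves_q_sum(self):
        rng = np.random.default_rng(5)
        p = ModelParams(alpha=0.7, alpha_hab=0.2, beta=2.0, w=0.4)
        state = initial_state(p)
        for _ in range(300):
            side = ("left", "right")[rng.integers(2)]
            fb = ("approach", "avoidance")[rng.integers(2)]
            state, _ = update_values(state, side, fb, p, "counterfactual")
            assert state.q[0] + state.q[1] == pytest.approx(1.0, abs=1e-12)

    def test_w_zero_reduces_to_plain_q_learning(self):
        """With w = 0 the habit kernel cannot influence choice probabilities."""
        rng = np.random.default_rng(9)
        ds = random_dataset(rng, n_trials=40)
        base = ModelParams(alpha=0.5, alpha_hab=0.3, beta=4.0, w=0.0)
        nohab = ModelParams(alpha=0.5, alpha_hab=0.0, beta=4.0, w=0.0)
        for kind in ("simple", "counterfactual"):
            a, pa = sequence_log_likelihood(ds, base, kind)
            b, pb = sequence_log_likelihood(ds, nohab, kind)
            assert a == pytest.approx(b, abs=1e-12)
            np.testing.assert_allclose(pa, pb, atol=1e-12)

    def test_pure_perseveration_limit(self):
        """alpha = 0, w = 1: probabilities depend only on choice history."""
        choices = ["left"] * 5 + ["right"] * 5
        a = make_dataset(choices, ["avoidance"] * 10)
        b = make_dataset(choices, ["approach"] * 10)
        p = ModelParams(alpha=0.0, alpha_hab=0.3, beta=5.0, w=1.0)
        la, _ = sequence_log_likelihood(a, p, "simple")
        lb, _ = sequence_log_likelihood(b, p, "simple")
        assert la == pytest.approx(lb, abs=1e-12)


class TestRandomModel:
    def test_full_session_value(self):
        ds = make_dataset(["left"] * 300, ["avoidance"] * 300)
        ll = random_log_likelihood(ds)
        assert ll == pytest.approx(300 * math.log(0.5), abs=1e-12)
        assert round(ll) == -208

    def test_counts_only_valid_trials(self):
        ds = make_dataset(["left"] * 10, ["avoidance"] * 10,
                          valid=[True] * 7 + [False] * 3)
        assert random_log_likelihood(ds) == pytest.approx(7 * math.log(0.5))

    def test_empty_dataset_is_zero(self):
        ds = make_dataset(["left"] * 4, ["avoidance"] * 4, valid=[False] * 4)
        assert random_log_likelihood(ds) == 0.0


class TestGenerativeTwin:
    def test_fast_simulator_matches_object_api_replay(self, default_config):
        """simulate_rl_choices consumes (u_choice, u_feedback) exactly like a
        per-trial replay through initial_state/action_probability/update_values."""
        rng = np.random.default_rng(31)
        optimal = np.array([0] * 20 + [1] * 20)
        params = ModelParams(alpha=0.6, alpha_hab=0.15, beta=3.0, w=0.4)
        for kind in ("simple", "counterfactual"):
            seed = int(rng.integers(2**31))
            choices, rewards = simulate_rl_choices(
                optimal, params, kind, np.random.default_rng(seed))
            # independent replay with the same uniform draws
            rep = np.random.default_rng(seed)
            u_choice = rep.random(len(optimal))
            u_feedback = rep.random(len(optimal))
            state = initial_state(params)
            for i in range(len(optimal)):
                p_left = action_probability(state, params, "left")
                c = 0 if u_choice[i] < p_left else 1
                p_av = 0.8 if c == optimal[i] else 0.2
                r = 1 if u_feedback[i] < p_av else 0
                assert choices[i] == c and rewards[i] == r
                state, _ = update_values(
                    state, c, "avoidance" if r else "approach", params, kind)
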