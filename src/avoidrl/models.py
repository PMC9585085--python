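"""Reinforcement-learning likelihood core for the two-choice avoidance task.

Implements a Q-learning model augmented with a habit (choice-kernel)
value, in two variants:

``simple``
    only the chosen option's Q-value is updated with the obtained
    feedback (avoidance coded 1, approach coded 0);
``counterfactual``
    the unchosen option is additionally updated, with the same learning
    rate, against the complementary (fictive) outcome ``1 - R``.

Both variants track, per response side, an instrumental value ``Q``, a
habit value ``H`` that grows with repeated selection regardless of
outcome, and a combined decision value ``D = w*H + (1 - w)*Q``.  Choices
follow a softmax on the ``D`` difference with inverse temperature
``beta``.  A parameter-free ``random`` model (both sides at probability
0.5) serves as the chance baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LOG_FLOOR",
    "MODEL_KINDS",
    "RL_KINDS",
    "ModelParams",
    "LatentState",
    "TrialUpdate",
    "initial_state",
    "action_probability",
    "update_values",
    "sequence_log_likelihood",
    "random_log_likelihood",
    "simulate_rl_choices",
]

#: Floor applied to per-trial log choice probabilities so the optimizer
#: never sees -inf at extreme inverse temperatures.
LOG_FLOOR = math.log(1e-12)

MODEL_KINDS = ("random", "simple", "counterfactual")
#: The two kinds that carry free parameters.
RL_KINDS = ("simple", "counterfactual")

#: Integer codes for the two response sides.
LEFT, RIGHT = 0, 1
SIDE_NAMES = ("left", "right")


def side_code(side) -> int:
    """Normalize a side given as ``"left"/"right"`` or ``0/1`` to an int code."""
    if side in (LEFT, RIGHT):
        return int(side)
    try:
        return SIDE_NAMES.index(side)
    except ValueError:
        raise ValueError(f"unknown side {side!r}; expected 'left', 'right', 0 or 1")


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the learning models.

    Parameters
    ----------
    alpha:
        Learning rate for the instrumental Q-values, in [0, 1].
    alpha_hab:
        Habit (perseveration) learning rate, in [0, 1].
    beta:
        Softmax inverse temperature, >= 0.  Larger values make choices
        more deterministic with respect to value differences.
    w:
        Mixing weight between habit and instrumental value in the
        combined decision value ``D = w*H + (1 - w)*Q``; ``w -> 1``
        means choice is dominated by perseveration.
    """

    alpha: float
    alpha_hab: float
    beta: float
    w: float

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 <= self.alpha_hab <= 1.0:
            raise ValueError(f"alpha_hab must lie in [0, 1], got {self.alpha_hab}")
        if not self.beta >= 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w}")

    def to_array(self) -> np.ndarray:
        """Pack as ``[alpha, alpha_hab, beta, w]`` (the optimizer's order)."""
        return np.array([self.alpha, self.alpha_hab, self.beta, self.w])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "ModelParams":
        a, ah, b, w = (float(v) for v in x)
        return cls(alpha=a, alpha_hab=ah, beta=b, w=w)


@dataclass
class LatentState:
    """Per-side latent values carried across trials.

    ``q``, ``h`` and ``d`` are ``(left, right)`` pairs.  ``d`` is stored
    explicitly: it is initialized at 0.5 for the first choice and
    recomputed as ``w*h + (1 - w)*q`` after every update.
    """

    q: tuple
    h: tuple
    d: tuple


@dataclass
class TrialUpdate:
    """Bookkeeping emitted by a single value update."""

    reward_chosen: float
    reward_unchosen: Optional[float]
    delta_chosen: float
    delta_unchosen: Optional[float]
    log_prob_choice: float
    updated: bool = True


def initial_state(params: ModelParams) -> LatentState:
    """State before the first trial: Q and D at 0.5, H at 0 on both sides."""
    return LatentState(q=(0.5, 0.5), h=(0.0, 0.0), d=(0.5, 0.5))


def action_probability(state: LatentState, params: ModelParams, side) -> float:
    """Softmax probability of choosing ``side`` given the current D values.

    ``P(a) = 1 / (1 + exp((D(b) - D(a)) * beta))`` where ``b`` is the
    other side.  ``beta = 0`` yields 0.5 regardless of the values.
    """
    a = side_code(side)
    b = 1 - a
    x = (state.d[b] - state.d[a]) * params.beta
    # guard against overflow at extreme beta
    if x > 700.0:
        return 1e-300
    return 1.0 / (1.0 + math.exp(x))


def update_values(
    state: LatentState,
    chosen_side,
    feedback: str,
    params: ModelParams,
    kind: str,
) -> tuple:
    """Apply one trial's learning updates; returns ``(new_state, TrialUpdate)``.

    Feedback is coded ``R = 1`` for avoidance and ``R = 0`` for approach.
    The chosen Q-value moves toward R by ``alpha``; under the
    counterfactual kind the unchosen Q-value moves toward ``1 - R`` with
    the same rate, otherwise it is left untouched.  Habit values update
    on every valid trial for both sides: the chosen H toward 1 and the
    unchosen H toward 0, both at rate ``alpha_hab``.  D is recomputed
    last.  ``feedback == "none"`` is a no-op flagged in the update.
    """
    if kind not in RL_KINDS:
        raise ValueError(f"kind must be one of {RL_KINDS}, got {kind!r}")
    c = side_code(chosen_side)
    log_p = math.log(max(action_probability(state, params, c), 1e-300))
    if feedback == "none":
        return state, TrialUpdate(
            reward_chosen=math.nan,
            reward_unchosen=None,
            delta_chosen=math.nan,
            delta_unchosen=None,
            log_prob_choice=log_p,
            updated=False,
        )
    if feedback not in ("avoidance", "approach"):
        raise ValueError(f"unknown feedback {feedback!r}")
    u = 1 - c
    r_c = 1.0 if feedback == "avoidance" else 0.0

    q = list(state.q)
    h = list(state.h)
    delta_c = r_c - q[c]
    q[c] = q[c] + params.alpha * delta_c
    r_u = None
    delta_u = None
    if kind == "counterfactual":
        r_u = 1.0 - r_c
        delta_u = r_u - q[u]
        q[u] = q[u] + params.alpha * delta_u
    h[c] = h[c] + params.alpha_hab * (1.0 - h[c])
    h[u] = h[u] + params.alpha_hab * (0.0 - h[u])
    d = tuple(params.w * h[i] + (1.0 - params.w) * q[i] for i in (0, 1))
    new_state = LatentState(q=tuple(q), h=tuple(h), d=d)
    return new_state, TrialUpdate(
        reward_chosen=r_c,
        reward_unchosen=r_u,
        delta_chosen=delta_c,
        delta_unchosen=delta_u,
        log_prob_choice=log_p,
    )


def _dataset_arrays(dataset):
    """Extract ``(choices, rewards, valid)`` int/bool arrays from a dataset.

    Accepts a ParticipantDataset (duck-typed via ``.arrays()``) or a
    pandas DataFrame with ``choice_side``, ``feedback`` and ``valid``
    columns.  Invalid trials carry choice/reward code -1.
    """
    if hasattr(dataset, "arrays"):
        return dataset.arrays()
    df = dataset
    valid = df["valid"].to_numpy(dtype=bool)
    choice = np.full(len(df), -1, dtype=np.int64)
    ch = df["choice_side"].to_numpy(dtype=object)
    choice[valid] = [side_code(s) for s in ch[valid]]
    reward = np.full(len(df), -1, dtype=np.int64)
    fb = df["feedback"].to_numpy(dtype=object)
    reward[valid] = [1 if f == "avoidance" else 0 for f in fb[valid]]
    return choice, reward, valid


def sequence_log_likelihood(dataset, params: ModelParams, kind: str):
    """Log-likelihood of a subject's choice sequence under one model.

    Iterates the latent state over trials in order; invalid trials
    contribute no likelihood term and trigger no update.  Returns
    ``(log_likelihood, per_trial_probabilities)`` where the probability
    array is NaN on invalid trials.  Per-trial log terms are floored at
    ``LOG_FLOOR``.
    """
    if kind not in RL_KINDS:
        raise ValueError(f"kind must be one of {RL_KINDS}, got {kind!r}")
    choices, rewards, valid = _dataset_arrays(dataset)
    n = len(choices)
    probs = np.full(n, np.nan)
    if not valid.any():
        warnings.warn("dataset has no valid trials; log-likelihood is 0")
        return 0.0, probs

    alpha = params.alpha
    ahab = params.alpha_hab
    beta = params.beta
    w = params.w
    cf = kind == "counterfactual"
    ql = qr = 0.5
    hl = hr = 0.0
    dl = dr = 0.5
    ll = 0.0
    exp = math.exp
    log = math.log
    for i in range(n):
        if not valid[i]:
            continue
        c = choices[i]
        x = (dr - dl) * beta if c == LEFT else (dl - dr) * beta
        p = 0.0 if x > 700.0 else 1.0 / (1.0 + exp(x))
        probs[i] = p
        ll += log(p) if p > 1e-12 else LOG_FLOOR
        r = float(rewards[i])
        if c == LEFT:
            ql += alpha * (r - ql)
            if cf:
                qr += alpha * ((1.0 - r) - qr)
            hl += ahab * (1.0 - hl)
            hr += ahab * (0.0 - hr)
        else:
            qr += alpha * (r - qr)
            if cf:
                ql += alpha * ((1.0 - r) - ql)
            hr += ahab * (1.0 - hr)
            hl += ahab * (0.0 - hl)
        dl = w * hl + (1.0 - w) * ql
        dr = w * hr + (1.0 - w) * qr
    return ll, probs


def random_log_likelihood(dataset) -> float:
    """Chance-baseline log-likelihood: ``n_valid * ln(0.5)``."""
    _, _, valid = _dataset_arrays(dataset)
    return int(valid.sum()) * math.log(0.5)


def simulate_rl_choices(
    optimal_codes: np.ndarray,
    params: ModelParams,
    kind: str,
    rng: np.random.Generator,
    p_avoid_optimal: float = 0.8,
    p_avoid_nonoptimal: float = 0.2,
    respond_mask: Optional[np.ndarray] = None,
):
    """Generative twin of :func:`sequence_log_likelihood`.

    Rolls an RL agent forward over a schedule given as per-trial optimal
    side codes, sampling choices from the softmax policy and feedback
    from the task contingencies.  ``respond_mask`` marks trials on which
    the agent responds (missed trials yield code -1 and no update).
    Returns ``(choices, rewards)`` int arrays (-1 where no response).
    """
    if kind not in RL_KINDS:
        raise ValueError(f"kind must be one of {RL_KINDS}, got {kind!r}")
    n = len(optimal_codes)
    choices = np.full(n, -1, dtype=np.int64)
    rewards = np.full(n, -1, dtype=np.int64)
    u_choice = rng.random(n)
    u_feedback = rng.random(n)
    alpha, ahab, beta, w = params.alpha, params.alpha_hab, params.beta, params.w
    cf = kind == "counterfactual"
    ql = qr = 0.5
    hl = hr = 0.0
    dl = dr = 0.5
    exp = math.exp
    for i in range(n):
        if respond_mask is not None and not respond_mask[i]:
            continue
        x = (dr - dl) * beta
        p_left = 0.0 if x > 700.0 else 1.0 / (1.0 + exp(x))
        c = LEFT if u_choice[i] < p_left else RIGHT
        p_av = p_avoid_optimal if c == optimal_codes[i] else p_avoid_nonoptimal
        r = 1 if u_feedback[i] < p_av else 0
        choices[i] = c
        rewards[i] = r
        rf = float(r)
        if c == LEFT:
            ql += alpha * (rf - ql)
            if cf:
                qr += alpha * ((1.0 - rf) - qr)
            hl += ahab * (1.0 - hl)
            hr += ahab * (0.0 - hr)
        else:
            qr += alpha * (rf - qr)
            if cf:
                ql += alpha * ((1.0 - rf) - ql)
            hr += ahab * (1.0 - hr)
            hl += ahab * (0.0 - hl)
        dl = w * hl + (1.0 - w) * ql
        dr = w * hr + (1.0 - w) * qr
    return choices, rewards
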