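"""Probabilistic-reversal avoidance task: schedules, agents, synthetic cohorts.

The simulated environment mirrors a two-choice social-avoidance task:
on every trial one response side carries an 80% probability of an
avoidance outcome (ending up far from an angry individual) and the
other side the complementary 20%.  The advantageous side reverses at
block boundaries; a session comprises 12 blocks (three each of 20, 24,
26 and 30 trials, 300 trials in total) presented in random order, so
contingencies reverse every 25 trials on average.

Agents range from a chance baseline to the RL learners defined in
:mod:`avoidrl.models`; cohorts can be generated from mixtures of agent
profiles, alongside subjective-evaluation rating tables and degraded
datasets (missed and anticipated responses) for exclusion testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import (
    LEFT,
    RIGHT,
    SIDE_NAMES,
    ModelParams,
    side_code,
    simulate_rl_choices,
)

__all__ = [
    "TaskConfig",
    "BlockSchedule",
    "AgentSpec",
    "ParticipantDataset",
    "RatingModelSpec",
    "PopulationSpec",
    "DEFAULT_POPULATION",
    "build_block_schedule",
    "simulate_participant",
    "generate_cohort",
    "sample_parameters",
    "generate_ratings",
    "degrade_dataset",
]

DEFAULT_BLOCK_LENGTHS = (20, 20, 20, 24, 24, 24, 26, 26, 26, 30, 30, 30)

AGENT_KINDS = ("random", "rl_simple", "rl_counterfactual", "oracle", "fixed_side")

# Response-time generator (lognormal, ms). RTs only exist to exercise the
# exclusion filters; no model ever reads them.
RT_MEDIAN_MS = 450.0
RT_SIGMA = 0.3
RT_MAX_MS = 1500.0
ANTICIPATION_CUTOFF_MS = 100.0


@dataclass(frozen=True)
class TaskConfig:
    """Design of one session of the reversal task."""

    block_lengths: Tuple[int, ...] = DEFAULT_BLOCK_LENGTHS
    p_avoid_optimal: float = 0.8
    p_avoid_nonoptimal: float = 0.2
    miss_probability: float = 0.0
    anticipation_probability: float = 0.0

    def __post_init__(self):
        if len(self.block_lengths) == 0:
            raise ValueError("block_lengths must be nonempty")
        if any(int(b) <= 0 for b in self.block_lengths):
            raise ValueError("block lengths must be positive")
        for name in ("p_avoid_optimal", "p_avoid_nonoptimal",
                     "miss_probability", "anticipation_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def n_trials_total(self) -> int:
        return int(sum(self.block_lengths))


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered block lengths and which side is optimal in each block."""

    lengths: Tuple[int, ...]
    optimal_sides: Tuple[str, ...]

    def __post_init__(self):
        if len(self.lengths) != len(self.optimal_sides):
            raise ValueError("lengths and optimal_sides must align")

    @property
    def n_trials(self) -> int:
        return int(sum(self.lengths))

    @property
    def n_blocks(self) -> int:
        return len(self.lengths)

    def to_frame(self) -> pd.DataFrame:
        """Per-trial expansion with 0-based trial/block/within-block indices."""
        rows = []
        t = 0
        for b, (length, side) in enumerate(zip(self.lengths, self.optimal_sides)):
            for j in range(length):
                rows.append((t, b, j, side))
                t += 1
        return pd.DataFrame(
            rows,
            columns=["trial_index", "block_index", "within_block_index", "optimal_side"],
        )

    def optimal_codes(self) -> np.ndarray:
        """Per-trial optimal side as 0 (left) / 1 (right)."""
        return np.repeat(
            [side_code(s) for s in self.optimal_sides],
            np.asarray(self.lengths, dtype=int),
        )


@dataclass(frozen=True)
class AgentSpec:
    """Which decision policy generates a simulated participant's choices."""

    kind: str
    params: Optional[ModelParams] = None
    side: Optional[str] = None

    def __post_init__(self):
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"agent kind must be one of {AGENT_KINDS}, got {self.kind!r}")
        if self.kind.startswith("rl_") and self.params is None:
            raise ValueError(f"agent kind {self.kind!r} requires params")
        if not self.kind.startswith("rl_") and self.params is not None:
            raise ValueError(f"agent kind {self.kind!r} takes no params")
        if self.kind == "fixed_side":
            if self.side not in SIDE_NAMES:
                raise ValueError("fixed_side agent requires side 'left' or 'right'")


TRIAL_COLUMNS = [
    "trial_index",
    "block_index",
    "within_block_index",
    "optimal_side",
    "choice_side",
    "valid",
    "rt_ms",
    "feedback",
]


@dataclass
class ParticipantDataset:
    """Ordered trial records for one subject.

    ``trials`` holds one row per trial with columns ``trial_index``,
    ``block_index``, ``within_block_index``, ``optimal_side``,
    ``choice_side`` (empty string when missing), ``valid``, ``rt_ms``
    and ``feedback`` (``"avoidance"``/``"approach"``/``"none"``).
    ``feedback == "none"`` iff ``valid`` is False.
    """

    subject_id: str
    trials: pd.DataFrame
    strategy_group: Optional[str] = None
    _arrays: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trials frame missing columns: {missing}")
        ti = self.trials["trial_index"].to_numpy()
        if len(ti) and not np.array_equal(ti, np.arange(ti[0], ti[0] + len(ti))):
            raise ValueError("trial_index must be strictly increasing and gap-free")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_valid(self) -> int:
        return int(self.trials["valid"].sum())

    def arrays(self):
        """Cached ``(choices, rewards, valid)`` arrays for the likelihood loop."""
        if self._arrays is None:
            df = self.trials
            valid = df["valid"].to_numpy(dtype=bool)
            choice = np.full(len(df), -1, dtype=np.int64)
            reward = np.full(len(df), -1, dtype=np.int64)
            ch = df["choice_side"].to_numpy(dtype=object)
            fb = df["feedback"].to_numpy(dtype=object)
            for i in np.flatnonzero(valid):
                choice[i] = side_code(ch[i])
                reward[i] = 1 if fb[i] == "avoidance" else 0
            object.__setattr__(self, "_arrays", (choice, reward, valid))
        return self._arrays

    def optimal_codes(self) -> np.ndarray:
        return np.array([side_code(s) for s in self.trials["optimal_side"]])


def build_block_schedule(config: TaskConfig, seed: int) -> BlockSchedule:
    """Randomly order the configured block lengths and assign optimal sides.

    The block-length multiset is permuted uniformly; the first block's
    optimal side is drawn uniformly and sides alternate at every block
    boundary thereafter (the contingency reversal).  Identical seeds
    give identical schedules.
    """
    rng = np.random.default_rng(seed)
    lengths = tuple(int(v) for v in rng.permutation(np.asarray(config.block_lengths)))
    first = int(rng.integers(2))
    sides = tuple(SIDE_NAMES[(first + i) % 2] for i in range(len(lengths)))
    return BlockSchedule(lengths=lengths, optimal_sides=sides)


def _draw_rts(rng: np.random.Generator, n: int) -> np.ndarray:
    rt = rng.lognormal(mean=math.log(RT_MEDIAN_MS), sigma=RT_SIGMA, size=n)
    return np.clip(rt, ANTICIPATION_CUTOFF_MS + 1.0, RT_MAX_MS)


def simulate_participant(
    agent: AgentSpec,
    schedule: BlockSchedule,
    config: TaskConfig,
    seed: int,
    subject_id: str = "sim",
    strategy_group: Optional[str] = None,
) -> ParticipantDataset:
    """Simulate one session of the task for one agent.

    Feedback is Bernoulli(``p_avoid_optimal``) when the currently
    optimal side is chosen and Bernoulli(``p_avoid_nonoptimal``)
    otherwise.  Trials missed under ``config.miss_probability`` are
    invalid: no choice, no feedback, no RL update.  Anticipations
    (responses faster than 100 ms) occur with
    ``config.anticipation_probability`` and only affect the recorded RT.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_trials
    if n != config.n_trials_total:
        raise ValueError("schedule is inconsistent with config block lengths")
    optimal = schedule.optimal_codes()
    respond = rng.random(n) >= config.miss_probability

    if agent.kind.startswith("rl_"):
        kind = agent.kind.removeprefix("rl_")
        choices, rewards = simulate_rl_choices(
            optimal, agent.params, kind, rng,
            p_avoid_optimal=config.p_avoid_optimal,
            p_avoid_nonoptimal=config.p_avoid_nonoptimal,
            respond_mask=respond,
        )
    else:
        choices = np.full(n, -1, dtype=np.int64)
        rewards = np.full(n, -1, dtype=np.int64)
        u_fb = rng.random(n)
        if agent.kind == "random":
            drawn = rng.integers(0, 2, size=n)
        elif agent.kind == "oracle":
            drawn = optimal.copy()
        elif agent.kind == "fixed_side":
            drawn = np.full(n, side_code(agent.side), dtype=np.int64)
        else:  # pragma: no cover - exhaustive over AGENT_KINDS
            raise ValueError(f"unhandled agent kind {agent.kind!r}")
        for i in range(n):
            if not respond[i]:
                continue
            c = int(drawn[i])
            p_av = (
                config.p_avoid_optimal if c == optimal[i] else config.p_avoid_nonoptimal
            )
            choices[i] = c
            rewards[i] = 1 if u_fb[i] < p_av else 0

    rt = _draw_rts(rng, n)
    anticipate = rng.random(n) < config.anticipation_probability
    rt[anticipate] = rng.uniform(20.0, ANTICIPATION_CUTOFF_MS - 1.0, size=int(anticipate.sum()))
    rt[~respond] = np.nan

    frame = schedule.to_frame()
    valid = respond
    frame["choice_side"] = [
        SIDE_NAMES[c] if c >= 0 else "" for c in choices
    ]
    frame["valid"] = valid
    frame["rt_ms"] = rt
    frame["feedback"] = [
        ("avoidance" if r == 1 else "approach") if r >= 0 else "none" for r in rewards
    ]
    return ParticipantDataset(
        subject_id=subject_id, trials=frame, strategy_group=strategy_group
    )


def sample_parameters(seed: int, rng: Optional[np.random.Generator] = None) -> ModelParams:
    """Draw model parameters from the fitting priors.

    ``beta ~ Gamma(k=1.2, theta=5)``; ``alpha``, ``alpha_hab`` and ``w``
    each ``~ Beta(1.1, 1.1)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    beta = float(rng.gamma(shape=1.2, scale=5.0))
    alpha, alpha_hab, w = (float(v) for v in rng.beta(1.1, 1.1, size=3))
    return ModelParams(alpha=alpha, alpha_hab=alpha_hab, beta=beta, w=w)


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture of agent profiles defining a simulated cohort."""

    groups: Dict[str, AgentSpec]
    weights: Dict[str, float]

    def __post_init__(self):
        if set(self.groups) != set(self.weights):
            raise ValueError("groups and weights must share keys")
        total = sum(self.weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")


#: Default cohort: counterfactual learners at the two strategy groups'
#: median parameter profiles, mixed 154:60.
DEFAULT_POPULATION = PopulationSpec(
    groups={
        "non_explicit": AgentSpec(
            kind="rl_counterfactual",
            params=ModelParams(alpha=0.50, alpha_hab=0.084, beta=1.50, w=0.78),
        ),
        "explicit": AgentSpec(
            kind="rl_counterfactual",
            params=ModelParams(alpha=0.74, alpha_hab=0.06, beta=1.84, w=0.63),
        ),
    },
    weights={"non_explicit": 154 / 214, "explicit": 60 / 214},
)


def generate_cohort(
    n_subjects: int,
    population: Optional[PopulationSpec] = None,
    config: Optional[TaskConfig] = None,
    seed: int = 0,
) -> List[ParticipantDataset]:
    """Simulate ``n_subjects`` independent sessions from a population mixture.

    Each subject receives an independently randomized block schedule and
    an agent drawn from the population's group weights; the group label
    is recorded as ``strategy_group``.
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    population = population or DEFAULT_POPULATION
    config = config or TaskConfig()
    ss = np.random.SeedSequence(seed)
    group_rng = np.random.default_rng(ss.spawn(1)[0])
    names = sorted(population.groups)
    probs = np.array([population.weights[g] for g in names])
    cohort = []
    for i, child in enumerate(ss.spawn(n_subjects + 1)[1:]):
        g = names[int(group_rng.choice(len(names), p=probs))]
        sched_seed, sim_seed = (int(s) for s in child.generate_state(2) % (2**31))
        schedule = build_block_schedule(config, sched_seed)
        cohort.append(
            simulate_participant(
                population.groups[g],
                schedule,
                config,
                sim_seed,
                subject_id=f"S{i:03d}",
                strategy_group=g,
            )
        )
    return cohort


@dataclass(frozen=True)
class RatingModelSpec:
    """Generator for the subjective-evaluation rating table.

    Each subject rates all 40 feedback scenarios (10 identity pairs x 2
    anger positions x 2 seat positions; 20 approach, 20 avoidance) on a
    0-100 scale.  Ratings follow
    ``approach_mean + avoidance_effect*[avoidance] + subject intercept
    + residual noise``, truncated to the scale.  The default condition
    means reproduce an approach mean of 25.34 and an avoidance increase
    of 37.05; the dispersion terms are generator choices kept small
    enough that truncation barely biases the configured means.
    """

    approach_mean: float = 25.34
    avoidance_effect: float = 37.05
    subject_sd: float = 8.0
    residual_sd: float = 6.0
    lower: float = 0.0
    upper: float = 100.0

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("truncation bounds must satisfy lower < upper")
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")


N_RATING_PAIRS = 10


def generate_ratings(
    cohort: Sequence[ParticipantDataset],
    spec: Optional[RatingModelSpec] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Rating table: 40 scenario instances per subject.

    Columns: ``subject_id``, ``pair_id`` (0-9), ``anger_position`` and
    ``self_position`` (left/right), ``scenario`` (avoidance when the
    rated seat is on the opposite side from the angry individual) and
    ``rating``.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    spec = spec or RatingModelSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for ds in cohort:
        intercept = rng.normal(0.0, spec.subject_sd) if spec.subject_sd > 0 else 0.0
        for pair in range(N_RATING_PAIRS):
            for anger_pos in SIDE_NAMES:
                for self_pos in SIDE_NAMES:
                    scenario = "approach" if anger_pos == self_pos else "avoidance"
                    mu = spec.approach_mean + intercept
                    if scenario == "avoidance":
                        mu += spec.avoidance_effect
                    noise = rng.normal(0.0, spec.residual_sd) if spec.residual_sd > 0 else 0.0
                    rating = min(max(mu + noise, spec.lower), spec.upper)
                    rows.append(
                        (ds.subject_id, pair, anger_pos, self_pos, scenario, rating)
                    )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "pair_id", "anger_position", "self_position",
                 "scenario", "rating"],
    )


def degrade_dataset(
    dataset: ParticipantDataset,
    miss_probability: float,
    anticipation_probability: float,
    seed: int,
) -> ParticipantDataset:
    """Inject missed and anticipated responses into an existing dataset.

    Selected trials become invalid (choice removed, feedback ``none``,
    RT missing) or receive an RT below the 100 ms anticipation cutoff;
    trial order is preserved.  Zero rates return an identical copy.
    """
    for name, p in (("miss_probability", miss_probability),
                    ("anticipation_probability", anticipation_probability)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    df = dataset.trials.copy()
    n = len(df)
    miss = rng.random(n) < miss_probability
    anticipate = (rng.random(n) < anticipation_probability) & ~miss
    df.loc[miss, "choice_side"] = ""
    df.loc[miss, "valid"] = False
    df.loc[miss, "feedback"] = "none"
    df.loc[miss, "rt_ms"] = np.nan
    if anticipate.any():
        # only valid responses can be anticipations
        anticipate &= df["valid"].to_numpy(dtype=bool)
        df.loc[anticipate, "rt_ms"] = rng.uniform(
            20.0, ANTICIPATION_CUTOFF_MS - 1.0, size=int(anticipate.sum())
        )
    return ParticipantDataset(
        subject_id=dataset.subject_id,
        trials=df,
        strategy_group=dataset.strategy_group,
    )
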