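import numpy as np
import pandas as pd
import pytest

from avoidrl import (
    AgentSpec,
    ModelParams,
    ParticipantDataset,
    TaskConfig,
    build_block_schedule,
    generate_cohort,
    simulate_participant,
)


def make_dataset(choices, feedbacks, valid=None, optimal=None, subject_id="T"):
    """Hand-build a ParticipantDataset from per-trial choice/feedback lists.

    ``choices`` are 'left'/'right' (ignored where invalid); ``feedbacks``
    'avoidance'/'approach'.  Invalid trials get empty choice and 'none'.
    """
    n = len(choices)
    if valid is None:
        valid = [True] * n
    if optimal is None:
        optimal = ["left"] * n
    df = pd.DataFrame({
        "trial_index": range(n),
        "block_index": 0,
        "within_block_index": range(n),
        "optimal_side": optimal,
        "choice_side": [c if v else "" for c, v in zip(choices, valid)],
        "valid": valid,
        "rt_ms": [500.0 if v else np.nan for v in valid],
        "feedback": [f if v else "none" for f, v in zip(feedbacks, valid)],
    })
    return ParticipantDataset(subject_id=subject_id, trials=df)


def random_dataset(rng, n_trials=10):
    """A short random choice/feedback sequence with occasional invalid trials."""
    choices = [("left", "right")[rng.integers(2)] for _ in range(n_trials)]
    feedbacks = [("approach", "avoidance")[rng.integers(2)] for _ in range(n_trials)]
    valid = [bool(rng.random() > 0.15) for _ in range(n_trials)]
    return make_dataset(choices, feedbacks, valid)


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def schedule(default_config):
    return build_block_schedule(default_config, seed=1)


@pytest.fixture(scope="session")
def learner_params():
    return ModelParams(alpha=0.6, alpha_hab=0.1, beta=3.0, w=0.3)


@pytest.fixture(scope="session")
def learner_dataset(schedule, default_config, learner_params):
    agent = AgentSpec(kind="rl_counterfactual", params=learner_params)
    return simulate_participant(agent, schedule, default_config, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(10, seed=123)
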