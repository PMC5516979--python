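import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from twostep.agents import AgentSpec, CONTROL_PRESET, simulate_session
from twostep.task import TRIAL_COLUMNS, default_task_config, trials_to_frame


@pytest.fixture(scope="session")
def config():
    return default_task_config()


@pytest.fixture(scope="session")
def control_session(config):
    """One seeded 240-trial session from a control-preset hybrid agent."""
    recs = simulate_session(
        AgentSpec(kind="hybrid", params=CONTROL_PRESET), config, seed=42
    )
    return recs


@pytest.fixture(scope="session")
def control_session_frame(control_session):
    return trials_to_frame(control_session)


def make_trial_frame(choices1, transitions, outcomes, subject_id="s01", condition="control"):
    """Hand-built single-subject trial log; stage-2 fields are filler."""
    n = len(choices1)
    return pd.DataFrame(
        {
            "subject_id": [subject_id] * n,
            "condition": [condition] * n,
            "trial": np.arange(1, n + 1),
            "block": np.ones(n, dtype=int),
            "choice1": list(choices1),
            "transition": list(transitions),
            "state2": ["s2"] * n,
            "choice2": ["opt1"] * n,
            "outcome": list(outcomes),
        }
    )[list(TRIAL_COLUMNS)]
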