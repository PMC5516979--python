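"""Two-stage Markov reversal task: structure, sampling, and trial-log I/O.

The task is a two-stage decision problem. A first-stage choice between two
actions (``a1``, ``a2``) leads probabilistically to one of two second-stage
states (``s2``, ``s3``): each action is strongly (70%) linked to one state,
and that mapping is fixed for the whole session. In the second stage the
subject picks one of two options whose reward probabilities follow a
block-wise schedule with uncued reversals: in block 1 both states offer a
0.6/0.2 pair (neither first-stage action dominates), and from block 2 on a
single "favored" state offers 0.8/0.2 while the other state's options both
pay 0.2, the favored state alternating between blocks. Rewards are 100
points or nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

ACTIONS = ("a1", "a2")
STATES = ("s2", "s3")
OPTIONS = ("opt1", "opt2")

#: Fixed header of the trial-log CSV, one row per trial.
TRIAL_COLUMNS = (
    "subject_id",
    "condition",
    "trial",
    "block",
    "choice1",
    "transition",
    "state2",
    "choice2",
    "outcome",
)


@dataclass(frozen=True)
class TaskConfig:
    """Complete specification of the two-stage reversal task.

    Parameters
    ----------
    n_blocks, trials_per_block
        Block structure; the session has ``n_blocks * trials_per_block``
        trials with no break or cue at block boundaries.
    common_transition_prob
        Probability that a first-stage action leads to its mapped
        second-stage state.  Must exceed 0.5 so that "common" is meaningful.
    reward_schedule
        Array-like of shape ``(n_blocks, 2 states, 2 options)`` holding the
        reward probability of each second-stage option in each block.
    reward_magnitude
        Points delivered on a rewarded trial (otherwise 0).
    action_state_map
        Which first-stage action is strongly linked to which second-stage
        state; a bijection, fixed for the session.
    """

    n_blocks: int = 6
    trials_per_block: int = 40
    common_transition_prob: float = 0.7
    reward_schedule: tuple = ()
    reward_magnitude: int = 100
    action_state_map: Mapping[str, str] = field(
        default_factory=lambda: {"a1": "s2", "a2": "s3"}
    )

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be positive")
        if not 0.5 < self.common_transition_prob <= 1.0:
            raise ValueError(
                "common_transition_prob must lie in (0.5, 1]; got "
                f"{self.common_transition_prob}"
            )
        sched = np.asarray(self.reward_schedule, dtype=float)
        if sched.shape != (self.n_blocks, 2, 2):
            raise ValueError(
                f"reward_schedule must have shape ({self.n_blocks}, 2, 2); "
                f"got {sched.shape}"
            )
        if np.any(sched < 0) or np.any(sched > 1):
            raise ValueError("reward probabilities must lie in [0, 1]")
        object.__setattr__(
            self,
            "reward_schedule",
            tuple(tuple(tuple(float(p) for p in s) for s in b) for b in sched),
        )
        if sorted(self.action_state_map) != list(ACTIONS) or sorted(
            self.action_state_map.values()
        ) != list(STATES):
            raise ValueError("action_state_map must map {a1, a2} onto {s2, s3}")
        object.__setattr__(self, "action_state_map", dict(self.action_state_map))

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def schedule_array(self) -> np.ndarray:
        return np.asarray(self.reward_schedule, dtype=float)

    def state_of(self, action: str) -> str:
        """Second-stage state strongly linked to a first-stage action."""
        return self.action_state_map[action]

    def action_of(self, state: str) -> str:
        """First-stage action strongly linked to a second-stage state."""
        inv = {s: a for a, s in self.action_state_map.items()}
        return inv[state]

    def reward_prob(self, state2: str, choice2: str, block: int) -> float:
        if not 1 <= block <= self.n_blocks:
            raise ValueError(f"block {block} outside schedule 1..{self.n_blocks}")
        return self.schedule_array[
            block - 1, STATES.index(state2), OPTIONS.index(choice2)
        ]

    def block_of(self, trial_index: int) -> int:
        """1-based block of a 1-based trial index."""
        return (trial_index - 1) // self.trials_per_block + 1

    def favored_state(self, block: int) -> str | None:
        """State holding the high-probability option, or None if symmetric.

        In block 1 of the default schedule both states offer the same pair,
        so neither first-stage action is advantageous.
        """
        probs = self.schedule_array[block - 1]
        best = probs.max(axis=1)
        if best[0] == best[1]:
            return None
        return STATES[int(np.argmax(best))]

    def advantageous_action(self, block: int) -> str | None:
        """First-stage action linked to the favored state, if one exists."""
        state = self.favored_state(block)
        return None if state is None else self.action_of(state)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_blocks": self.n_blocks,
            "trials_per_block": self.trials_per_block,
            "common_transition_prob": self.common_transition_prob,
            "reward_schedule": [[list(s) for s in b] for b in self.reward_schedule],
            "reward_magnitude": self.reward_magnitude,
            "action_state_map": dict(self.action_state_map),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TaskConfig":
        return cls(**dict(d))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "TaskConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class TrialRecord:
    """One trial's choices, transition type, state, and outcome."""

    subject_id: str
    condition: str
    trial: int
    block: int
    choice1: str
    transition: str
    state2: str
    choice2: str
    outcome: int

    def __post_init__(self) -> None:
        if self.choice1 not in ACTIONS:
            raise ValueError(f"choice1 must be one of {ACTIONS}")
        if self.state2 not in STATES:
            raise ValueError(f"state2 must be one of {STATES}")
        if self.choice2 not in OPTIONS:
            raise ValueError(f"choice2 must be one of {OPTIONS}")
        if self.transition not in ("common", "rare"):
            raise ValueError("transition must be 'common' or 'rare'")


#: The block-wise reward schedule of the default task.  Rows are blocks,
#: then states (s2, s3), then options.  Option 1 carries the high
#: probability in the favored state; the within-state assignment is an
#: arbitrary but fixed convention.
DEFAULT_SCHEDULE = (
    ((0.6, 0.2), (0.6, 0.2)),  # block 1: symmetric, no advantageous action
    ((0.8, 0.2), (0.2, 0.2)),  # block 2: s2 favored
    ((0.2, 0.2), (0.8, 0.2)),  # block 3: s3 favored
    ((0.8, 0.2), (0.2, 0.2)),  # block 4: s2 favored
    ((0.2, 0.2), (0.8, 0.2)),  # block 5: s3 favored
    ((0.8, 0.2), (0.2, 0.2)),  # block 6: s2 favored
)


def default_task_config() -> TaskConfig:
    """The full task: six blocks of 40 trials, 240 trials in total."""
    return TaskConfig(
        n_blocks=6,
        trials_per_block=40,
        common_transition_prob=0.7,
        reward_schedule=DEFAULT_SCHEDULE,
        reward_magnitude=100,
    )


def practice_task_config() -> TaskConfig:
    """The practice session: the same schedule at five trials per block."""
    return TaskConfig(
        n_blocks=6,
        trials_per_block=5,
        common_transition_prob=0.7,
        reward_schedule=DEFAULT_SCHEDULE,
        reward_magnitude=100,
    )


def sample_transition(
    choice1: str, config: TaskConfig, rng: np.random.Generator
) -> tuple[str, str]:
    """Sample the second-stage state reached by a first-stage action.

    Returns ``(state2, transition)`` where transition is ``"common"`` when
    the mapped state was reached and ``"rare"`` otherwise.
    """
    if choice1 not in ACTIONS:
        raise ValueError(f"choice1 must be one of {ACTIONS}; got {choice1!r}")
    mapped = config.state_of(choice1)
    other = STATES[1 - STATES.index(mapped)]
    if rng.random() < config.common_transition_prob:
        return mapped, "common"
    return other, "rare"


def sample_outcome(
    state2: str, choice2: str, block: int, config: TaskConfig, rng: np.random.Generator
) -> int:
    """Sample the trial outcome (0 or ``reward_magnitude`` points)."""
    p = config.reward_prob(state2, choice2, block)
    return config.reward_magnitude if rng.random() < p else 0


# -- trial-log I/O --------------------------------------------------------


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Stack TrialRecords into a trial-log DataFrame with the fixed header."""
    df = pd.DataFrame([vars(t) for t in trials])
    return df.loc[:, list(TRIAL_COLUMNS)]


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            subject_id=str(r.subject_id),
            condition=str(r.condition),
            trial=int(r.trial),
            block=int(r.block),
            choice1=str(r.choice1),
            transition=str(r.transition),
            state2=str(r.state2),
            choice2=str(r.choice2),
            outcome=int(r.outcome),
        )
        for r in df.itertuples(index=False)
    ]


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    df.loc[:, list(TRIAL_COLUMNS)].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "condition": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    return df.loc[:, list(TRIAL_COLUMNS)]
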