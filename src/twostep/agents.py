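"""Generative agents and synthetic cohorts for the two-stage reversal task.

Because raw trial-level data from the original study are not available, all
analyses in this package run on synthetic cohorts.  The hybrid agent is the
generative counterpart of the fitted model: it chooses first-stage actions
from the softmax over the decaying hybrid values and updates them with the
same attribution rules the likelihood assumes.  Condition presets are the
median best-fitting parameters reported for the control and stress groups,
so a simulated cohort reproduces the statistical structure the downstream
analyses (stay-probability ANOVA, group comparisons, parameter recovery)
are designed to detect.

Reference agents (pure model-free, pure model-based, random, perseverator)
exist to pin down the qualitative stay-shift signatures and the exclusion
rule: a pure model-free agent stays after reward regardless of transition
type, while a pure model-based agent's staying depends on the reward x
transition conjunction.

The first-stage model is agnostic about second-stage behavior (second-stage
choices never enter the likelihood), but the simulator still needs a
second-stage policy to generate outcome streams.  Agents use a per-state
Rescorla-Wagner update on the binarized outcome with a softmax readout --
the minimal standard assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams, PARAM_NAMES, ValueState, choice_prob, update_values
from .task import (
    ACTIONS,
    OPTIONS,
    STATES,
    TaskConfig,
    TrialRecord,
    default_task_config,
    sample_outcome,
    sample_transition,
    trials_to_frame,
)

AGENT_KINDS = ("hybrid", "pure_model_free", "pure_model_based", "random", "perseverator")

#: Median best-fitting parameters per condition (the simulation presets).
CONTROL_PRESET = ModelParams(
    gamma=0.47, d_plus_mf=1.09, d_plus_mb=0.33, d_minus_mf=0.48, d_minus_mb=-0.14
)
STRESS_PRESET = ModelParams(
    gamma=0.73, d_plus_mf=0.50, d_plus_mb=-0.04, d_minus_mf=0.02, d_minus_mb=-0.01
)
CONDITION_PRESETS = {"control": CONTROL_PRESET, "stress": STRESS_PRESET}

#: Between-subject dispersion defaults, one scale per parameter.  Derived
#: from the reported interquartile ranges of the fitted parameters in the
#: two conditions (sigma ~ mean IQR / 1.349, the normal-distribution
#: conversion), so that a jittered cohort spreads like the fitted one.
DEFAULT_JITTER = {
    "gamma": 0.28,
    "d_plus_mf": 0.74,
    "d_plus_mb": 0.41,
    "d_minus_mf": 0.33,
    "d_minus_mb": 0.26,
}

#: Canonical parameters for the reference agents: symmetric win-stay /
#: lose-shift increments confined to one system.
PURE_MF_PRESET = ModelParams(0.47, 1.0, 0.0, -1.0, 0.0)
PURE_MB_PRESET = ModelParams(0.47, 0.0, 1.0, 0.0, -1.0)


@dataclass(frozen=True)
class Stage2Policy:
    """Second-stage choice rule: per-state Rescorla-Wagner + softmax.

    Option values within each second-stage state are learned on the
    binarized outcome (reward = 1) with rate ``learning_rate`` and read out
    through a softmax with ``inverse_temperature`` (values live on the 0-1
    probability scale, so a temperature of ~5 makes an 0.8-vs-0.2 option
    pair yield ~95% choice of the better option at asymptote).
    """

    learning_rate: float = 0.3
    inverse_temperature: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in [0, 1]")
        if self.inverse_temperature < 0.0:
            raise ValueError("inverse_temperature must be non-negative")


@dataclass(frozen=True)
class AgentSpec:
    """A playable agent: kind, first-stage parameters, second-stage policy."""

    kind: str = "hybrid"
    params: ModelParams | None = None
    stage2: Stage2Policy = field(default_factory=Stage2Policy)

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"kind must be one of {AGENT_KINDS}")
        params = self.params
        if self.kind == "hybrid" and params is None:
            raise ValueError("hybrid agents require params")
        if self.kind == "pure_model_free":
            params = params or PURE_MF_PRESET
            if params.d_plus_mb != 0.0 or params.d_minus_mb != 0.0:
                raise ValueError("pure_model_free requires zero model-based deltas")
        if self.kind == "pure_model_based":
            params = params or PURE_MB_PRESET
            if params.d_plus_mf != 0.0 or params.d_minus_mf != 0.0:
                raise ValueError("pure_model_based requires zero model-free deltas")
        object.__setattr__(self, "params", params)


@dataclass(frozen=True)
class CohortSpec:
    """A two-condition synthetic cohort.

    ``jitter`` scales the between-subject normal dispersion around each
    condition preset (1.0 = the IQR-derived defaults; 0 = all subjects share
    the preset exactly).  Jittered gammas are clamped to [0, 1].  Subject
    seeds derive deterministically from ``master_seed``.
    """

    n_subjects_per_condition: int = 26
    condition_presets: dict = field(
        default_factory=lambda: dict(CONDITION_PRESETS)
    )
    jitter: float = 1.0
    stage2: Stage2Policy = field(default_factory=Stage2Policy)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_condition < 1:
            raise ValueError("need at least one subject per condition")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


def _draw_subject_params(
    preset: ModelParams, jitter: float, rng: np.random.Generator
) -> ModelParams:
    if jitter == 0.0:
        return preset
    vals = {}
    for name in PARAM_NAMES:
        scale = jitter * DEFAULT_JITTER[name]
        vals[name] = float(getattr(preset, name) + rng.normal(0.0, scale))
    vals["gamma"] = min(1.0, max(0.0, vals["gamma"]))
    return ModelParams(**vals)


def _stage2_choice(
    q: np.ndarray, policy: Stage2Policy, rng: np.random.Generator
) -> int:
    d = policy.inverse_temperature * (q[0] - q[1])
    p0 = 1.0 / (1.0 + math.exp(-d)) if d >= 0 else math.exp(d) / (1.0 + math.exp(d))
    return 0 if rng.random() < p0 else 1


def simulate_session(
    agent: AgentSpec,
    config: TaskConfig,
    seed: int | np.random.SeedSequence,
    subject_id: str = "s01",
    condition: str = "control",
) -> list[TrialRecord]:
    """Play one full session and return the ordered trial records.

    Hybrid (and pure-*) agents choose stage 1 from the softmax over the
    current value difference, update first-stage values with the hybrid
    attribution rules after every trial, and choose stage 2 from the
    Rescorla-Wagner policy.  Values are never reset at block boundaries --
    reversals are uncued, so the agent cannot know a block changed.
    """
    rng = np.random.default_rng(seed)
    v = ValueState()
    q = {s: np.zeros(2) for s in STATES}  # per-state second-stage values
    first_choice: str | None = None
    records: list[TrialRecord] = []
    for trial in range(1, config.n_trials + 1):
        block = config.block_of(trial)
        # first-stage choice
        if agent.kind == "random":
            choice1 = ACTIONS[int(rng.integers(2))]
        elif agent.kind == "perseverator":
            if first_choice is None:
                first_choice = ACTIONS[int(rng.integers(2))]
            choice1 = first_choice
        else:
            p1 = choice_prob(v)
            choice1 = "a1" if rng.random() < p1 else "a2"
        state2, transition = sample_transition(choice1, config, rng)
        c2 = _stage2_choice(q[state2], agent.stage2, rng)
        choice2 = OPTIONS[c2]
        outcome = sample_outcome(state2, choice2, block, config, rng)
        rewarded = outcome > 0
        # learning
        if agent.params is not None:
            v = update_values(v, choice1, transition, rewarded, agent.params)
        q[state2][c2] += agent.stage2.learning_rate * (float(rewarded) - q[state2][c2])
        records.append(
            TrialRecord(
                subject_id=subject_id,
                condition=condition,
                trial=trial,
                block=block,
                choice1=choice1,
                transition=transition,
                state2=state2,
                choice2=choice2,
                outcome=outcome,
            )
        )
    return records


def simulate_cohort(
    cohort: CohortSpec, config: TaskConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one session per synthetic subject across both conditions.

    Returns ``(trials, truth)``: the stacked trial log and the ground-truth
    table (one row per subject: condition, true parameters, session seed)
    used later for parameter recovery.
    """
    config = config or default_task_config()
    root = np.random.SeedSequence(cohort.master_seed)
    conditions = sorted(cohort.condition_presets)
    n = cohort.n_subjects_per_condition
    children = root.spawn(2 * n * len(conditions))
    frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    k = 0
    for cond in conditions:
        preset = cohort.condition_presets[cond]
        for i in range(n):
            sid = f"{cond}_{i + 1:02d}"
            param_ss, session_ss = children[k], children[k + 1]
            k += 2
            params = _draw_subject_params(
                preset, cohort.jitter, np.random.default_rng(param_ss)
            )
            agent = AgentSpec(kind="hybrid", params=params, stage2=cohort.stage2)
            recs = simulate_session(
                agent, config, session_ss, subject_id=sid, condition=cond
            )
            frames.append(trials_to_frame(recs))
            row = {"subject_id": sid, "condition": cond}
            row.update({f"true_{n_}": getattr(params, n_) for n_ in PARAM_NAMES})
            row["session_entropy"] = str(session_ss.entropy)
            row["spawn_key"] = str(session_ss.spawn_key)
            truth_rows.append(row)
    trials = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth
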