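"""Hybrid model-free / model-based value updates and the choice likelihood.

First-stage behavior is modeled by two action values V(a1), V(a2) that decay
every trial and receive outcome-dependent increments.  In the decay
parameterization the update for every option x is

    V(x) <- gamma * V(x) + Delta,

where gamma in [0, 1] is the decay (discount) factor and the increment
Delta depends on the outcome valence (+ for reward, - for no reward), on
the system (model-free vs model-based), and on the transition type of the
trial:

    common & rewarded    chosen += D+mf + D+mb
    rare   & rewarded    chosen += D+mf,  unchosen += D+mb
    common & unrewarded  chosen += D-mf + D-mb
    rare   & unrewarded  chosen += D-mf,  unchosen += D-mb

The model-free system credits the outcome to the action actually taken; the
model-based system credits it to the action that most likely leads to the
state where the outcome occurred.  The decay parameterization is
algebraically identical to the learning-rate form V <- V + alpha*(kappa - V)
with gamma = 1 - alpha and Delta = alpha * kappa, but is numerically better
behaved: as alpha -> 0 the kappas blow up to compensate while the Deltas
stay finite.

Choice follows a softmax on the value difference with unit slope,
P(a1) = 1 / (1 + exp(-(V(a1) - V(a2)))); no inverse temperature is needed
because the magnitude of the Deltas already sets choice determinism.
Values start at zero for both actions, so the first choice is uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

PARAM_NAMES = ("gamma", "d_plus_mf", "d_plus_mb", "d_minus_mf", "d_minus_mb")


@dataclass(frozen=True)
class ModelParams:
    """Decay-form parameters: gamma plus the four value-change increments."""

    gamma: float
    d_plus_mf: float
    d_plus_mb: float
    d_minus_mf: float
    d_minus_mb: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1]; got {self.gamma}")
        for name in PARAM_NAMES[1:]:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "ModelParams":
        return cls(*(float(v) for v in x))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


@dataclass(frozen=True)
class KappaParams:
    """Learning-rate form: alpha plus the four reinforcement strengths."""

    alpha: float
    kappa_plus_mf: float
    kappa_plus_mb: float
    kappa_minus_mf: float
    kappa_minus_mb: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1]; got {self.alpha}")


def to_delta(kp: KappaParams) -> ModelParams:
    """Map the learning-rate form to the equivalent decay form.

    gamma = 1 - alpha and each Delta = alpha * kappa.  The inverse mapping
    is undefined at alpha = 0, which the KappaParams invariant excludes.
    """
    a = kp.alpha
    return ModelParams(
        gamma=1.0 - a,
        d_plus_mf=a * kp.kappa_plus_mf,
        d_plus_mb=a * kp.kappa_plus_mb,
        d_minus_mf=a * kp.kappa_minus_mf,
        d_minus_mb=a * kp.kappa_minus_mb,
    )


def to_kappa(p: ModelParams) -> KappaParams:
    """Inverse of :func:`to_delta`; undefined at gamma = 1 (alpha = 0)."""
    a = 1.0 - p.gamma
    if a == 0.0:
        raise ValueError("gamma = 1 has no kappa-form equivalent (alpha = 0)")
    return KappaParams(
        alpha=a,
        kappa_plus_mf=p.d_plus_mf / a,
        kappa_plus_mb=p.d_plus_mb / a,
        kappa_minus_mf=p.d_minus_mf / a,
        kappa_minus_mb=p.d_minus_mb / a,
    )


@dataclass
class ValueState:
    """The two first-stage action values, ordered (V(a1), V(a2))."""

    v: np.ndarray

    def __init__(self, v: Sequence[float] = (0.0, 0.0)) -> None:
        arr = np.asarray(v, dtype=float).copy()
        if arr.shape != (2,) or not np.all(np.isfinite(arr)):
            raise ValueError("ValueState needs exactly two finite values")
        self.v = arr


def update_values(
    v: ValueState,
    choice1: str,
    transition: str,
    rewarded: bool,
    p: ModelParams,
) -> ValueState:
    """Apply one trial's decay-and-increment update to both action values.

    Both values decay by gamma every trial (chosen and unchosen alike);
    increments are then attributed per the model-free / model-based rules in
    the module docstring.  Outcome magnitude never enters, only valence.
    """
    chosen = 0 if choice1 == "a1" else 1
    unchosen = 1 - chosen
    d_mf = p.d_plus_mf if rewarded else p.d_minus_mf
    d_mb = p.d_plus_mb if rewarded else p.d_minus_mb
    new = ValueState(p.gamma * v.v)
    if transition == "common":
        new.v[chosen] += d_mf + d_mb
    elif transition == "rare":
        new.v[chosen] += d_mf
        new.v[unchosen] += d_mb
    else:
        raise ValueError("transition must be 'common' or 'rare'")
    return new


def update_values_kappa(
    v: ValueState,
    choice1: str,
    transition: str,
    rewarded: bool,
    kp: KappaParams,
) -> ValueState:
    """One trial's update written in the explicit alpha/kappa form.

    V(x) <- (1 - alpha) V(x) + alpha * kappa(x), where kappa(x) collects the
    model-free and/or model-based strengths attributed to option x on this
    trial (zero for an option receiving no credit).  Kept separate from
    :func:`update_values` so the algebraic equivalence of the two forms can
    be checked rather than assumed.
    """
    chosen = 0 if choice1 == "a1" else 1
    unchosen = 1 - chosen
    k_mf = kp.kappa_plus_mf if rewarded else kp.kappa_minus_mf
    k_mb = kp.kappa_plus_mb if rewarded else kp.kappa_minus_mb
    kappa = np.zeros(2)
    if transition == "common":
        kappa[chosen] = k_mf + k_mb
    elif transition == "rare":
        kappa[chosen] = k_mf
        kappa[unchosen] = k_mb
    else:
        raise ValueError("transition must be 'common' or 'rare'")
    return ValueState((1.0 - kp.alpha) * v.v + kp.alpha * kappa)


def choice_prob(v: ValueState) -> float:
    """Probability of choosing a1: the logistic of V(a1) - V(a2)."""
    d = v.v[0] - v.v[1]
    if d >= 0:
        return 1.0 / (1.0 + math.exp(-d))
    e = math.exp(d)
    return e / (1.0 + e)


# -- session likelihood ---------------------------------------------------
#
# Only the value DIFFERENCE d = V(a1) - V(a2) enters the choice rule, and
# it follows the scalar recursion d' = gamma*d + s*m where s = +/-1 encodes
# which action was chosen and m is one of four trial-type increments:
#
#   common & rewarded    m = D+mf + D+mb
#   rare   & rewarded    m = D+mf - D+mb
#   common & unrewarded  m = D-mf + D-mb
#   rare   & unrewarded  m = D-mf - D-mb
#
# (the unchosen option's model-based credit on rare trials enters with a
# minus sign in the difference).  Running that linear recursion with an IIR
# filter gives the whole value-difference trajectory in one vectorized pass.

_CASE_COMMON_REWARD = 0
_CASE_RARE_REWARD = 1
_CASE_COMMON_NOREWARD = 2
_CASE_RARE_NOREWARD = 3


def encode_trials(trials: pd.DataFrame | Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a single-subject trial log to likelihood sufficient statistics.

    Returns ``(sign, case)`` arrays over trials in order: ``sign`` is +1 for
    choice a1 and -1 for a2; ``case`` indexes the four (transition, valence)
    cells.  Second-stage choices carry no information about the first-stage
    model and are dropped.
    """
    if isinstance(trials, pd.DataFrame):
        df = trials.sort_values("trial")
        choice1 = df["choice1"].to_numpy()
        transition = df["transition"].to_numpy()
        rewarded = df["outcome"].to_numpy() > 0
    else:
        choice1 = np.array([t.choice1 for t in trials])
        transition = np.array([t.transition for t in trials])
        rewarded = np.array([t.outcome > 0 for t in trials])
    sign = np.where(choice1 == "a1", 1.0, -1.0)
    common = transition == "common"
    case = np.where(
        rewarded,
        np.where(common, _CASE_COMMON_REWARD, _CASE_RARE_REWARD),
        np.where(common, _CASE_COMMON_NOREWARD, _CASE_RARE_NOREWARD),
    )
    return sign, case.astype(np.intp)


def loglik_encoded(x: np.ndarray, sign: np.ndarray, case: np.ndarray) -> float:
    """Session log-likelihood from encoded trials and a raw parameter vector.

    ``x`` is (gamma, D+mf, D+mb, D-mf, D-mb).  Values start at zero, so the
    first trial contributes log(1/2).
    """
    gamma, dpf, dpb, dnf, dnb = x
    m = np.array([dpf + dpb, dpf - dpb, dnf + dnb, dnf - dnb])
    delta = sign * m[case]
    # d[t] is the value difference BEFORE trial t's choice; d[0] = 0.
    z = lfilter([1.0], [1.0, -gamma], delta)
    d = np.empty_like(z)
    d[0] = 0.0
    d[1:] = z[:-1]
    # log P(observed) = -log(1 + exp(-sign * d))
    return float(-np.logaddexp(0.0, -sign * d).sum())


def value_difference_trajectory(p: ModelParams, trials) -> np.ndarray:
    """V(a1) - V(a2) before each trial's choice, starting at zero."""
    sign, case = encode_trials(trials)
    m = np.array(
        [
            p.d_plus_mf + p.d_plus_mb,
            p.d_plus_mf - p.d_plus_mb,
            p.d_minus_mf + p.d_minus_mb,
            p.d_minus_mf - p.d_minus_mb,
        ]
    )
    delta = sign * m[case]
    z = lfilter([1.0], [1.0, -p.gamma], delta)
    d = np.empty_like(z)
    d[0] = 0.0
    d[1:] = z[:-1]
    return d


def session_loglik(p: ModelParams, trials: pd.DataFrame | Sequence) -> float:
    """Log-likelihood of a session's first-stage choices under the model.

    Trials must belong to one subject and be ordered by trial index (a
    DataFrame is sorted defensively).  An empty session returns 0.0 by
    convention.
    """
    n = len(trials)
    if n == 0:
        return 0.0
    sign, case = encode_trials(trials)
    return loglik_encoded(p.as_array(), sign, case)


def session_loglik_loop(p: ModelParams, trials: Sequence) -> float:
    """Reference implementation: explicit per-trial update_values loop.

    Slower than :func:`session_loglik` but follows the update equations
    literally; the two must agree to floating tolerance.
    """
    v = ValueState()
    total = 0.0
    for t in sorted(trials, key=lambda t: t.trial):
        p1 = choice_prob(v)
        prob = p1 if t.choice1 == "a1" else 1.0 - p1
        total += math.log(prob)
        v = update_values(v, t.choice1, t.transition, t.outcome > 0, p)
    return total
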