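"""Emotion appraisal, mood dynamics, and the bipolar mood rhythm.

Emotion follows appraisal theory: an interaction's emotional value is the
(squashed) difference between the perceived reward -- the counterpart's
cooperation level scaled by the agent's reward sensitivity ``beta`` -- and
the agent's own expectation, which under the cooperation rule equals its
own cooperation level.  Mood is an exponentially smoothed summary of recent
emotions, kept in ``[-1, 1]`` by a tanh squash.  Bipolar agents do not
integrate emotion into mood; their mood follows an intrinsic sinusoidal
rhythm whose angular rate is resampled periodically, and their reward
sensitivity is re-derived from the current mood every round.

All functions are pure and accept scalars; they are written with numpy
ufuncs so array inputs broadcast where that is natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AffectState",
    "BipolarRhythm",
    "appraise_emotion",
    "update_mood",
    "initial_mood",
    "bipolar_mood",
    "resample_omega",
    "bipolar_reward_sensitivity",
]


@dataclass
class AffectState:
    """Affective state of one agent.

    Parameters
    ----------
    mood : float
        Current mood ``nu`` in ``[-1, 1]``.
    mood_change_rate : float
        Rate ``kappa`` in ``[0, 1]`` at which mood tracks emotion. Zero for
        rational agents (their mood is pinned at neutral); not used by
        bipolar agents, whose mood is rhythm-driven.
    reward_sensitivity : float
        Current ``beta`` in ``[0, beta_max]``; exactly 1 for rational
        agents, constant for manic/depressed agents, time-varying for
        bipolar agents.
    beta0 : float
        Trait (initial) reward sensitivity ``beta^0``.
    beta_max : float
        Upper cap on reward sensitivity, > 1.
    """

    mood: float
    mood_change_rate: float
    reward_sensitivity: float
    beta0: float
    beta_max: float = 10.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.mood <= 1.0:
            raise ValueError(f"mood must be in [-1, 1], got {self.mood}")
        if not 0.0 <= self.mood_change_rate <= 1.0:
            raise ValueError("mood_change_rate must be in [0, 1]")
        if self.beta_max <= 1.0:
            raise ValueError("beta_max must exceed 1")
        if not 0.0 <= self.reward_sensitivity <= self.beta_max:
            raise ValueError("reward_sensitivity must be in [0, beta_max]")


@dataclass
class BipolarRhythm:
    """Intrinsic mood oscillation of a bipolar agent.

    ``mood(t) = clamp(sin(omega * t) + offset, -1, 1)``.  The angular rate
    ``omega`` is redrawn every ``resample_interval`` rounds from an
    exponential distribution with agent-constant mean ``omega_mean``; the
    offset ``lambda`` shifts the cycle toward mostly-manic (> 0) or
    mostly-depressed (< 0).
    """

    omega: float
    omega_mean: float
    offset: float
    resample_interval: int = 50

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.omega_mean <= 0:
            raise ValueError("omega_mean must be positive")
        if not -1.0 <= self.offset <= 1.0:
            raise ValueError("offset must be in [-1, 1]")
        if self.resample_interval < 1:
            raise ValueError("resample_interval must be a positive integer")


def _check_unit_interval(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def appraise_emotion(reward_sensitivity, c_other, c_self):
    """Emotion induced by receiving cooperation ``c_other`` while extending
    ``c_self``, for an agent with the given reward sensitivity.

    Returns ``tanh(beta * c_other - c_self)``.  With ``beta = 1`` the
    pre-squash argument is the plain reward-minus-expectation difference of
    a rational appraisal; ``beta > 1`` inflates perceived reward (mania),
    ``beta < 1`` dampens it (anhedonia).
    """
    _check_unit_interval("c_other", c_other)
    _check_unit_interval("c_self", c_self)
    if np.any(np.asarray(reward_sensitivity, dtype=float) < 0.0):
        raise ValueError("reward_sensitivity must be non-negative")
    return np.tanh(np.asarray(reward_sensitivity, dtype=float) * c_other - c_self)


def update_mood(mood_prev, kappa, emotion):
    """One mood step: ``tanh(nu + kappa * (delta - nu))``.

    ``kappa = 1`` makes mood fleeting (equal to squashed emotion);
    ``kappa = 0`` leaves a neutral mood untouched.
    """
    mood_prev = np.asarray(mood_prev, dtype=float)
    emotion = np.asarray(emotion, dtype=float)
    if np.any(np.abs(mood_prev) > 1.0):
        raise ValueError("mood_prev must be in [-1, 1]")
    if np.any(np.abs(emotion) > 1.0):
        raise ValueError("emotion must be in [-1, 1]")
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0.0) or np.any(kappa > 1.0):
        raise ValueError("kappa must be in [0, 1]")
    return np.tanh(mood_prev + kappa * (emotion - mood_prev))


def initial_mood(beta0: float, beta_max: float = 10.0) -> float:
    """Initial mood implied by trait reward sensitivity.

    Depressed traits (``beta0 < 1``) start at ``beta0 - 1`` (negative);
    manic traits (``beta0 > 1``) start at ``(beta0 - 1) / (beta_max - 1)``,
    which maps the manic range onto ``(0, 1]``; ``beta0 = 1`` is neutral.
    """
    if beta_max <= 1.0:
        raise ValueError("beta_max must exceed 1")
    if not 0.0 <= beta0 <= beta_max:
        raise ValueError(f"beta0 must be in [0, beta_max], got {beta0}")
    if beta0 < 1.0:
        return beta0 - 1.0
    if beta0 > 1.0:
        return (beta0 - 1.0) / (beta_max - 1.0)
    return 0.0


def bipolar_mood(rhythm: BipolarRhythm, t: int) -> float:
    """Mood of a bipolar agent at round ``t``.

    ``sin(omega * t) + offset`` clamped to ``[-1, 1]``; the clamp keeps the
    mood inside the domain on which reward sensitivity and the retrieval
    kernel are defined (a nonzero offset would otherwise push the raw sine
    outside it).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    raw = math.sin(rhythm.omega * t) + rhythm.offset
    return max(-1.0, min(1.0, raw))


def resample_omega(rhythm: BipolarRhythm, rng: np.random.Generator) -> float:
    """Draw a fresh angular rate from ``Exponential(mean=omega_mean)``.

    The caller installs the draw as ``rhythm.omega`` every
    ``resample_interval`` rounds, emulating the irregular cycling speed
    seen across bipolar episodes.
    """
    if rhythm.omega_mean <= 0:
        raise ValueError("omega_mean must be positive")
    return float(rng.exponential(rhythm.omega_mean))


def bipolar_reward_sensitivity(mood, beta_max: float = 10.0):
    """Reward sensitivity implied by the current mood.

    Piecewise-linear and continuous: neutral mood gives 1, negative mood
    shrinks sensitivity linearly toward 0 (``mood + 1``), positive mood
    inflates it linearly toward ``beta_max``
    (``1 + mood * (beta_max - 1)``).
    """
    if beta_max <= 1.0:
        raise ValueError("beta_max must exceed 1")
    mood_arr = np.asarray(mood, dtype=float)
    if np.any(np.abs(mood_arr) > 1.0):
        raise ValueError("mood must be in [-1, 1]")
    out = np.where(mood_arr < 0.0, mood_arr + 1.0, 1.0 + mood_arr * (beta_max - 1.0))
    if np.isscalar(mood) or np.ndim(mood) == 0:
        return float(out)
    return out
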