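"""Construct the heterogeneous agent society.

Per-type trait sampling: rational agents have reward sensitivity exactly
1; manic traits are uniform on (1, beta_max]; depressed traits uniform on
[0, 1).  Bipolar agents do not sample a trait sensitivity -- they sample a
rhythm (offset and mean angular rate) and their sensitivity at t = 0 is
derived from the initial mood.  Drive (participation probability) and
target degree (social reach) are min-max rescalings of the trait
sensitivity, so manic agents are never less engaged or less connected
than depressed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .affect import (
    AffectState,
    BipolarRhythm,
    bipolar_mood,
    bipolar_reward_sensitivity,
    initial_mood,
    resample_omega,
)
from .config import AGENT_TYPES, SimulationConfig
from .memory import AgentMemory, MemoryParams

__all__ = ["Agent", "drive_of", "degree_of", "spawn_population"]


@dataclass
class Agent:
    """One simulated individual.

    Ids are consecutive integers ``0 .. n_agents - 1`` and double as array
    indices everywhere in the engine.
    """

    id: int
    agent_type: str
    affect: AffectState
    mem_params: MemoryParams
    drive: float
    target_degree: int
    rhythm: Optional[BipolarRhythm] = None
    diversity: Optional[float] = None
    memory: AgentMemory = field(default_factory=AgentMemory)
    cumulative_payoff: float = 0.0
    n_interactions: int = 0
    n_active_rounds: int = 0


def _check_beta0(beta0: float, beta_max: float) -> None:
    if not 0.0 <= beta0 <= beta_max:
        raise ValueError(f"beta0 must be in [0, beta_max], got {beta0}")


def drive_of(beta0: float, beta_max: float = 10.0) -> float:
    """Participation probability implied by trait sensitivity.

    0.5 at the rational point, scaled into [0, 0.5) for depressed traits
    and (0.5, 1] for manic traits by min-max rescaling.
    """
    _check_beta0(beta0, beta_max)
    if beta0 < 1.0:
        return 0.5 * beta0
    if beta0 > 1.0:
        return 0.5 + 0.5 * (beta0 - 1.0) / (beta_max - 1.0)
    return 0.5


def degree_of(beta0: float, beta_max: float, n_agents: int) -> int:
    """Target neighborhood size implied by trait sensitivity.

    Same rescaling as :func:`drive_of` applied to the society size,
    rounded to the nearest integer and capped at ``n_agents - 1`` (a node
    cannot have more neighbors than there are other agents; the manic
    branch is extended to include ``beta0 = beta_max``).
    """
    _check_beta0(beta0, beta_max)
    if n_agents < 2:
        raise ValueError("n_agents must be at least 2")
    if beta0 < 1.0:
        raw = 0.5 * beta0 * n_agents
    elif beta0 > 1.0:
        raw = (0.5 + 0.5 * (beta0 - 1.0) / (beta_max - 1.0)) * n_agents
    else:
        raw = 0.5 * n_agents
    return min(int(round(raw)), n_agents - 1)


def _sample_beta0(agent_type: str, config: SimulationConfig, rng: np.random.Generator) -> float:
    override = (config.beta_override or {}).get(agent_type)
    if override is not None:
        return float(override)
    if agent_type == "rational":
        return 1.0
    if agent_type == "manic":
        # uniform on (1, beta_max]: 1 - random() is in (0, 1]
        return 1.0 + (config.beta_max - 1.0) * (1.0 - rng.random())
    if agent_type == "depressed":
        return float(rng.random())  # [0, 1)
    raise ValueError(f"unknown agent type {agent_type!r}")


def spawn_population(config: SimulationConfig, rng: np.random.Generator) -> List[Agent]:
    """Create the society described by ``config``.

    Agents are laid out in type blocks (rational, manic, depressed,
    bipolar) with ids 0..n-1.  Bipolar agents get a rhythm with offset
    ``lambda ~ U(bipolar_offset_range)``, mean rate
    ``omega' ~ U(omega_mean_range)`` and an initial rate drawn from
    ``Exponential(omega')``; their mood at t = 0 is the (clamped) rhythm
    value and their sensitivity, drive and degree derive from it.
    """
    config.validate()
    counts = config.type_counts()
    agents: List[Agent] = []
    next_id = 0
    for agent_type in AGENT_TYPES:
        for _ in range(counts[agent_type]):
            if agent_type == "bipolar":
                offset = float(rng.uniform(*config.bipolar_offset_range))
                omega_mean = float(rng.uniform(*config.omega_mean_range))
                rhythm = BipolarRhythm(
                    omega=omega_mean,  # placeholder; resampled next line
                    omega_mean=omega_mean,
                    offset=offset,
                    resample_interval=config.omega_resample_every,
                )
                rhythm.omega = resample_omega(rhythm, rng)
                mood = bipolar_mood(rhythm, 0)
                beta0 = bipolar_reward_sensitivity(mood, config.beta_max)
                kappa = 0.0  # not pertinent: mood is rhythm-driven
            else:
                rhythm = None
                beta0 = _sample_beta0(agent_type, config, rng)
                mood = initial_mood(beta0, config.beta_max)
                kappa = 0.0 if agent_type == "rational" else config.kappa_mood
            affect = AffectState(
                mood=mood,
                mood_change_rate=kappa,
                reward_sensitivity=beta0,
                beta0=beta0,
                beta_max=config.beta_max,
            )
            drive = config.drive_override if config.drive_override is not None else drive_of(
                beta0, config.beta_max
            )
            agents.append(
                Agent(
                    id=next_id,
                    agent_type=agent_type,
                    affect=affect,
                    mem_params=config.memory,
                    drive=drive,
                    target_degree=degree_of(beta0, config.beta_max, config.n_agents),
                    rhythm=rhythm,
                    diversity=config.diversity if agent_type == "depressed" else None,
                )
            )
            next_id += 1
    return agents
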