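"""Simulation configuration: constants, per-type parameter ranges, seeds.

A :class:`SimulationConfig` fully determines a run together with one
integer seed.  Configs round-trip through plain dicts and YAML so a run
can be reproduced from the echoed config file alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .game import PayoffConstants
from .memory import MemoryParams

__all__ = ["AGENT_TYPES", "ConfigError", "SimulationConfig"]

AGENT_TYPES = ("rational", "manic", "depressed", "bipolar")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _equal_proportions() -> dict:
    return {t: 0.25 for t in AGENT_TYPES}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything a run needs besides the seed.

    Attributes
    ----------
    n_agents, proportions, n_rounds
        Society size, per-type fractions (must sum to 1), and the number
        of interaction rounds ``K``.
    payoff
        CPD corner payoffs.
    beta_max
        Cap on reward sensitivity (manic trait range is ``(1, beta_max]``).
    kappa_mood
        Mood change rate for manic and depressed agents (rational agents
        use 0; bipolar mood is rhythm-driven and ignores it).
    memory
        Shared memory parameters (forgetting rate, encoding gradients,
        deletion floor, mood dependence).
    diversity
        Connection-diversity ``pi`` of depressed agents: target fraction
        of their neighbors that are themselves depressed; the rest of
        their neighborhood is split equally over the other three types.
    bipolar_offset_range, omega_mean_range, omega_resample_every
        Bipolar rhythm: per-agent offset ``lambda`` ~ U(range), rhythm
        mean rate ``omega'`` ~ U(range) (rad/round), and the resampling
        interval of the instantaneous rate.
    cold_start
        Expectation used when no trace is retrieved: the string
        ``"uniform"`` draws a fresh U[0, 1] expectation per cold start
        (the default -- it is what seeds heterogeneous cooperation
        levels), or a fixed float in [0, 1].
    subjective_traces
        If True (default), a trace stores the reward as the agent
        perceived it -- the counterpart's cooperation scaled by the
        agent's reward sensitivity, clipped to [0, 1] -- so expectation,
        cooperation, and appraisal all live on the agent's subjective
        reward scale (mania inflates expectations, anhedonia deflates
        them).  If False, traces store the objective cooperation level.
    broadcast
        Whether interaction gists propagate to neighbors.  Off by
        default: gists accumulate roughly an order of magnitude faster
        than firsthand traces, and at full strength secondhand
        information swamps the per-interaction memory dynamics the model
        is built around.
    drive_override
        Force every agent's participation probability to this value
        (diagnostics and tiny deterministic runs).
    beta_override
        Map agent type -> fixed trait sensitivity, overriding the
        per-type sampling range (used by the reward-sensitivity sweeps).
    """

    n_agents: int = 200
    proportions: Mapping[str, float] = field(default_factory=_equal_proportions)
    n_rounds: int = 2000
    payoff: PayoffConstants = field(default_factory=PayoffConstants)
    beta_max: float = 10.0
    kappa_mood: float = 0.1
    memory: MemoryParams = field(default_factory=MemoryParams)
    diversity: float = 0.25
    bipolar_offset_range: tuple = (-1.0, 1.0)
    omega_mean_range: tuple = (0.01, 0.5)
    omega_resample_every: int = 50
    cold_start: Any = "uniform"
    subjective_traces: bool = True
    broadcast: bool = False
    drive_override: float | None = None
    beta_override: Mapping[str, float] | None = None
    n_replicates: int = 10
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> "SimulationConfig":
        if self.n_agents < 2:
            raise ConfigError("n_agents must be at least 2")
        if self.n_rounds < 1:
            raise ConfigError("n_rounds must be positive")
        unknown = set(self.proportions) - set(AGENT_TYPES)
        if unknown:
            raise ConfigError(f"unknown agent types in proportions: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"type proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.proportions.values()):
            raise ConfigError("type proportions must be non-negative")
        if self.beta_max <= 1:
            raise ConfigError("beta_max must exceed 1")
        if not 0.0 <= self.kappa_mood <= 1.0:
            raise ConfigError("kappa_mood must be in [0, 1]")
        if not 0.0 <= self.diversity <= 1.0:
            raise ConfigError("diversity must be in [0, 1]")
        # Feasibility of the depressed-neighbor quota: a depressed agent's
        # degree can reach 0.5 * n, so pi * 0.5 must not exceed the
        # depressed fraction of the society.
        p_dep = self.proportions.get("depressed", 0.0)
        if p_dep > 0 and self.diversity * 0.5 > p_dep + 1e-12:
            raise ConfigError(
                f"diversity pi={self.diversity} is infeasible: a depressed agent "
                f"may need up to pi * 0.5 * n = {self.diversity * 0.5 * self.n_agents:.0f} "
                f"depressed neighbors but only {p_dep * self.n_agents:.0f} depressed "
                "agents exist; require pi * 0.5 <= depressed proportion"
            )
        if isinstance(self.cold_start, str):
            if self.cold_start != "uniform":
                raise ConfigError("cold_start must be 'uniform' or a float in [0, 1]")
        elif not 0.0 <= float(self.cold_start) <= 1.0:
            raise ConfigError("cold_start must be in [0, 1]")
        if self.drive_override is not None and not 0.0 <= self.drive_override <= 1.0:
            raise ConfigError("drive_override must be in [0, 1]")
        if self.beta_override:
            for typ, b in self.beta_override.items():
                if typ not in ("manic", "depressed"):
                    raise ConfigError("beta_override applies to manic/depressed only")
                if typ == "manic" and not 1.0 < b <= self.beta_max:
                    raise ConfigError("manic beta override must be in (1, beta_max]")
                if typ == "depressed" and not 0.0 <= b < 1.0:
                    raise ConfigError("depressed beta override must be in [0, 1)")
        if self.omega_resample_every < 1:
            raise ConfigError("omega_resample_every must be positive")
        lo, hi = self.omega_mean_range
        if not 0 < lo <= hi:
            raise ConfigError("omega_mean_range must be positive and ordered")
        lo, hi = self.bipolar_offset_range
        if not -1.0 <= lo <= hi <= 1.0:
            raise ConfigError("bipolar_offset_range must lie inside [-1, 1]")
        # PayoffConstants / MemoryParams validate themselves on creation.
        return self

    # ------------------------------------------------------------------
    def replace(self, **changes: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def with_memory(self, **changes: Any) -> "SimulationConfig":
        """Copy with some memory parameters replaced."""
        return self.replace(memory=dataclasses.replace(self.memory, **changes))

    def type_counts(self) -> dict[str, int]:
        """Integer per-type counts via largest-remainder apportionment."""
        quotas = {t: self.proportions.get(t, 0.0) * self.n_agents for t in AGENT_TYPES}
        counts = {t: int(q) for t, q in quotas.items()}
        short = self.n_agents - sum(counts.values())
        by_frac = sorted(AGENT_TYPES, key=lambda t: quotas[t] - counts[t], reverse=True)
        for t in by_frac[:short]:
            counts[t] += 1
        return counts

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["proportions"] = dict(self.proportions)
        d["payoff"] = dataclasses.asdict(self.payoff)
        d["memory"] = dataclasses.asdict(self.memory)
        d["bipolar_offset_range"] = list(self.bipolar_offset_range)
        d["omega_mean_range"] = list(self.omega_mean_range)
        if self.beta_override is not None:
            d["beta_override"] = dict(self.beta_override)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        kwargs = dict(data)
        if "payoff" in kwargs and not isinstance(kwargs["payoff"], PayoffConstants):
            kwargs["payoff"] = PayoffConstants(**kwargs["payoff"])
        if "memory" in kwargs and not isinstance(kwargs["memory"], MemoryParams):
            kwargs["memory"] = MemoryParams(**kwargs["memory"])
        for key in ("bipolar_offset_range", "omega_mean_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
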