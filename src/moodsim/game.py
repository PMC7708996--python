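"""Continuous Prisoner's Dilemma: expectation, cooperation rule, payoff.

Each player picks a cooperation level in [0, 1]; the payoff bilinearly
interpolates the discrete PD matrix corners (C mutual cooperation, T
temptation, D mutual defection, S sucker).  An agent's expectation of a
counterpart is the mean cooperation over whatever traces it retrieved,
and it cooperates at exactly that expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["PayoffConstants", "expected_cooperation", "choose_cooperation", "cpd_payoff"]


@dataclass(frozen=True)
class PayoffConstants:
    """Discrete-corner payoffs.

    Must satisfy the PD ordering ``T > C > D > S`` and the iterated-game
    condition ``2C > T + D`` (mutual cooperation beats alternating
    exploitation).  The classic (T, C, D, S) = (5, 3, 1, 0) violates the
    latter and is rejected; the defaults (5, 4, 1, 0) satisfy both.
    """

    C: float = 4.0
    T: float = 5.0
    D: float = 1.0
    S: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T > self.C > self.D > self.S):
            raise ValueError(
                f"payoff constants must satisfy T > C > D > S, got "
                f"T={self.T}, C={self.C}, D={self.D}, S={self.S}"
            )
        if not 2 * self.C > self.T + self.D:
            raise ValueError(
                f"payoff constants must satisfy 2C > T + D, got "
                f"2C={2 * self.C}, T+D={self.T + self.D}"
            )


def expected_cooperation(retrieved_coops: Sequence[float], cold_start: float) -> float:
    """Mean cooperation over retrieved traces; ``cold_start`` when empty.

    An empty retrieval means either a first encounter or total forgetting;
    the caller supplies the cold-start expectation (see the engine's
    cold-start policy).
    """
    coops = np.asarray(retrieved_coops, dtype=float)
    if coops.size == 0:
        if not 0.0 <= cold_start <= 1.0:
            raise ValueError("cold_start must be in [0, 1]")
        return float(cold_start)
    return float(coops.mean())


def choose_cooperation(expectation: float) -> float:
    """Cooperation rule: cooperate at the expected level (identity map).

    Kept as its own operation so alternative strategies could be plugged
    in without touching the engine.
    """
    if not 0.0 <= expectation <= 1.0:
        raise ValueError("expectation must be in [0, 1]")
    return expectation


def cpd_payoff(c_self, c_other, constants: PayoffConstants):
    """Bilinear interpolation of the discrete payoff matrix.

    ``p = c_s*c_o*C + c_s*(1-c_o)*S + (1-c_s)*c_o*T + (1-c_s)*(1-c_o)*D``;
    exact at the four corners.
    """
    c_s = np.asarray(c_self, dtype=float)
    c_o = np.asarray(c_other, dtype=float)
    if np.any(c_s < 0) or np.any(c_s > 1) or np.any(c_o < 0) or np.any(c_o > 1):
        raise ValueError("cooperation levels must be in [0, 1]")
    out = (
        c_s * c_o * constants.C
        + c_s * (1.0 - c_o) * constants.S
        + (1.0 - c_s) * c_o * constants.T
        + (1.0 - c_s) * (1.0 - c_o) * constants.D
    )
    if out.ndim == 0:
        return float(out)
    return out
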