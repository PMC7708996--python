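"""The round loop: activity sampling, neighbor pairing, interactions,
memory and mood updates, gist broadcasting, and the event log.

Each round, every agent independently decides to participate with its
drive probability; active agents are matched pairwise along network
edges (at most one interaction per agent per round).  An interaction is
simultaneous-move: both sides retrieve traces about each other, form an
expectation, cooperate at that expectation, collect the bilinear CPD
payoff, appraise the emotion, encode a firsthand trace, and (for
non-bipolar agents) integrate the emotion into mood.  Bipolar mood is
recomputed from the sinusoidal rhythm on the global round clock instead.

Broadcasting: both participants' neighbors receive a secondhand "gist"
trace about the respective counterpart -- its cooperation level with
neutral emotion, hence weakly encoded (strength equal to the encoding
intercept) and short-lived unless refreshed.  The engine materializes
gists lazily: every interaction is appended once to a per-agent public
history, and a recipient's gist traces about a counterpart are
instantiated from that history the next time the recipient queries its
memory about that counterpart.  This is observationally identical to
writing every gist eagerly at the end of the round it occurred in (gists
become retrievable from the following round; dead gists are never seen
because deletion depends only on elapsed time), while doing work
proportional to the traces actually consulted.  The eager per-record
semantics is available as :func:`broadcast` and is checked against the
lazy path in the test-suite.

Determinism: a single master seed fans out to named substreams
(population, network, rhythm, activity, pairing, retrieval, cold-start),
so a run is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .memory import PairStore
from .population import Agent, spawn_population
from .socialnet import SocialNetwork, build_network

__all__ = [
    "InteractionRecord",
    "SimulationResult",
    "Simulation",
    "sample_active",
    "pair_active",
    "broadcast",
    "run_simulation",
]

_STREAMS = ("population", "network", "rhythm", "activity", "pairing", "retrieval", "cold_start")

RECORD_FIELDS = (
    "round",
    "id_a",
    "id_b",
    "c_a",
    "c_b",
    "payoff_a",
    "payoff_b",
    "emotion_a",
    "emotion_b",
)


@dataclass(frozen=True)
class InteractionRecord:
    """One row of the event log; payoffs are recomputable from c_a/c_b."""

    round: int
    id_a: int
    id_b: int
    c_a: float
    c_b: float
    payoff_a: float
    payoff_b: float
    emotion_a: float
    emotion_b: float


def sample_active(drives: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(drive) participation draw; returns a bool mask."""
    return rng.random(drives.shape[0]) < drives


def pair_active(
    network: SocialNetwork, active: np.ndarray, rng: np.random.Generator
) -> List[tuple]:
    """Match active agents pairwise along edges.

    Active agents are visited in a seeded random order; each yet-unmatched
    agent picks one uniformly random unmatched active neighbor (if any).
    An agent that finds no partner stays available and may still be picked
    by a later agent; every agent ends up in at most one pair.
    """
    active_ids = np.flatnonzero(active)
    order = active_ids[rng.permutation(active_ids.shape[0])]
    available = active.copy()
    matched = np.zeros_like(active)
    pairs: List[tuple] = []
    for a in order:
        a = int(a)
        if matched[a]:
            continue
        nbrs = network.neighbors[a]
        cands = nbrs[available[nbrs] & ~matched[nbrs]]
        if cands.shape[0] == 0:
            continue
        b = int(cands[rng.integers(cands.shape[0])])
        matched[a] = True
        matched[b] = True
        pairs.append((a, b))
    return pairs


def broadcast(
    record: InteractionRecord,
    agents: Sequence[Agent],
    network: SocialNetwork,
    t: int,
    subjective: bool = True,
) -> int:
    """Eagerly write the gist of one interaction to the neighbors.

    Every neighbor of A other than B receives a secondhand trace about B
    (B's cooperation level, neutral emotion, intercept strength), and
    symmetrically for neighbors of B about A.  With ``subjective`` the
    recipient files the reported level through its own reward
    sensitivity, like a firsthand reward.  Returns the number of gist
    traces written.  The engine's lazy history materialization implements
    the same semantics; this function is the explicit per-record form.
    """
    count = 0
    sides = (
        (record.id_a, record.id_b, record.c_b),
        (record.id_b, record.id_a, record.c_a),
    )
    for src, about, coop in sides:
        for nb in network.neighbors[src]:
            nb = int(nb)
            if nb == about:
                continue
            agent = agents[nb]
            heard = min(agent.affect.reward_sensitivity * coop, 1.0) if subjective else coop
            agent.memory.encode(about, heard, 0.0, t, agent.mem_params, firsthand=False)
            count += 1
    return count


class _History:
    """Public per-agent interaction history feeding lazy gist delivery."""

    __slots__ = ("t", "partner", "coop", "n")

    def __init__(self, capacity: int = 16) -> None:
        self.t = np.empty(capacity, dtype=np.float64)
        self.partner = np.empty(capacity, dtype=np.int64)
        self.coop = np.empty(capacity, dtype=np.float64)
        self.n = 0

    def append(self, t: int, partner: int, coop: float) -> None:
        if self.n == self.t.shape[0]:
            cap = self.t.shape[0] * 2
            for name in ("t", "partner", "coop"):
                old = getattr(self, name)
                new = np.empty(cap, dtype=old.dtype)
                new[: self.n] = old[: self.n]
                setattr(self, name, new)
        self.t[self.n] = t
        self.partner[self.n] = partner
        self.coop[self.n] = coop
        self.n += 1


@dataclass
class SimulationResult:
    """Final agents, the event log, and per-agent / per-type summaries."""

    config: SimulationConfig
    seed: int
    agents: List[Agent]
    network: SocialNetwork
    records: pd.DataFrame
    n_rounds: int
    n_queries: int = 0
    n_retrieved: int = 0
    n_cold_starts: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        degrees = self.network.realized_degrees()
        for ag in self.agents:
            rows.append(
                {
                    "id": ag.id,
                    "type": ag.agent_type,
                    "beta0": ag.affect.beta0,
                    "target_degree": ag.target_degree,
                    "realized_degree": int(degrees[ag.id]),
                    "drive": ag.drive,
                    "activity_rate": ag.n_active_rounds / self.n_rounds,
                    "n_interactions": ag.n_interactions,
                    "cumulative_payoff": ag.cumulative_payoff,
                    "final_mood": ag.affect.mood,
                }
            )
        return pd.DataFrame(rows)

    def type_payoffs(self) -> pd.Series:
        """Mean cumulative payoff per agent type."""
        df = self.summary()
        return df.groupby("type")["cumulative_payoff"].mean()

    def write_event_log(self, path: str | Path) -> None:
        """JSON-lines event log, one interaction record per line."""
        with open(path, "w") as fh:
            for row in self.records.itertuples(index=False):
                fh.write(json.dumps(dict(zip(RECORD_FIELDS, row))) + "\n")

    def write_summary(self, path: str | Path) -> None:
        self.summary().to_csv(path, index=False)


class Simulation:
    """One seeded society run; ``run()`` executes the round loop."""

    def __init__(self, config: SimulationConfig, seed: Optional[int] = None) -> None:
        config.validate()
        self.config = config
        self.seed = config.seed if seed is None else seed
        streams = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        self.rng = {name: np.random.default_rng(s) for name, s in zip(_STREAMS, streams)}
        self.agents = spawn_population(config, self.rng["population"])
        self.network = build_network(self.agents, config.diversity, self.rng["network"])
        n = config.n_agents
        self.mood = np.array([ag.affect.mood for ag in self.agents])
        self.beta = np.array([ag.affect.reward_sensitivity for ag in self.agents])
        self.kappa = np.array([ag.affect.mood_change_rate for ag in self.agents])
        self.drives = np.array([ag.drive for ag in self.agents])
        self.payoffs = np.zeros(n)
        self.n_interactions = np.zeros(n, dtype=np.int64)
        self.n_active_rounds = np.zeros(n, dtype=np.int64)
        self.is_bipolar = np.array([ag.agent_type == "bipolar" for ag in self.agents])
        self.bipolar_ids = np.flatnonzero(self.is_bipolar)
        self.omega = np.array(
            [ag.rhythm.omega if ag.rhythm else np.nan for ag in self.agents]
        )
        self.omega_mean = np.array(
            [ag.rhythm.omega_mean if ag.rhythm else np.nan for ag in self.agents]
        )
        self.offset = np.array(
            [ag.rhythm.offset if ag.rhythm else np.nan for ag in self.agents]
        )
        self.history = [_History() for _ in range(n)]
        self._sync_ptr: List[dict] = [dict() for _ in range(n)]
        self._cold_fixed = (
            None if config.cold_start == "uniform" else float(config.cold_start)
        )
        self._corners = (config.payoff.C, config.payoff.T, config.payoff.D, config.payoff.S)
        self._subjective = config.subjective_traces
        # unrefreshed lifetime of a gist trace (elapsed rounds until deletion)
        self._gist_lifetime = np.array(
            [
                math.log(ag.mem_params.intercept / ag.mem_params.min_strength)
                / ag.mem_params.forget_rate
                for ag in self.agents
            ]
        )
        self._buffers: dict = {name: [] for name in RECORD_FIELDS}
        self.n_queries = 0
        self.n_retrieved = 0
        self.n_cold_starts = 0
        self.t = 0

    # ------------------------------------------------------------------
    def _refresh_bipolar(self, t: int) -> None:
        ids = self.bipolar_ids
        if ids.shape[0] == 0:
            return
        cfg = self.config
        if t % cfg.omega_resample_every == 0:
            self.omega[ids] = self.rng["rhythm"].exponential(self.omega_mean[ids])
        mood = np.clip(np.sin(self.omega[ids] * t) + self.offset[ids], -1.0, 1.0)
        self.mood[ids] = mood
        self.beta[ids] = np.where(
            mood < 0.0, mood + 1.0, 1.0 + mood * (cfg.beta_max - 1.0)
        )

    def _cold_start(self) -> float:
        self.n_cold_starts += 1
        if self._cold_fixed is not None:
            return self._cold_fixed
        return float(self.rng["cold_start"].random())

    def _sync_gists(self, observer: int, about: int, store: PairStore, t: int) -> None:
        """Materialize broadcast gists the observer has received about
        ``about`` since the last query (those still alive at ``t``)."""
        hist = self.history[about]
        ptrs = self._sync_ptr[observer]
        start = ptrs.get(about, 0)
        end = hist.n
        if start >= end:
            return
        ptrs[about] = end
        ts = hist.t[start:end]
        partners = hist.partner[start:end]
        # a gist reaches the observer iff it neighbors the broadcaster
        # (adjacency excludes the observer itself); skip gists that have
        # already decayed past the deletion floor
        mask = self.network.adj[observer, partners]
        mask &= (t - ts) <= self._gist_lifetime[observer]
        if mask.any():
            coops = hist.coop[start:end][mask]
            if self._subjective:
                coops = np.minimum(coops * self.beta[observer], 1.0)
            store.extend_gists(coops, ts[mask], self.agents[observer].mem_params)

    def _expectation(self, observer: int, about: int, t: int) -> float:
        agent = self.agents[observer]
        store = agent.memory.store_for(about)
        if self.config.broadcast:
            self._sync_gists(observer, about, store, t)
        coops = store.query(t, self.mood[observer], agent.mem_params, self.rng["retrieval"])
        self.n_queries += 1
        k = coops.shape[0]
        if k == 0:
            return self._cold_start()
        self.n_retrieved += k
        return float(coops.sum()) / k

    def run_interaction(self, a: int, b: int, t: int) -> InteractionRecord:
        """Execute one pairwise interaction between neighbors ``a``, ``b``."""
        if not self.network.adj[a, b]:
            raise RuntimeError(f"agents {a} and {b} are not neighbors (pairing bug)")
        # simultaneous moves from pre-round memory state
        c_a = self._expectation(a, b, t)
        c_b = self._expectation(b, a, t)
        C, T, D, S = self._corners  # inline bilinear CPD payoff
        p_a = c_a * c_b * C + c_a * (1 - c_b) * S + (1 - c_a) * c_b * T + (1 - c_a) * (1 - c_b) * D
        p_b = c_b * c_a * C + c_b * (1 - c_a) * S + (1 - c_b) * c_a * T + (1 - c_b) * (1 - c_a) * D
        self.payoffs[a] += p_a
        self.payoffs[b] += p_b
        d_a = math.tanh(self.beta[a] * c_b - c_a)
        d_b = math.tanh(self.beta[b] * c_a - c_b)
        agent_a, agent_b = self.agents[a], self.agents[b]
        # the trace stores the reward as perceived through the agent's
        # sensitivity (clipped to the cooperation scale), so expectations
        # live on the same subjective scale the appraisal compares against
        if self._subjective:
            r_a = min(self.beta[a] * c_b, 1.0)
            r_b = min(self.beta[b] * c_a, 1.0)
        else:
            r_a, r_b = c_b, c_a
        agent_a.memory.encode(b, r_a, d_a, t, agent_a.mem_params, firsthand=True)
        agent_b.memory.encode(a, r_b, d_b, t, agent_b.mem_params, firsthand=True)
        self.history[a].append(t, b, c_a)
        self.history[b].append(t, a, c_b)
        if not self.is_bipolar[a]:
            self.mood[a] = math.tanh(self.mood[a] + self.kappa[a] * (d_a - self.mood[a]))
        if not self.is_bipolar[b]:
            self.mood[b] = math.tanh(self.mood[b] + self.kappa[b] * (d_b - self.mood[b]))
        self.n_interactions[a] += 1
        self.n_interactions[b] += 1
        return InteractionRecord(t, a, b, c_a, c_b, p_a, p_b, d_a, d_b)

    def step(self, t: int) -> List[InteractionRecord]:
        """Advance one round; returns the round's interaction records."""
        self.t = t
        self._refresh_bipolar(t)
        active = sample_active(self.drives, self.rng["activity"])
        self.n_active_rounds += active
        pairs = pair_active(self.network, active, self.rng["pairing"])
        records = [self.run_interaction(a, b, t) for a, b in pairs]
        buf = self._buffers
        for rec in records:
            buf["round"].append(rec.round)
            buf["id_a"].append(rec.id_a)
            buf["id_b"].append(rec.id_b)
            buf["c_a"].append(rec.c_a)
            buf["c_b"].append(rec.c_b)
            buf["payoff_a"].append(rec.payoff_a)
            buf["payoff_b"].append(rec.payoff_b)
            buf["emotion_a"].append(rec.emotion_a)
            buf["emotion_b"].append(rec.emotion_b)
        return records

    def run(self, on_round: Optional[Callable] = None) -> SimulationResult:
        """Execute all rounds and return the collected result.

        ``on_round(sim, t)`` is called after each round (diagnostics,
        invariant audits, progress reporting).
        """
        for t in range(1, self.config.n_rounds + 1):
            self.step(t)
            if on_round is not None:
                on_round(self, t)
        return self._finalize()

    def _finalize(self) -> SimulationResult:
        for ag in self.agents:
            ag.cumulative_payoff = float(self.payoffs[ag.id])
            ag.n_interactions = int(self.n_interactions[ag.id])
            ag.n_active_rounds = int(self.n_active_rounds[ag.id])
            ag.affect.mood = float(self.mood[ag.id])
            ag.affect.reward_sensitivity = float(self.beta[ag.id])
        buf = self._buffers
        records = pd.DataFrame(
            {
                "round": np.array(buf["round"], dtype=np.int64),
                "id_a": np.array(buf["id_a"], dtype=np.int64),
                "id_b": np.array(buf["id_b"], dtype=np.int64),
                "c_a": np.array(buf["c_a"]),
                "c_b": np.array(buf["c_b"]),
                "payoff_a": np.array(buf["payoff_a"]),
                "payoff_b": np.array(buf["payoff_b"]),
                "emotion_a": np.array(buf["emotion_a"]),
                "emotion_b": np.array(buf["emotion_b"]),
            }
        )
        return SimulationResult(
            config=self.config,
            seed=self.seed,
            agents=self.agents,
            network=self.network,
            records=records,
            n_rounds=self.config.n_rounds,
            n_queries=self.n_queries,
            n_retrieved=self.n_retrieved,
            n_cold_starts=self.n_cold_starts,
        )


def run_simulation(
    config: SimulationConfig,
    seed: Optional[int] = None,
    on_round: Optional[Callable] = None,
) -> SimulationResult:
    """Spawn, wire, and run one society; see :class:`Simulation`."""
    return Simulation(config, seed=seed).run(on_round=on_round)
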