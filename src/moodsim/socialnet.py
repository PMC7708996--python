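"""Build the undirected interaction graph.

Each agent brings a target degree derived from its trait reward
sensitivity; depressed agents additionally carry a connection-diversity
quota ``pi``: a fraction ``pi`` of their neighbors should themselves be
depressed, with the remaining slots split equally over the other three
types.  Construction is seeded randomized stub matching with per-type
quota bookkeeping for depressed agents, followed by bounded retry passes
and an edge-swap repair step; heterogeneous degree sequences are not in
general exactly graphical, so realized degrees approximate targets and
the residual stub counts are reported on the result.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import AGENT_TYPES, ConfigError
from .population import Agent

__all__ = ["SocialNetwork", "build_network"]

logger = logging.getLogger(__name__)

_MAX_PASSES = 30
_MAX_REPAIR_TRIES = 500


@dataclass
class SocialNetwork:
    """Static undirected interaction graph over the agent society."""

    graph: nx.Graph
    neighbors: List[np.ndarray]  # index = agent id, sorted neighbor ids
    adj: np.ndarray  # boolean adjacency matrix
    residual_stubs: Dict[int, int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.neighbors)

    def degree(self, agent_id: int) -> int:
        return int(self.neighbors[agent_id].shape[0])

    def realized_degrees(self) -> np.ndarray:
        return np.array([nbrs.shape[0] for nbrs in self.neighbors])

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node, data in sorted(self.graph.nodes(data=True)):
            rows.append(
                {
                    "id": node,
                    "type": data.get("agent_type"),
                    "beta0": data.get("beta0"),
                    "target_degree": data.get("target_degree"),
                    "realized_degree": self.degree(node),
                }
            )
        return pd.DataFrame(rows)

    def to_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges()):
                fh.write(f"{u}\t{v}\n")

    def write_node_table(self, path: str | Path) -> None:
        self.node_table().to_csv(path, index=False)


class _Builder:
    def __init__(self, n: int) -> None:
        self.n = n
        self.adj_sets: List[set] = [set() for _ in range(n)]
        self.edges: set = set()
        # edges satisfying a diversity quota; never sacrificed by rewiring
        self.protected: set = set()

    def has_edge(self, u: int, v: int) -> bool:
        return (u, v) in self.edges if u < v else (v, u) in self.edges

    def add_edge(self, u: int, v: int) -> None:
        key = (u, v) if u < v else (v, u)
        self.edges.add(key)
        self.adj_sets[u].add(v)
        self.adj_sets[v].add(u)

    def remove_edge(self, u: int, v: int) -> None:
        key = (u, v) if u < v else (v, u)
        self.edges.remove(key)
        self.adj_sets[u].discard(v)
        self.adj_sets[v].discard(u)

    def degree(self, u: int) -> int:
        return len(self.adj_sets[u])

    def protect(self, u: int, v: int) -> None:
        self.protected.add((u, v) if u < v else (v, u))

    def is_protected(self, u: int, v: int) -> bool:
        return ((u, v) if u < v else (v, u)) in self.protected


def _match_stubs(builder: _Builder, stubs: List[int], rng: np.random.Generator) -> List[int]:
    """Pair stubs uniformly at random, rejecting self-loops/multi-edges.

    Returns the stubs left unpaired after the retry passes.
    """
    pending = list(stubs)
    for _ in range(_MAX_PASSES):
        if len(pending) < 2:
            break
        order = rng.permutation(len(pending))
        pending = [pending[i] for i in order]
        rejected: List[int] = []
        if len(pending) % 2:
            rejected.append(pending.pop())
        progressed = False
        for i in range(0, len(pending), 2):
            u, v = pending[i], pending[i + 1]
            if u == v or builder.has_edge(u, v):
                rejected.extend((u, v))
            else:
                builder.add_edge(u, v)
                progressed = True
        pending = rejected
        if not progressed:
            break
    return pending


def _complete_deficits(
    builder: _Builder, targets: Sequence[int], rng: np.random.Generator
) -> Dict[int, int]:
    """Close remaining degree deficits left by random stub matching.

    First pairs deficit nodes directly (largest deficit first, seeded
    tie-breaks); then, for a node still short by two or more whose
    non-neighbors have no spare capacity, rewires an existing edge (x, y)
    between two of its non-neighbors into (u, x), (u, y); finally tries a
    double swap for pairs of adjacent single-deficit nodes.  Returns the
    per-node deficits that could not be closed (dropped stubs).
    """
    n = len(targets)
    perm = rng.permutation(n)

    def deficit(i: int) -> int:
        return targets[i] - builder.degree(i)

    # 1) direct pairing among deficit nodes
    progress = True
    while progress:
        progress = False
        nodes = sorted(
            (i for i in range(n) if deficit(i) > 0),
            key=lambda i: (-deficit(i), perm[i]),
        )
        for u in nodes:
            if deficit(u) <= 0:
                continue
            cands = sorted(
                (
                    v
                    for v in nodes
                    if v != u and deficit(v) > 0 and v not in builder.adj_sets[u]
                ),
                key=lambda v: (-deficit(v), perm[v]),
            )
            for v in cands:
                if deficit(u) <= 0:
                    break
                if deficit(v) <= 0:
                    continue
                builder.add_edge(u, v)
                progress = True

    # 2) rewire an edge among u's non-neighbors into two edges on u
    for u in range(n):
        tries = 0
        while deficit(u) >= 2 and tries < _MAX_REPAIR_TRIES:
            tries += 1
            non_nbrs = [x for x in range(n) if x != u and x not in builder.adj_sets[u]]
            rng.shuffle(non_nbrs)
            nn_set = set(non_nbrs)
            found = False
            for x in non_nbrs:
                ys = [
                    y
                    for y in builder.adj_sets[x]
                    if y in nn_set and not builder.is_protected(x, y)
                ]
                if ys:
                    y = ys[int(rng.integers(len(ys)))]
                    builder.remove_edge(x, y)
                    builder.add_edge(u, x)
                    builder.add_edge(u, y)
                    found = True
                    break
            if not found:
                break

    # 3) double swap for adjacent single-deficit pairs
    singles = [i for i in range(n) if deficit(i) > 0]
    for u, v in itertools.combinations(singles, 2):
        if deficit(u) <= 0 or deficit(v) <= 0:
            continue
        if not builder.has_edge(u, v):
            builder.add_edge(u, v)
            continue
        done = False
        for x in (x for x in range(n) if x not in builder.adj_sets[u] and x != u and x != v):
            for y in builder.adj_sets[x]:
                if (
                    y != u
                    and y != v
                    and y not in builder.adj_sets[v]
                    and not builder.is_protected(x, y)
                ):
                    builder.remove_edge(x, y)
                    builder.add_edge(u, x)
                    builder.add_edge(v, y)
                    done = True
                    break
            if done:
                break

    return {i: deficit(i) for i in range(n) if deficit(i) > 0}


def _depressed_quotas(
    agent: Agent, dd_realized: int, other_types: Sequence[str], rng: np.random.Generator
) -> Dict[str, int]:
    remaining = max(agent.target_degree - dd_realized, 0)
    base, extra = divmod(remaining, len(other_types))
    quotas = {t: base for t in other_types}
    for t in rng.permutation(list(other_types))[:extra]:
        quotas[str(t)] += 1
    return quotas


def build_network(agents: Sequence[Agent], pi: float, rng: np.random.Generator) -> SocialNetwork:
    """Wire the society.

    Depressed agents first connect among themselves (quota
    ``round(pi * target_degree)`` each, via stub matching), then fill the
    rest of their neighborhood with equal per-type quotas from the other
    three types; all remaining capacity is paired by unconstrained stub
    matching.  Residual stubs that survive the repair step are dropped and
    reported in ``residual_stubs``.
    """
    if not 0.0 <= pi <= 1.0:
        raise ConfigError("pi must be in [0, 1]")
    n = len(agents)
    by_type: Dict[str, List[int]] = {t: [] for t in AGENT_TYPES}
    for ag in agents:
        by_type[ag.agent_type].append(ag.id)
    dep_ids = by_type["depressed"]
    if dep_ids:
        max_quota = max(int(round(pi * agents[i].target_degree)) for i in dep_ids)
        if max_quota > len(dep_ids) - 1:
            raise ConfigError(
                f"diversity pi={pi} demands up to {max_quota} depressed neighbors "
                f"but only {len(dep_ids) - 1} other depressed agents exist"
            )

    builder = _Builder(n)

    # Phase A: depressed-depressed quota edges.
    dd_stubs: List[int] = []
    for i in dep_ids:
        dd_stubs.extend([i] * int(round(pi * agents[i].target_degree)))
    leftover_dd = _match_stubs(builder, dd_stubs, rng)
    if leftover_dd:
        logger.debug("diversity phase left %d unpaired depressed stubs", len(leftover_dd))
    builder.protected.update(builder.edges)  # keep the quota edges intact

    # Phase B: fill depressed neighborhoods with equal per-type quotas.
    other_types = [t for t in AGENT_TYPES if t != "depressed"]
    for i in rng.permutation(dep_ids) if dep_ids else []:
        i = int(i)
        quotas = _depressed_quotas(agents[i], builder.degree(i), other_types, rng)
        for t, need in quotas.items():
            if need == 0:
                continue
            cands = [
                j
                for j in by_type[t]
                if builder.degree(j) < agents[j].target_degree and j not in builder.adj_sets[i]
            ]
            if len(cands) < need:
                logger.debug(
                    "agent %d: only %d/%d candidates of type %s", i, len(cands), need, t
                )
                chosen = cands
            else:
                chosen = [int(c) for c in rng.choice(cands, size=need, replace=False)]
            for j in chosen:
                builder.add_edge(i, j)

    # Phase C: unconstrained stub matching over all remaining capacity,
    # then close the deficits the random matching could not pair.
    stubs: List[int] = []
    for ag in agents:
        rem = ag.target_degree - builder.degree(ag.id)
        if rem > 0:
            stubs.extend([ag.id] * rem)
    _match_stubs(builder, stubs, rng)
    targets = [ag.target_degree for ag in agents]
    residual_counts = _complete_deficits(builder, targets, rng)
    if residual_counts:
        logger.debug(
            "dropped %d unpairable stubs: %s", sum(residual_counts.values()), residual_counts
        )

    graph = nx.Graph()
    for ag in agents:
        graph.add_node(
            ag.id,
            agent_type=ag.agent_type,
            beta0=ag.affect.beta0,
            target_degree=ag.target_degree,
        )
    graph.add_edges_from(builder.edges)

    neighbors = [np.array(sorted(builder.adj_sets[i]), dtype=np.int64) for i in range(n)]
    adj = np.zeros((n, n), dtype=bool)
    for u, v in builder.edges:
        adj[u, v] = True
        adj[v, u] = True
    return SocialNetwork(graph=graph, neighbors=neighbors, adj=adj, residual_stubs=residual_counts)
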