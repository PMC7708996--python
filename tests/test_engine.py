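"""Round loop: activity, pairing, interactions, broadcasting, logging."""

import dataclasses
import itertools
import math

import networkx as nx
import numpy as np
import pytest

from moodsim import SimulationConfig
from moodsim.engine import (
    Simulation,
    broadcast,
    pair_active,
    run_simulation,
    sample_active,
)
from moodsim.game import cpd_payoff
from moodsim.memory import AgentMemory
from moodsim.socialnet import SocialNetwork


def net_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        adj[u, v] = adj[v, u] = True
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from(edges)
    neighbors = [np.flatnonzero(adj[i]) for i in range(n)]
    return SocialNetwork(graph=graph, neighbors=neighbors, adj=adj)


class TestSampleActive:
    def test_extremes(self, rng):
        assert sample_active(np.ones(10), rng).all()
        assert not sample_active(np.zeros(10), rng).any()

    def test_activity_rate_tracks_drive(self):
        cfg = SimulationConfig(
            n_agents=50, n_rounds=400, proportions={"rational": 1.0}, seed=2
        )
        res = run_simulation(cfg)
        rates = res.summary()["activity_rate"].to_numpy()
        se = math.sqrt(0.25 / 400)
        assert (np.abs(rates - 0.5) < 4.5 * se).all()
        assert abs(rates.mean() - 0.5) < 3 * se / math.sqrt(50)


class TestPairActive:
    def test_two_mutual_neighbors(self, rng):
        net = net_from_edges(2, [(0, 1)])
        pairs = pair_active(net, np.array([True, True]), rng)
        assert len(pairs) == 1 and set(pairs[0]) == {0, 1}

    def test_no_internal_edges(self, rng):
        net = net_from_edges(4, [(0, 1)])
        active = np.array([True, False, True, True])  # 0 active but 1 not
        assert pair_active(net, active, rng) == []

    def test_unmatched_agents_receive_nothing(self):
        cfg = SimulationConfig(n_agents=30, n_rounds=40, seed=5)
        res = run_simulation(cfg)
        per_round = res.records.groupby("round").size()
        assert (per_round <= cfg.n_agents // 2).all()

    def test_path_graph_matches_enumeration(self):
        """Matching frequencies on the path A-B-C agree with brute-force
        enumeration of the seeded procedure (orderings x uniform picks)."""
        # enumeration: visit orders are uniform; each agent picks uniformly
        # among unmatched active neighbors
        outcomes = {}
        for order in itertools.permutations(range(3)):
            for first_choice in ({0, 2} if order[0] == 1 else {1}):
                pair = frozenset({order[0], first_choice})
                weight = (1 / 6) * (0.5 if order[0] == 1 else 1.0)
                outcomes[pair] = outcomes.get(pair, 0.0) + weight
        assert outcomes[frozenset({0, 1})] == pytest.approx(0.5)

        net = net_from_edges(3, [(0, 1), (1, 2)])
        active = np.ones(3, dtype=bool)
        n = 4000
        count_01 = 0
        for seed in range(n):
            pairs = pair_active(net, active, np.random.default_rng(seed))
            assert len(pairs) == 1
            assert 1 in pairs[0]  # the middle node is always matched
            if set(pairs[0]) == {0, 1}:
                count_01 += 1
        se = math.sqrt(0.25 / n)
        assert abs(count_01 / n - 0.5) < 4 * se


class TestRunInteraction:
    def test_cold_start_hand_trace(self):
        """Two rational cold-start agents cooperate at 0.5, feel nothing,
        and split the bilinear midpoint payoff."""
        cfg = SimulationConfig(
            n_agents=2,
            n_rounds=1,
            proportions={"rational": 1.0},
            drive_override=1.0,
            cold_start=0.5,
            seed=0,
        )
        res = run_simulation(cfg)
        assert len(res.records) == 1
        rec = res.records.iloc[0]
        assert rec["c_a"] == rec["c_b"] == 0.5
        assert rec["payoff_a"] == rec["payoff_b"] == pytest.approx(2.5)
        assert rec["emotion_a"] == rec["emotion_b"] == pytest.approx(0.0)

    def test_manic_overestimation(self):
        cfg = SimulationConfig(
            n_agents=2,
            n_rounds=1,
            proportions={"rational": 0.5, "manic": 0.5},
            beta_override={"manic": 10.0},
            drive_override=1.0,
            cold_start=0.5,
            seed=0,
        )
        res = run_simulation(cfg)
        rec = res.records.iloc[0]
        emotions = {rec["id_a"]: rec["emotion_a"], rec["id_b"]: rec["emotion_b"]}
        manic_id = next(ag.id for ag in res.agents if ag.agent_type == "manic")
        rational_id = 1 - manic_id
        assert emotions[manic_id] == pytest.approx(math.tanh(4.5), abs=1e-9)
        assert emotions[rational_id] == pytest.approx(0.0, abs=1e-12)

    def test_payoffs_recomputable_from_log(self, tiny_config):
        res = run_simulation(tiny_config)
        k = tiny_config.payoff
        for rec in res.records.itertuples():
            assert rec.payoff_a == pytest.approx(cpd_payoff(rec.c_a, rec.c_b, k), abs=1e-12)
            assert rec.payoff_b == pytest.approx(cpd_payoff(rec.c_b, rec.c_a, k), abs=1e-12)

    def test_non_adjacent_pair_is_internal_error(self, tiny_config):
        sim = Simulation(tiny_config)
        i, j = 0, 1
        while sim.network.adj[i, j]:
            j += 1
        with pytest.raises(RuntimeError):
            sim.run_interaction(i, j, 1)


class TestBroadcast:
    def test_gist_counts(self):
        # A(0) has 3 other neighbors, B(5) has 2: 5 gists total
        edges = [(0, 1), (0, 2), (0, 3), (0, 5), (5, 4), (5, 6)]
        net = net_from_edges(7, edges)
        cfg = SimulationConfig(n_agents=7, proportions={"rational": 1.0})
        from moodsim.population import spawn_population

        agents = spawn_population(cfg, np.random.default_rng(0))
        sim_rec = None
        from moodsim.engine import InteractionRecord

        sim_rec = InteractionRecord(3, 0, 5, 0.4, 0.7, 0.0, 0.0, 0.0, 0.0)
        count = broadcast(sim_rec, agents, net, 3)
        assert count == 5
        # recipients store the counterpart's level with neutral emotion at
        # intercept strength (rational recipients perceive it unchanged)
        tr = agents[1].memory.all_traces()[0]
        assert tr.counterpart_id == 5 and tr.cooperation == 0.7
        assert tr.emotion == 0.0
        assert tr.initial_strength == agents[1].mem_params.intercept
        assert not tr.firsthand
        # B's other neighbors heard about A
        tr4 = agents[4].memory.all_traces()[0]
        assert tr4.counterpart_id == 0 and tr4.cooperation == 0.4

    def test_isolated_participants_produce_no_gists(self):
        net = net_from_edges(2, [(0, 1)])
        cfg = SimulationConfig(n_agents=2, proportions={"rational": 1.0})
        from moodsim.population import spawn_population
        from moodsim.engine import InteractionRecord

        agents = spawn_population(cfg, np.random.default_rng(0))
        rec = InteractionRecord(1, 0, 1, 0.5, 0.5, 2.5, 2.5, 0.0, 0.0)
        assert broadcast(rec, agents, net, 1) == 0

    def test_lazy_materialization_equals_eager_broadcast(self):
        """The engine's deferred gist delivery yields exactly the gists an
        eager per-record broadcast would have written (manic society with
        saturated moods so no gist is ever retrieved/refreshed)."""
        cfg = SimulationConfig(
            n_agents=12,
            n_rounds=30,
            proportions={"manic": 1.0},
            beta_override={"manic": 5.0},
            broadcast=True,
            seed=9,
        ).with_memory(forget_rate=1e-4, mood_dependence=10.0)
        sim = Simulation(cfg)
        res = sim.run()
        # force-sync every pair at a common later time
        t_end = cfg.n_rounds + 1
        lazy = {}
        for x in range(cfg.n_agents):
            for y in range(cfg.n_agents):
                if x == y:
                    continue
                store = sim.agents[x].memory.store_for(y)
                sim._sync_gists(x, y, store, t_end)
                gists = [
                    (round(float(store.coop[i]), 12), int(store.encoded_at[i]))
                    for i in range(store.n)
                    if not store.firsthand[i]
                ]
                lazy[(x, y)] = sorted(gists)
        # eager replay of the event log
        eager_agents = [
            dataclasses.replace(ag, memory=AgentMemory()) for ag in sim.agents
        ]
        from moodsim.engine import InteractionRecord

        for rec in res.records.itertuples(index=False):
            record = InteractionRecord(*rec)
            broadcast(record, eager_agents, sim.network, record.round)
        for x in range(cfg.n_agents):
            for y in range(cfg.n_agents):
                if x == y:
                    continue
                store = eager_agents[x].memory.stores.get(y)
                gists = []
                if store is not None:
                    gists = [
                        (round(float(store.coop[i]), 12), int(store.encoded_at[i]))
                        for i in range(store.n)
                        if not store.firsthand[i]
                    ]
                assert sorted(gists) == lazy[(x, y)], (x, y)


class TestRunSimulation:
    def test_single_pair_single_round(self):
        cfg = SimulationConfig(
            n_agents=2,
            n_rounds=1,
            proportions={"rational": 1.0},
            drive_override=1.0,
            cold_start=0.5,
            seed=1,
        )
        res = run_simulation(cfg)
        assert len(res.records) == 1
        assert res.agents[0].cumulative_payoff == pytest.approx(2.5)

    def test_determinism_byte_identical_logs(self, tiny_config, tmp_path):
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        run_simulation(tiny_config).write_event_log(p1)
        run_simulation(tiny_config).write_event_log(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert len(p1.read_bytes()) > 0

    def test_payoff_ledger_conservation(self, tiny_config):
        res = run_simulation(tiny_config)
        totals = np.zeros(tiny_config.n_agents)
        np.add.at(totals, res.records["id_a"].to_numpy(), res.records["payoff_a"].to_numpy())
        np.add.at(totals, res.records["id_b"].to_numpy(), res.records["payoff_b"].to_numpy())
        online = np.array([ag.cumulative_payoff for ag in res.agents])
        assert np.allclose(totals, online, rtol=1e-12, atol=1e-9)
        counts = np.zeros(tiny_config.n_agents, dtype=int)
        np.add.at(counts, res.records["id_a"].to_numpy(), 1)
        np.add.at(counts, res.records["id_b"].to_numpy(), 1)
        assert (counts == [ag.n_interactions for ag in res.agents]).all()

    def test_interactions_only_between_neighbors_once_per_round(self, tiny_config):
        sim = Simulation(tiny_config)
        res = sim.run()
        for rec in res.records.itertuples():
            assert sim.network.adj[rec.id_a, rec.id_b]
        per_round = {}
        for rec in res.records.itertuples():
            seen = per_round.setdefault(rec.round, set())
            assert rec.id_a not in seen and rec.id_b not in seen
            seen.update((rec.id_a, rec.id_b))

    def test_mood_bounds_and_bipolar_tracking(self):
        """Moods stay in [-1, 1] every round and bipolar sensitivity
        tracks the piecewise map of the clamped rhythm mood exactly."""
        cfg = SimulationConfig(n_agents=40, n_rounds=120, seed=13)
        sim = Simulation(cfg)

        def audit(s, t):
            assert (np.abs(s.mood) <= 1.0).all()
            ids = s.bipolar_ids
            expected_mood = np.clip(np.sin(s.omega[ids] * t) + s.offset[ids], -1, 1)
            assert np.allclose(s.mood[ids], expected_mood)
            expected_beta = np.where(
                expected_mood < 0, expected_mood + 1, 1 + expected_mood * 9
            )
            assert np.allclose(s.beta[ids], expected_beta)
            rational = [ag.id for ag in s.agents if ag.agent_type == "rational"]
            assert (s.mood[rational] == 0.0).all()
            assert (s.beta[rational] == 1.0).all()

        sim.run(on_round=audit)

    def test_omega_resampled_on_schedule(self):
        cfg = SimulationConfig(n_agents=30, n_rounds=101, seed=3, omega_resample_every=50)
        sim = Simulation(cfg)
        seen = {}

        def watch(s, t):
            seen[t] = s.omega[s.bipolar_ids].copy()

        sim.run(on_round=watch)
        assert np.array_equal(seen[49], seen[1])
        assert not np.array_equal(seen[50], seen[49])
        assert np.array_equal(seen[99], seen[50])
        assert not np.array_equal(seen[100], seen[99])

    def test_cumulative_payoff_non_decreasing(self, tiny_config):
        sim = Simulation(tiny_config)
        prev = np.zeros(tiny_config.n_agents)

        def watch(s, t):
            nonlocal prev
            assert (s.payoffs >= prev - 1e-12).all()
            prev = s.payoffs.copy()

        sim.run(on_round=watch)

    def test_summary_contents(self, tiny_config):
        res = run_simulation(tiny_config)
        df = res.summary()
        assert len(df) == tiny_config.n_agents
        assert set(df["type"]) <= {"rational", "manic", "depressed", "bipolar"}
        assert (df["cumulative_payoff"] >= 0).all()
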