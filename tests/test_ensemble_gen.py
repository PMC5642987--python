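"""Sweep driver, built-in heuristic and planted-structure generators."""

import itertools

import numpy as np
import pytest

from champ.champ_1d import champ_prune_1d
from champ.ensemble_gen import (
    PlantedConfig,
    SweepConfig,
    builtin_heuristic,
    planted_multilayer,
    planted_partition_graph,
    run_sweep,
)
from champ.partition_core import (
    Network,
    canonicalize,
    compute_coefficients,
    compute_multilayer_coefficients,
)


class TestBuiltinHeuristic:
    def test_two_triangles_is_exhaustive_maximum(self, two_triangles):
        """Greedy search finds the partition an exhaustive scan proves optimal."""
        best_q, best_part = -np.inf, None
        for raw in itertools.product(range(3), repeat=6):
            part = canonicalize(list(raw))
            rec = compute_coefficients(two_triangles, part)
            q = rec.a_hat - rec.p_hat
            if q > best_q + 1e-12:
                best_q, best_part = q, part
        found = canonicalize(builtin_heuristic(two_triangles, 1.0, seed=4))
        assert found == best_part
        assert found.membership == (0, 0, 0, 1, 1, 1)

    def test_gamma_zero_reaches_max_a_hat(self, two_triangles, k3):
        for net in (two_triangles, k3):
            part = canonicalize(builtin_heuristic(net, 0.0, seed=1))
            rec = compute_coefficients(net, part)
            assert rec.a_hat == 2.0 * net.total_weight  # no inter-community edges left

    def test_seed_reproducibility(self, two_triangles):
        m1 = builtin_heuristic(two_triangles, 1.0, seed=9)
        m2 = builtin_heuristic(two_triangles, 1.0, seed=9)
        assert m1 == m2

    def test_never_decreases_quality(self):
        rng = np.random.default_rng(44)
        cfg = PlantedConfig(n_nodes=40, n_blocks=3, p_in=0.6, p_out=0.1)
        net, _ = planted_partition_graph(cfg, seed=5)
        for gamma in (0.5, 1.0, 2.0):
            part = canonicalize(builtin_heuristic(net, gamma, seed=int(rng.integers(100))))
            rec = compute_coefficients(net, part)
            singles = compute_coefficients(net, canonicalize(list(range(40))))
            assert rec.modularity(gamma) >= singles.modularity(gamma) - 1e-9

    def test_multilayer_coupling_promotes_spanning(self):
        cfg = PlantedConfig(
            n_nodes=12, n_blocks=2, p_in=1.0, p_out=0.0, n_layers=3,
            persistence=1.0, coupling_weight=1.0,
        )
        net, truth = planted_multilayer(cfg, seed=1)
        part = canonicalize(builtin_heuristic(net, 1.0, omega=1.0, seed=2))
        assert part == truth  # blocks persist, coupling glues them across layers
        rec = compute_multilayer_coefficients(net, part)
        assert rec.c_hat > 0


class TestRunSweep:
    def test_deterministic_stub_yields_single_partition(self, k3):
        # stub ignores parameters and returns the same (permutation-invariant)
        # partition every run: dedup collapses the whole sweep to one entry
        stub = lambda net, gamma, omega, seed: [0] * net.n_nodes
        cfg = SweepConfig(gammas=np.linspace(0, 2, 5), runs_per_point=4, heuristic=stub)
        ens = run_sweep(k3, cfg)
        assert len(ens) == 1
        assert ens.multiplicities == [20]

    def test_dedup_upper_bound(self, two_triangles):
        cfg = SweepConfig(gammas=np.linspace(0, 2, 5), runs_per_point=10, seed=3)
        ens = run_sweep(two_triangles, cfg)
        assert len(ens) <= 50
        assert ens.n_runs == 50
        assert sum(ens.multiplicities) == 50

    def test_full_reproducibility(self, two_triangles):
        cfg = SweepConfig(gammas=np.linspace(0, 3, 4), runs_per_point=3, seed=11)
        e1 = run_sweep(two_triangles, cfg)
        e2 = run_sweep(two_triangles, cfg)
        assert [p.membership for p in e1.partitions] == [p.membership for p in e2.partitions]
        assert e1.multiplicities == e2.multiplicities

    def test_wrong_length_membership_names_grid_point(self, k3):
        bad = lambda net, gamma, omega, seed: [0, 0]
        cfg = SweepConfig(gammas=[1.5], heuristic=bad)
        with pytest.raises(ValueError, match="gamma=1.5"):
            run_sweep(k3, cfg)

    def test_planted_partition_recovered_in_sweep(self):
        cfg = PlantedConfig(n_nodes=80, n_blocks=4, p_in=0.9, p_out=0.05)
        net, truth = planted_partition_graph(cfg, seed=42)
        sweep = SweepConfig(gammas=np.linspace(0.5, 1.5, 20), runs_per_point=10, seed=7)
        ens = run_sweep(net, sweep)
        assert truth.membership in {p.membership for p in ens.partitions}


class TestPlantedPartitionGraph:
    def test_disconnected_blocks_at_extreme_probabilities(self):
        import networkx as nx

        cfg = PlantedConfig(n_nodes=30, n_blocks=3, p_in=1.0, p_out=0.0)
        net, truth = planted_partition_graph(cfg, seed=0)
        g = nx.Graph()
        g.add_nodes_from(range(30))
        g.add_edges_from((u, v) for u, v, _ in net.edges)
        comps = [frozenset(c) for c in nx.connected_components(g)]
        blocks = {
            frozenset(np.flatnonzero(truth.as_array() == b))
            for b in range(truth.n_communities)
        }
        assert set(comps) == blocks

    def test_edge_count_matches_binomial_mean(self):
        p = 0.3
        cfg = PlantedConfig(n_nodes=40, n_blocks=4, p_in=p, p_out=p)
        n_pairs = 40 * 39 // 2
        counts = [
            len(planted_partition_graph(cfg, seed=s)[0].edges) for s in range(100)
        ]
        mean = np.mean(counts)
        se = np.sqrt(n_pairs * p * (1 - p) / 100)
        assert abs(mean - n_pairs * p) < 3 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PlantedConfig(n_nodes=10, n_blocks=0, p_in=0.5, p_out=0.1)
        with pytest.raises(ValueError):
            PlantedConfig(n_nodes=10, n_blocks=2, p_in=0.1, p_out=0.5)


class TestPlantedMultilayer:
    def test_full_persistence_spans_layers(self):
        cfg = PlantedConfig(
            n_nodes=20, n_blocks=2, p_in=0.9, p_out=0.1, n_layers=3, persistence=1.0
        )
        net, truth = planted_multilayer(cfg, seed=2)
        labels = truth.as_array().reshape(3, 20)
        assert (labels == labels[0]).all()
        assert truth.n_communities == 2

    def test_zero_persistence_zero_coupling_independent_layers(self):
        cfg = PlantedConfig(
            n_nodes=20, n_blocks=2, p_in=0.9, p_out=0.1, n_layers=3,
            persistence=0.0, coupling_weight=0.0,
        )
        net, _ = planted_multilayer(cfg, seed=3)
        assert net.interlayer_edges == []

    def test_minimal_fixture_matches_hand_built(self, ml_2x2):
        cfg = PlantedConfig(n_nodes=2, n_blocks=1, p_in=1.0, p_out=0.0, n_layers=2)
        net, truth = planted_multilayer(cfg, seed=0)
        assert net.intralayer_edges == ml_2x2.intralayer_edges
        assert net.interlayer_edges == ml_2x2.interlayer_edges
        assert net.layer_of.tolist() == ml_2x2.layer_of.tolist()
        assert truth.n_communities == 1


class TestRecoveryThroughPruning:
    def test_truth_admissible_with_domain_containing_gamma_one(self):
        cfg = PlantedConfig(n_nodes=80, n_blocks=4, p_in=0.9, p_out=0.05)
        net, truth = planted_partition_graph(cfg, seed=42)
        sweep = SweepConfig(gammas=np.linspace(0.5, 1.5, 20), runs_per_point=10, seed=7)
        ens = run_sweep(net, sweep)
        env = champ_prune_1d(ens.records, gamma_start=0.0, gamma_end=4.0)
        by_id = ens.partition_by_id()
        truth_domains = [
            d for d in env.domains if by_id[d.partition_id].membership == truth.membership
        ]
        assert len(truth_domains) == 1
        d = truth_domains[0]
        assert d.gamma_lo <= 1.0 < d.gamma_hi
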