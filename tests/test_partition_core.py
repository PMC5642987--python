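"""Canonical partitions and coefficient reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from champ.partition_core import (
    CoefficientRecord,
    MultilayerNetwork,
    Network,
    canonicalize,
    compute_coefficients,
    compute_multilayer_coefficients,
    deduplicate,
    modularity_at,
    normalized_modularity,
    permute_nodes,
)
from conftest import brute_coefficients, brute_multilayer_coefficients


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            (["b", "b", "a"], (0, 0, 1)),
            ([0, 0, 1], (0, 0, 1)),
            ([5, 3, 5, 3], (0, 1, 0, 1)),
            ([1, 0, 1, 0], (0, 1, 0, 1)),
        ],
    )
    def test_first_appearance_relabeling(self, raw, expected):
        assert canonicalize(raw).membership == expected

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty partition"):
            canonicalize([])

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=30))
    @settings(deadline=None)
    def test_idempotent_and_comembership_preserving(self, raw):
        p1 = canonicalize(raw)
        p2 = canonicalize(list(p1.membership))
        assert p1 == p2
        c = p1.as_array()
        for i in range(len(raw)):
            for j in range(len(raw)):
                assert (raw[i] == raw[j]) == (c[i] == c[j])


class TestCoefficients:
    def test_k3_one_community_equals_2m(self, k3):
        rec = compute_coefficients(k3, canonicalize([0, 0, 0]))
        assert (rec.a_hat, rec.p_hat) == (6.0, 6.0)

    def test_k3_singletons(self, k3):
        rec = compute_coefficients(k3, canonicalize([0, 1, 2]))
        assert (rec.a_hat, rec.p_hat) == (0.0, 2.0)

    def test_star_mixed_partition(self, star4):
        rec = compute_coefficients(star4, canonicalize([0, 0, 1, 2]))
        assert rec.a_hat == 2.0
        assert rec.p_hat == pytest.approx(3.0, abs=1e-12)

    def test_length_mismatch_and_zero_weight_errors(self, k3):
        with pytest.raises(ValueError, match="does not match"):
            compute_coefficients(k3, canonicalize([0, 0]))
        empty = Network(2, [(0, 1, 0.0)])
        with pytest.raises(ValueError, match="m = 0"):
            compute_coefficients(empty, canonicalize([0, 1]))

    def test_matches_double_loop_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 50))
            mask = np.triu(rng.random((n, n)) < 0.2)
            edges = [
                (i, j, float(rng.uniform(0.5, 3.0)))
                for i, j in zip(*np.nonzero(mask))
            ]
            if not edges:
                continue
            net = Network(n, edges)  # may include self-loops (i == j on diagonal)
            part = canonicalize(rng.integers(0, 5, n).tolist())
            rec = compute_coefficients(net, part)
            a_b, p_b = brute_coefficients(net, part)
            assert rec.a_hat == pytest.approx(a_b, rel=1e-12)
            assert rec.p_hat == pytest.approx(p_b, rel=1e-12)

    def test_refinement_never_increases_sums(self):
        rng = np.random.default_rng(8)
        n = 30
        mask = np.triu(rng.random((n, n)) < 0.3, k=1)
        net = Network(n, [(i, j, 1.0) for i, j in zip(*np.nonzero(mask))])
        coarse = canonicalize(rng.integers(0, 3, n).tolist())
        # split community 0 into two
        split_raw = coarse.as_array().copy()
        members = np.flatnonzero(split_raw == 0)
        split_raw[members[: len(members) // 2]] = coarse.n_communities
        fine = canonicalize(split_raw.tolist())
        rc = compute_coefficients(net, coarse)
        rf = compute_coefficients(net, fine)
        assert rf.a_hat <= rc.a_hat
        assert rf.p_hat <= rc.p_hat

    def test_normalized_matches_networkx_modularity(self):
        import networkx as nx

        rng = np.random.default_rng(13)
        for _ in range(5):
            g = nx.gnp_random_graph(60, 0.1, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            net = Network(60, [(u, v, 1.0) for u, v in g.edges()])
            part = canonicalize(rng.integers(0, 4, 60).tolist())
            rec = compute_coefficients(net, part)
            comms = [set(np.flatnonzero(part.as_array() == c)) for c in range(part.n_communities)]
            expected = nx.algorithms.community.modularity(g, comms)
            assert normalized_modularity(rec, net, gamma=1.0) == pytest.approx(
                expected, rel=1e-12, abs=1e-12
            )

    def test_invariant_under_node_and_label_permutation(self, star4):
        rng = np.random.default_rng(2)
        part = canonicalize([0, 0, 1, 2])
        rec = compute_coefficients(star4, part)
        perm = rng.permutation(4)
        pnet = permute_nodes(star4, perm)
        pm = part.as_array()[perm]  # node j of pnet is old node perm[j]
        prec = compute_coefficients(pnet, canonicalize(pm.tolist()))
        assert (prec.a_hat, prec.p_hat) == (rec.a_hat, rec.p_hat)


class TestMultilayerCoefficients:
    @pytest.mark.parametrize(
        "membership,expected",
        [
            ([0, 0, 0, 0], (4.0, 4.0, 4.0)),
            ([0, 0, 1, 1], (4.0, 4.0, 0.0)),
            ([0, 1, 2, 3], (0.0, 2.0, 0.0)),
        ],
    )
    def test_worked_fixture(self, ml_2x2, membership, expected):
        rec = compute_multilayer_coefficients(ml_2x2, canonicalize(membership))
        assert (rec.a_hat, rec.p_hat, rec.c_hat) == expected

    def test_matches_double_loop_on_random_multilayer(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n_per, L = int(rng.integers(3, 8)), int(rng.integers(2, 4))
            layer_of = np.repeat(np.arange(L), n_per)
            n = n_per * L
            intra, inter = [], []
            for i in range(n):
                for j in range(i + 1, n):
                    if layer_of[i] == layer_of[j] and rng.random() < 0.5:
                        intra.append((i, j, float(rng.uniform(0.5, 2))))
                    elif layer_of[i] != layer_of[j] and rng.random() < 0.1:
                        inter.append((i, j, float(rng.uniform(0.5, 2))))
            if not intra:
                continue
            net = MultilayerNetwork(intra, inter, layer_of)
            part = canonicalize(rng.integers(0, 4, n).tolist())
            rec = compute_multilayer_coefficients(net, part)
            a_b, p_b, c_b = brute_multilayer_coefficients(net, part)
            assert rec.a_hat == pytest.approx(a_b, rel=1e-12)
            assert rec.p_hat == pytest.approx(p_b, rel=1e-12)
            assert rec.c_hat == pytest.approx(c_b, rel=1e-12)

    def test_edge_layer_validation(self):
        with pytest.raises(ValueError, match="spans layers"):
            MultilayerNetwork([(0, 2, 1.0)], [], [0, 0, 1, 1])
        with pytest.raises(ValueError, match="within a layer"):
            MultilayerNetwork([], [(0, 1, 1.0)], [0, 0, 1, 1])
        with pytest.raises(ValueError, match="unknown state nodes"):
            MultilayerNetwork([(0, 9, 1.0)], [], [0, 0, 1, 1])


class TestModularityAt:
    @pytest.mark.parametrize(
        "rec,gamma,omega,expected",
        [
            (CoefficientRecord(6, 6, 0), 1.0, 0.0, 0.0),
            (CoefficientRecord(2, 3, 0), 0.0, 0.0, 2.0),
            (CoefficientRecord(4, 3, 1), 1.0, 2.0, 3.0),
        ],
    )
    def test_affine_evaluation(self, rec, gamma, omega, expected):
        assert modularity_at(rec, gamma, omega) == expected


class TestDeduplicate:
    def test_relabeling_collapse(self):
        uniq = deduplicate([[0, 0, 1], [1, 1, 0], [0, 1, 1]])
        assert len(uniq) == 2
        assert uniq.multiplicities == [2, 1]
        assert uniq.partitions[0].membership == (0, 0, 1)

    def test_empty_input(self):
        assert len(deduplicate([])) == 0

    def test_multiplicity_counting(self):
        uniq = deduplicate([[0, 1, 0]] * 100)
        assert len(uniq) == 1
        assert uniq.multiplicities == [100]

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed lengths"):
            deduplicate([[0, 1], [0, 1, 2]])
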