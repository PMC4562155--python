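"""Cliff detection, degree-preserving randomization, and permutation p-values."""

from __future__ import annotations

import numpy as np
import pytest

from ppicliffs.cliffs import (
    KnowledgeCliff,
    PermutationConfig,
    cliff_pvalue,
    degree_preserving_randomize,
    detect_knowledge_cliffs,
    estimate_edge_probabilities,
    test_cliffs as run_permutation_test,
)

from conftest import brute_force_cliffs, random_weighted_digraph, weighted_network


class TestDetector:
    def test_toy_network_single_cliff(self, toy_cliff_network):
        found = detect_knowledge_cliffs(toy_cliff_network, c=0.75)
        assert [cl.chain for cl in found] == [("A", "B", "C")]
        assert found[0].drop == pytest.approx(0.85)

    def test_toy_network_high_threshold_empty(self, toy_cliff_network):
        assert detect_knowledge_cliffs(toy_cliff_network, c=0.90) == []

    def test_no_two_paths_means_no_cliffs(self):
        net = weighted_network({("A", "B"): 1.0, ("C", "D"): 0.0})
        assert detect_knowledge_cliffs(net, c=0.5) == []

    def test_zero_weight_edges_never_qualify(self):
        net = weighted_network({("A", "B"): 1.0, ("B", "C"): 0.0, ("C", "D"): 0.4})
        assert detect_knowledge_cliffs(net, c=0.5) == []

    def test_threshold_range_enforced_unless_forced(self, toy_cliff_network):
        with pytest.raises(ValueError, match=r"0\.1"):
            detect_knowledge_cliffs(toy_cliff_network, c=1.5)
        assert detect_knowledge_cliffs(toy_cliff_network, c=0.05, force=True)

    def test_sorted_by_drop_then_chain(self):
        net = weighted_network(
            {("A", "B"): 1.0, ("B", "C"): 0.1, ("B", "D"): 0.2, ("E", "B"): 1.0}
        )
        found = detect_knowledge_cliffs(net, c=0.5)
        drops = [cl.drop for cl in found]
        assert drops == sorted(drops, reverse=True)
        assert [cl.chain for cl in found] == [
            ("A", "B", "C"), ("E", "B", "C"), ("A", "B", "D"), ("E", "B", "D")]

    def test_matches_brute_force_on_random_digraphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n = int(rng.integers(4, 30))
            net = random_weighted_digraph(rng, n, edge_prob=float(rng.uniform(0.05, 0.4)))
            c = float(rng.uniform(0.1, 0.99))
            got = {cl.chain for cl in detect_knowledge_cliffs(net, c=c)}
            assert got == brute_force_cliffs(net, c)

    def test_lowering_threshold_never_removes_cliffs(self):
        rng = np.random.default_rng(7)
        net = random_weighted_digraph(rng, 20, 0.2)
        previous: set = set()
        for c in [0.9, 0.7, 0.5, 0.3, 0.1]:
            current = {cl.chain for cl in detect_knowledge_cliffs(net, c=c)}
            assert previous <= current
            previous = current


class TestRandomization:
    def degrees(self, edges):
        out_d, in_d = {}, {}
        for s, t in edges:
            out_d[s] = out_d.get(s, 0) + 1
            in_d[t] = in_d.get(t, 0) + 1
        return out_d, in_d

    def test_exact_degree_preservation_every_draw(self):
        rng = np.random.default_rng(3)
        net = random_weighted_digraph(rng, 15, 0.25)
        orig = list(net.edges)
        for _ in range(50):
            shuffled = degree_preserving_randomize(net, rng)
            assert len(shuffled) == len(orig)
            assert self.degrees(shuffled) == self.degrees(orig)
            assert all(s != t for s, t in shuffled)  # simple digraph: no loops

    def test_two_edge_graph_only_two_outcomes(self):
        net = weighted_network({("A", "B"): 0.5, ("C", "D"): 0.5})
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(200):
            seen.add(frozenset(degree_preserving_randomize(net, rng)))
        assert seen == {
            frozenset({("A", "B"), ("C", "D")}),
            frozenset({("A", "D"), ("C", "B")}),
        }

    def test_fixed_seed_reproducible(self):
        rng_a = np.random.default_rng(99)
        rng_b = np.random.default_rng(99)
        net = random_weighted_digraph(np.random.default_rng(1), 12, 0.3)
        assert degree_preserving_randomize(net, rng_a) == degree_preserving_randomize(net, rng_b)

    def test_unswappable_network_returned_unchanged_with_warning(self):
        net = weighted_network({("A", "B"): 0.5, ("B", "A"): 0.5})
        with pytest.warns(UserWarning, match="no admissible"):
            out = degree_preserving_randomize(net, np.random.default_rng(0))
        assert out == {("A", "B"), ("B", "A")}


class TestEdgeProbabilities:
    def test_two_edge_toy_probability_near_half(self):
        net = weighted_network({("A", "B"): 0.5, ("C", "D"): 0.5})
        cfg = PermutationConfig(n_randomizations=10_000, seed=1)
        probs = estimate_edge_probabilities(net, cfg)
        # exact enumeration of this degree sequence gives P(A->B) = 1/2;
        # 3 binomial sigma at n = 10,000 is 0.015
        sigma3 = 3 * np.sqrt(0.25 / 10_000)
        assert probs[("A", "B")] == pytest.approx(0.5, abs=sigma3)
        assert probs[("C", "D")] == pytest.approx(0.5, abs=sigma3)

    def test_forced_edge_has_probability_one(self):
        # A->B plus B->A: no admissible swap exists, both edges always persist
        net = weighted_network({("A", "B"): 0.5, ("B", "A"): 0.5})
        cfg = PermutationConfig(n_randomizations=200, seed=2)
        probs = estimate_edge_probabilities(net, cfg)
        assert probs[("A", "B")] == 1.0

    def test_probabilities_in_unit_interval_and_positive(self):
        net = random_weighted_digraph(np.random.default_rng(4), 10, 0.3)
        probs = estimate_edge_probabilities(net, PermutationConfig(200, seed=3))
        assert all(0.0 < p <= 1.0 for p in probs.values())

    def test_invariant_to_node_relabeling(self):
        net = random_weighted_digraph(np.random.default_rng(8), 8, 0.35)
        mapping = {n: f"X_{n}" for n in net.nodes}
        relabeled = net.relabel(mapping)
        cfg = PermutationConfig(n_randomizations=500, seed=5)
        p1 = estimate_edge_probabilities(net, cfg)
        p2 = estimate_edge_probabilities(relabeled, cfg)
        for (s, t), p in p1.items():
            assert p2[(mapping[s], mapping[t])] == pytest.approx(p)


class TestCliffPValues:
    def make_cliff(self, chain=("I", "J", "K")):
        return KnowledgeCliff(chain=chain, w_ij=0.9, w_jk=0.1, threshold_c=0.75)

    @pytest.mark.parametrize(
        "p_ij, p_jk, expected",
        [(0.1, 0.2, 0.02), (1.0, 1.0, 1.0), (0.5, 0.5, 0.25)],
    )
    def test_product_rule(self, p_ij, p_jk, expected):
        probs = {("I", "J"): p_ij, ("J", "K"): p_jk}
        assert cliff_pvalue(self.make_cliff(), probs) == pytest.approx(expected)

    def test_longer_chain_multiplies_all_edges(self):
        cl = KnowledgeCliff(chain=("I", "J", "K", "L"), w_ij=0.9, w_jk=0.1,
                            threshold_c=0.75)
        probs = {("I", "J"): 0.5, ("J", "K"): 0.5, ("K", "L"): 0.5}
        assert cliff_pvalue(cl, probs) == pytest.approx(0.125)

    def test_missing_edge_rejected(self):
        with pytest.raises(KeyError):
            cliff_pvalue(self.make_cliff(), {("I", "J"): 0.5})

    def test_annotation_flags_and_determinism(self, toy_cliff_network):
        found = detect_knowledge_cliffs(toy_cliff_network, c=0.75)
        cfg = PermutationConfig(n_randomizations=300, seed=42)
        ann1, rep1 = run_permutation_test(toy_cliff_network, found, cfg, alpha=0.05)
        ann2, rep2 = run_permutation_test(toy_cliff_network, found, cfg, alpha=0.05)
        assert ann1 == ann2 and rep1 == rep2
        assert all(cl.p_value is not None and 0 < cl.p_value <= 1 for cl in ann1)
        for cl in ann1:
            assert cl.significant is (cl.p_value < 0.05)

    def test_ubiquitous_edges_not_significant(self):
        # reciprocal pair is frozen under the null -> probabilities 1, p = 1
        net = weighted_network({("A", "B"): 1.0, ("B", "A"): 0.05})
        cliff = KnowledgeCliff(chain=("A", "B", "A"), w_ij=1.0, w_jk=0.05,
                               threshold_c=0.75)
        ann, _ = run_permutation_test(net, [cliff], PermutationConfig(100, seed=1))
        assert ann[0].p_value == pytest.approx(1.0)
        assert ann[0].significant is False
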