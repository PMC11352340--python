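"""Hypergeometric over-representation and candidate interaction networks."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligosig.enrichment import build_candidate_network, enrich, expand_network


def tail_enumeration(N, K, n, k) -> float:
    """Brute-force P(X >= k) for X ~ Hypergeom(N, K, n)."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestEnrich:
    def universe(self, n):
        return {f"U{i}" for i in range(n)}

    def test_perfect_overlap_closed_form(self):
        uni = self.universe(20)
        gene_set = {f"U{i}" for i in range(5)}
        results = enrich(gene_set, {"s": gene_set}, uni)
        assert results[0].p_value == pytest.approx(1 / math.comb(20, 5))

    def test_zero_overlap_p_one(self):
        uni = self.universe(20)
        results = enrich({"U0", "U1"}, {"s": {"U10", "U11"}}, uni)
        assert results[0].p_value == 1.0

    def test_ease_decrements_overlap(self):
        uni = self.universe(20)
        res_f = enrich({"U0"}, {"s": {"U0"}}, uni, variant="fisher")
        res_e = enrich({"U0"}, {"s": {"U0"}}, uni, variant="ease")
        assert res_f[0].p_value < 1.0
        assert res_e[0].p_value == 1.0  # overlap 1 evaluated at 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enrich(set(), {}, set())

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            enrich({"X"}, {}, {"U0"})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_matches_tail_enumeration_on_small_universes(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 31))
        uni = [f"U{i}" for i in range(N)]
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        gene_set = list(rng.choice(uni, size=K, replace=False))
        query = list(rng.choice(uni, size=n, replace=False))
        k = len(set(gene_set) & set(query))
        [res] = enrich(query, {"s": gene_set}, uni)
        expected = tail_enumeration(N, K, n, k) if k > 0 else 1.0
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_bh_q_values_monotone_in_p_order(self):
        rng = np.random.default_rng(5)
        uni = [f"U{i}" for i in range(30)]
        sets = {
            f"s{j}": list(rng.choice(uni, size=int(rng.integers(2, 12)), replace=False))
            for j in range(12)
        }
        query = list(rng.choice(uni, size=8, replace=False))
        results = enrich(query, sets, uni)
        ps = [r.p_value for r in results]
        qs = [r.q_value for r in results]
        assert ps == sorted(ps)
        assert all(b >= a for a, b in zip(qs, qs[1:]))
        assert all(q >= p for p, q in zip(ps, qs))


class TestNetwork:
    def test_single_edge_spans_two_cases(self):
        net = build_candidate_network(
            {"case1": ["A"], "case2": ["B"]}, [("A", "B", "curated")]
        )
        assert net.components == [frozenset({"A", "B"})]
        assert net.component_cases() == [{"case1", "case2"}]

    def test_no_edges_no_components(self):
        net = build_candidate_network({"case1": ["A"], "case2": ["B"]}, [("X", "Y", "z")])
        assert net.components == []

    def test_component_case_labels_cover_networked_cases(self):
        net = build_candidate_network(
            {"c1": ["A"], "c2": ["B"], "c3": ["C", "D"]},
            [("A", "B", "x"), ("C", "D", "x")],
        )
        labelled = set().union(*net.component_cases())
        networked = {
            case for comp in net.components for g in comp for case in net.nodes[g]
        }
        assert labelled == networked == {"c1", "c2", "c3"}

    def test_expand_k_zero_is_identity(self):
        edges = [("A", "B", "x"), ("B", "C", "x")]
        net = build_candidate_network({"c": ["A", "B"]}, edges)
        same = expand_network(net, edges, k=0)
        assert set(same.nodes) == set(net.nodes)
        assert same.edges == net.edges

    def test_star_graph_forced_ranking(self):
        edges = [("HUB", leaf, "x") for leaf in ("L1", "L2", "L3")]
        net = build_candidate_network({"c": ["HUB"]}, edges)
        expanded = expand_network(net, edges, k=3)
        assert set(expanded.nodes) == {"HUB", "L1", "L2", "L3"}
        assert expanded.nodes["L1"] == set()  # added interactor owns no case

    def test_expansion_ranks_by_connectivity(self):
        edges = [
            ("A", "X", "e"), ("B", "X", "e"),  # X touches two candidates
            ("A", "Y", "e"),                    # Y touches one
            ("Y", "Z", "e"),
        ]
        net = build_candidate_network({"c": ["A", "B"]}, edges)
        expanded = expand_network(net, edges, k=1)
        assert "X" in expanded.nodes and "Y" not in expanded.nodes

    def test_expansion_never_disconnects(self):
        rng = np.random.default_rng(3)
        nodes = [f"N{i}" for i in range(30)]
        edges = [
            (nodes[int(rng.integers(30))], nodes[int(rng.integers(30))], "x")
            for _ in range(60)
        ]
        edges = [(a, b, l) for a, b, l in edges if a != b]
        net = build_candidate_network({"c": nodes[:8]}, edges)
        expanded = expand_network(net, edges, k=5)
        for comp in net.components:
            assert any(comp <= big for big in expanded.components)
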