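"""Connectivity permutation test and hypergeometric term enrichment."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

import pharmscreen as ps
import pandas as pd


def brute_force_edges(gene_set, network):
    gs = set(gene_set)
    return sum(1 for a, b in network.edges if a in gs and b in gs)


class TestConnectivity:
    def test_complete_graph_all_permutations_tie(self):
        g = nx.complete_graph(6)
        res = ps.connectivity_test([0, 1, 2, 3], g, n_perm=500, seed=1)
        assert res.observed_edges == 6 == math.comb(4, 2)
        assert res.expected_edges == pytest.approx(6.0)
        assert res.p_value == pytest.approx(1.0)

    def test_edgeless_network(self):
        g = nx.empty_graph(10)
        res = ps.connectivity_test([0, 1, 2], g, n_perm=200, seed=2)
        assert res.observed_edges == 0
        assert res.expected_edges == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_expected_matches_er_density(self):
        # closed form: a random k-set contains C(k,2) potential pairs, each
        # an edge with probability m / C(n,2)
        g = nx.gnp_random_graph(100, 0.1, seed=42)
        n_perm = 4000
        res = ps.connectivity_test(list(range(10)), g, n_perm=n_perm, seed=3)
        m = g.number_of_edges()
        expected_cf = math.comb(10, 2) * m / math.comb(100, 2)
        tol = 3 * math.sqrt(expected_cf / n_perm)  # ~3 SDs of the null mean
        assert abs(res.expected_edges - expected_cf) < tol

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_observed_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(40, 0.15, seed=seed)
        genes = list(rng.choice(40, size=8, replace=False))
        res = ps.connectivity_test(genes, g, n_perm=50, seed=seed)
        assert res.observed_edges == brute_force_edges(genes, g)

    def test_genes_missing_from_network_dropped_with_warning(self):
        g = nx.complete_graph(5)
        with pytest.warns(UserWarning, match="not in network"):
            res = ps.connectivity_test([0, 1, "absent"], g, n_perm=50, seed=4)
        assert res.set_size == 2

    def test_too_small_overlap_rejected(self):
        g = nx.complete_graph(5)
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            ps.connectivity_test(["x", "y"], g, n_perm=50, seed=5)

    def test_pvalue_never_zero_and_enriched_set_detected(self):
        # a clique planted in a sparse graph must come out significant
        g = nx.gnp_random_graph(80, 0.02, seed=6)
        clique = list(range(8))
        g.add_edges_from(itertools.combinations(clique, 2))
        res = ps.connectivity_test(clique, g, n_perm=2000, seed=7)
        assert 0 < res.p_value <= 1
        assert res.p_value < 0.01
        assert res.observed_edges > res.expected_edges

    def test_permutation_pvalues_are_valid(self):
        """Under the null (uniform random sets), P(p <= alpha) stays within
        alpha plus Monte-Carlo slack."""
        g = nx.gnp_random_graph(50, 0.1, seed=8)
        rng = np.random.default_rng(9)
        n_perm, reps = 200, 150
        ps_out = []
        for i in range(reps):
            genes = list(rng.choice(50, size=6, replace=False))
            r = ps.connectivity_test(genes, g, n_perm=n_perm, seed=int(rng.integers(2**31)))
            ps_out.append(r.p_value)
        ps_out = np.array(ps_out)
        slack = 2 / math.sqrt(n_perm)
        for alpha in (0.05, 0.2, 0.5):
            assert (ps_out <= alpha).mean() <= alpha + slack


def exhaustive_hypergeom_p(N, K, n, k):
    """P(|draw ∩ term| >= k) by enumerating all C(N, n) draws."""
    universe = list(range(N))
    term = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        hits += len(term & set(draw)) >= k
    return hits / total


class TestEnrichment:
    def test_perfect_overlap_closed_form(self):
        # N=20, K=5, n=5, k=5: only one of the C(20,5) draws hits all of
        # the term, so p = 1/15504
        universe = [f"g{i}" for i in range(20)]
        term = universe[:5]
        res = ps.term_enrichment(term, {"T": term}, universe)
        assert res[0].p == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        res = ps.term_enrichment(universe[10:15], {"T": universe[:5]}, universe)
        assert res[0].overlap == 0
        assert res[0].p == pytest.approx(1.0)

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 4, 5), (12, 5, 3)])
    def test_matches_exhaustive_enumeration(self, N, K, n):
        universe = [f"g{i}" for i in range(N)]
        term = universe[:K]
        rng = np.random.default_rng(N)
        gene_set = list(rng.choice(universe, size=n, replace=False))
        res = ps.term_enrichment(gene_set, {"T": term}, universe)
        k = res[0].overlap
        assert res[0].p == pytest.approx(
            exhaustive_hypergeom_p(N, K, n, k), rel=1e-9)

    def test_bh_adjustment_matches_hand_stepup(self):
        # hand step-up: sort p ascending, q_i = p_i * m / i, then a cumulative
        # minimum from the largest rank down; e.g. (0.01, 0.02, 0.04) -> (0.03,
        # 0.03, 0.04)
        def hand_bh(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            q = np.array(pvals, dtype=float)[order] * m / np.arange(1, m + 1)
            q = np.minimum.accumulate(q[::-1])[::-1]
            out = np.empty(m)
            out[order] = np.minimum(q, 1.0)
            return out

        assert np.allclose(hand_bh([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])
        universe = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(17)
        terms = {f"T{j}": list(rng.choice(universe, size=6, replace=False))
                 for j in range(6)}
        gene_set = list(rng.choice(universe, size=12, replace=False))
        res = ps.term_enrichment(gene_set, terms, universe)
        hand = dict(zip([r.term for r in res],
                        hand_bh([r.p for r in res])))
        for r in res:
            assert r.fdr == pytest.approx(hand[r.term], rel=1e-9)

    def test_bh_monotone_and_order_invariant(self):
        universe = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(11)
        terms = {f"T{j}": list(rng.choice(universe, size=rng.integers(3, 10),
                                          replace=False))
                 for j in range(8)}
        gene_set = list(rng.choice(universe, size=10, replace=False))
        res = ps.term_enrichment(gene_set, terms, universe)
        fdrs = [r.fdr for r in res]
        assert fdrs == sorted(fdrs)  # sorted output is monotone in fdr
        shuffled = dict(reversed(list(terms.items())))
        res2 = ps.term_enrichment(gene_set, shuffled, universe)
        assert {r.term: r.fdr for r in res} == {r.term: r.fdr for r in res2}

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ps.term_enrichment(["a"], {"T": ["a"]}, [])

    def test_gene_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ps.term_enrichment(["zz"], {"T": ["a"]}, ["a", "b"])


class TestNetworkLoading:
    def test_score_cutoff_and_dedup(self):
        edges = pd.DataFrame({
            "gene_a": ["A", "A", "B", "C", "C"],
            "gene_b": ["B", "B", "A", "C", "D"],
            "score": [0.9, 0.8, 0.95, 0.99, 0.1],
        })
        g = ps.network_from_edges(edges)
        assert set(g.edges) == {("A", "B")}  # dup collapsed, self-loop and
        # sub-threshold edge dropped
        assert g.number_of_edges() == 1

    def test_two_column_edge_list(self):
        edges = pd.DataFrame({"gene_a": ["A", "B"], "gene_b": ["B", "C"]})
        g = ps.network_from_edges(edges)
        assert g.number_of_edges() == 2

    @given(st.integers(0, 2**31 - 1))
    def test_connectivity_observed_never_exceeds_pair_count(self, seed):
        g = nx.gnp_random_graph(20, 0.3, seed=seed % 1000)
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        genes = list(rng.choice(20, size=k, replace=False))
        res = ps.connectivity_test(genes, g, n_perm=20, seed=seed % 997)
        assert 0 <= res.observed_edges <= math.comb(k, 2)
        assert 0 < res.p_value <= 1
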