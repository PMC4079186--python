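"""WNC scoring, the weight-permutation null and empirical P-values."""

import numpy as np
import pytest
from scipy import stats
from hypothesis import given, settings, strategies as st

from cohub import (
    NetworkError,
    PermutationConfig,
    WeightedNetwork,
    bonferroni_adjust,
    empirical_pvalues,
    generate_random_network,
    permute_weights,
    rank_concordance,
    run_wnc,
    wnc_scores,
    wncb_scores,
    wncc_scores,
)

from .conftest import random_weighted_network
from .oracles import exact_null_pvalues, reachable_assignments


class TestScores:
    def test_path_scores(self, path3):
        assert wnc_scores(path3) == pytest.approx({"A": 0.3, "B": 1.0, "C": 0.7})
        assert wncb_scores(path3) == pytest.approx({"A": 0.3, "B": 0.5, "C": 0.7})
        assert wncc_scores(path3) == pytest.approx({"A": 0.09, "B": 0.58, "C": 0.49})

    def test_uniform_complete_graph_closed_forms(self):
        n, w = 7, 0.5
        net = generate_random_network(n, ("constant", {"value": w}), seed=0)
        wnc = wnc_scores(net)
        assert all(v == pytest.approx((n - 1) * w) for v in wnc.values())
        # equal weights: wncb is the common weight, wncc = w * wnc
        assert all(v == pytest.approx(w) for v in wncb_scores(net).values())
        assert all(v == pytest.approx(w * (n - 1) * w) for v in wncc_scores(net).values())

    def test_wncb_errors_on_isolated_node(self):
        net = WeightedNetwork.from_edges([("A", "B", 0.4)], nodes=["A", "B", "C"])
        with pytest.raises(NetworkError, match="C"):
            wncb_scores(net)

    def test_isolated_node_wnc_is_zero(self):
        net = WeightedNetwork.from_edges([("A", "B", 0.4)], nodes=["A", "B", "C"])
        assert wnc_scores(net)["C"] == 0.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), complete=st.booleans())
    def test_conservation_sum_wnc_equals_twice_total_weight(self, seed, complete):
        """Every edge weight is counted at both its endpoints."""
        net = random_weighted_network(np.random.default_rng(seed), complete=complete)
        assert sum(wnc_scores(net).values()) == pytest.approx(2 * net.weights.sum())

    def test_adding_an_edge_strictly_increases_wnc_and_wncc(self):
        base = WeightedNetwork.from_edges([("A", "B", 0.4), ("B", "C", 0.2)])
        grown = WeightedNetwork.from_edges(
            [("A", "B", 0.4), ("B", "C", 0.2), ("A", "C", 0.3)]
        )
        for scorer in (wnc_scores, wncc_scores):
            assert scorer(grown)["A"] > scorer(base)["A"]
            assert scorer(grown)["C"] > scorer(base)["C"]


class TestPermuteWeights:
    def test_preserves_nodes_topology_and_weight_multiset(self):
        net = generate_random_network(8, ("uniform", {}), seed=11)
        cfg = PermutationConfig(n_permutations=50, seed=3, mode="swap")
        for k in (0, 17, 49):
            perm = permute_weights(net, cfg, k)
            assert perm.node_ids == net.node_ids
            np.testing.assert_array_equal(perm.edge_u, net.edge_u)
            np.testing.assert_array_equal(perm.edge_v, net.edge_v)
            np.testing.assert_array_equal(
                np.sort(perm.weights), np.sort(net.weights)
            )

    def test_sample_is_reproducible_from_seed_and_index(self):
        net = generate_random_network(6, ("uniform", {}), seed=5)
        cfg = PermutationConfig(n_permutations=10, seed=42, mode="shuffle")
        a = permute_weights(net, cfg, 3)
        b = permute_weights(net, cfg, 3)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_uniform_weights_make_permutation_a_noop(self, uniform_net):
        cfg = PermutationConfig(n_permutations=5, seed=0, mode="swap")
        perm = permute_weights(uniform_net, cfg, 2)
        np.testing.assert_array_equal(perm.weights, uniform_net.weights)

    def test_swap_mode_errors_without_disjoint_edge_pair(self):
        star = WeightedNetwork.from_edges(
            [("hub", leaf, 0.5) for leaf in "abcd"]
        )
        cfg = PermutationConfig(n_permutations=5, seed=0, mode="swap")
        with pytest.raises(NetworkError, match="shuffle"):
            permute_weights(star, cfg, 0)

    def test_sample_index_out_of_range(self, k4_distinct):
        cfg = PermutationConfig(n_permutations=5, seed=0, mode="shuffle")
        with pytest.raises(ValueError):
            permute_weights(k4_distinct, cfg, 5)

    def test_swap_chain_visits_reachable_assignments_uniformly(self, k4_distinct):
        """On K4, node-disjoint swaps reach exactly 8 weight assignments.

        Each edge of K4 is node-disjoint with exactly one other edge, so
        the three commuting transpositions generate a group of order 8;
        the lazy swap chain should visit those 8 assignments uniformly.
        """
        reachable = reachable_assignments(k4_distinct.edge_u, k4_distinct.edge_v)
        assert len(reachable) == 8
        n_samples = 4000
        cfg = PermutationConfig(n_permutations=n_samples, seed=9, mode="swap")
        w0 = list(k4_distinct.weights)
        counts: dict[tuple, int] = {}
        for k in range(n_samples):
            perm = permute_weights(k4_distinct, cfg, k)
            key = tuple(w0.index(w) for w in perm.weights)
            counts[key] = counts.get(key, 0) + 1
        assert set(counts) == reachable
        chi = stats.chisquare(list(counts.values()))
        assert chi.pvalue > 1e-4


class TestEmpiricalPvalues:
    def test_all_equal_weights_give_p_one_everywhere(self, uniform_net):
        cfg = PermutationConfig(n_permutations=200, seed=1, mode="swap")
        p = empirical_pvalues(uniform_net, cfg)
        assert all(v == 1.0 for v in p.values())

    def test_two_edge_path_matches_exact_enumeration(self, path3):
        """Shuffling 2 weights has 2 assignments: exact P is computable by hand.

        A (observed 0.3): both assignments give a null >= 0.3 -> P = 1.
        B: its score is always 1.0 -> P = 1.  C (observed 0.7): only the
        identity assignment ties -> P = 1/2.
        """
        cfg = PermutationConfig(n_permutations=4000, seed=2, mode="shuffle")
        p = empirical_pvalues(path3, cfg)
        assert p["A"] == 1.0
        assert p["B"] == 1.0
        assert p["C"] == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(4000))

    def test_k4_matches_exhaustive_enumeration(self, k4_distinct):
        """Empirical P within 3 Monte-Carlo SEs of the exact 720-assignment P."""
        exact = exact_null_pvalues(
            4, k4_distinct.edge_u, k4_distinct.edge_v, k4_distinct.weights
        )
        n = 20_000
        cfg = PermutationConfig(n_permutations=n, seed=3, mode="shuffle")
        p = empirical_pvalues(k4_distinct, cfg)
        for node, pe in zip(k4_distinct.node_ids, exact):
            se = np.sqrt(pe * (1 - pe) / n)
            assert abs(p[node] - pe) <= 3 * se + 1e-12

    def test_plus_one_estimator_never_returns_zero(self, k4_distinct):
        cfg = PermutationConfig(
            n_permutations=50, seed=4, mode="shuffle", plus_one=True
        )
        p = empirical_pvalues(k4_distinct, cfg)
        assert all(v > 0 for v in p.values())
        assert all(v <= 1 for v in p.values())

    def test_score_choice_changes_the_tested_statistic(self, path3):
        cfg = PermutationConfig(n_permutations=500, seed=5, mode="shuffle")
        p_wnc = empirical_pvalues(path3, cfg, score_fn="wnc")
        p_wncb = empirical_pvalues(path3, cfg, score_fn="wncb")
        # B has 2 neighbours: its WNCB is always the mean of both weights -> P=1
        assert p_wncb["B"] == 1.0
        assert p_wnc["B"] == 1.0


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.0002, 198, 0.0396), (0.01, 200, 1.0), (0.0, 5, 0.0)],
    )
    def test_examples(self, p, m, expected):
        assert bonferroni_adjust({"g": p}, m=m)["g"] == pytest.approx(expected)

    def test_rejects_out_of_range_p(self):
        with pytest.raises(ValueError):
            bonferroni_adjust({"g": 1.2}, m=3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=30),
        extra_m=st.integers(0, 100),
    )
    def test_contract_min_of_one_and_p_times_m(self, p, extra_m):
        pmap = {f"g{i}": v for i, v in enumerate(p)}
        m = len(p) + extra_m
        adj = bonferroni_adjust(pmap, m=m)
        for g, v in pmap.items():
            assert adj[g] == min(1.0, v * m)
            assert adj[g] >= v


class TestRunWnc:
    def test_uniform_network_yields_no_significant_genes(self, uniform_net):
        cfg = PermutationConfig(n_permutations=100, seed=0, mode="swap")
        res = run_wnc(uniform_net, cfg, alpha=0.049)
        assert (res.table["p_adjusted"] == 1.0).all()
        assert res.significant_genes == []

    def test_same_seed_gives_identical_tables(self, k4_distinct):
        cfg = PermutationConfig(n_permutations=300, seed=7, mode="shuffle")
        a = run_wnc(k4_distinct, cfg)
        b = run_wnc(k4_distinct, cfg)
        assert a.table.equals(b.table)

    def test_table_invariants(self, k4_distinct):
        cfg = PermutationConfig(n_permutations=300, seed=8, mode="shuffle")
        res = run_wnc(k4_distinct, cfg)
        t = res.table
        assert set(t["gene_id"]) == set(k4_distinct.node_ids)
        assert (t["p_adjusted"] >= t["p_nominal"]).all()
        assert (t["p_adjusted"] <= 1).all()
        assert list(t["rank"]) == list(range(1, 5))
        assert t["p_adjusted"].is_monotonic_increasing
        # wncb = wnc / (N - 1) on a complete graph
        np.testing.assert_allclose(t["wncb"], t["wnc"] / 3)

    def test_gene_subset_restricts_table_and_multiplicity(self, k4_distinct):
        cfg = PermutationConfig(n_permutations=200, seed=9, mode="shuffle")
        res = run_wnc(k4_distinct, cfg, genes=["A", "C"])
        assert set(res.table["gene_id"]) == {"A", "C"}
        row = res.table.set_index("gene_id")
        for g in ("A", "C"):
            assert row.loc[g, "p_adjusted"] == min(1.0, row.loc[g, "p_nominal"] * 2)

    def test_unknown_gene_in_subset_is_an_error(self, k4_distinct):
        cfg = PermutationConfig(n_permutations=10, seed=0, mode="shuffle")
        with pytest.raises(NetworkError, match="XYZ"):
            run_wnc(k4_distinct, cfg, genes=["A", "XYZ"])

    def test_wnc_anticorrelates_with_p_on_heterogeneous_network(self):
        """Stronger total connectivity should mean smaller empirical P."""
        net = generate_random_network(40, ("beta", {"a": 0.8, "b": 3.0}), seed=21)
        cfg = PermutationConfig(n_permutations=500, seed=22, mode="shuffle")
        res = run_wnc(net, cfg)
        r = np.corrcoef(res.table["wnc"], res.table["p_nominal"])[0, 1]
        assert r < 0


class TestRankConcordance:
    def test_identical_and_reversed(self):
        a = {"a": 1.0, "b": 2.0, "c": 3.0}
        assert rank_concordance(a, a) == pytest.approx(1.0)
        rev = {"a": 3.0, "b": 2.0, "c": 1.0}
        assert rank_concordance(a, rev) == pytest.approx(-1.0)

    def test_hand_computed_spearman(self):
        # d^2 sums to 2 -> rho = 1 - 6*2 / (5 * 24) = 0.9
        a = {g: v for g, v in zip("abcde", [1, 2, 3, 4, 5])}
        b = {g: v for g, v in zip("abcde", [1, 3, 2, 4, 5])}
        assert rank_concordance(a, b) == pytest.approx(0.9)

    def test_mismatched_gene_sets_error(self):
        with pytest.raises(ValueError):
            rank_concordance({"a": 1.0}, {"b": 1.0})
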