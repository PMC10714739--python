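"""Complexity, topology and trophic-structure metrics.

The trophic-level operation is cross-checked against an independent
recursive prey-averaging oracle on exhaustively enumerated acyclic webs.
"""

import itertools

import numpy as np
import pytest

from microweb import FoodWeb, TaxonNode
from microweb.metrics import (
    characteristic_path_length,
    clustering_coefficient,
    complexity,
    compute_all,
    degree_stats,
    modularity,
    omnivory,
    trophic_levels,
)

from conftest import make_web, web_with


def web_from_matrix(A):
    A = np.asarray(A)
    nodes = [TaxonNode(f"n{k}") for k in range(A.shape[0])]
    return FoodWeb(nodes, A)


def recursive_tl(A):
    """Independent oracle: memoized prey-averaged levels on an acyclic web."""
    S = A.shape[0]
    memo = {}

    def tl(j):
        if j in memo:
            return memo[j]
        prey = np.flatnonzero(A[:, j])
        memo[j] = 1.0 if len(prey) == 0 else 1.0 + np.mean([tl(int(i)) for i in prey])
        return memo[j]

    return np.array([tl(j) for j in range(S)])


class TestComplexity:
    @pytest.mark.parametrize(
        "S,L,ld,c",
        [
            (69, 780, 11.30, 0.16),  # spring
            (61, 462, 7.57, 0.12),   # autumn
        ],
    )
    def test_printed_seasonal_values_reproduced(self, S, L, ld, c):
        web = web_with(S, L, np.random.default_rng(1))
        m = complexity(web)
        assert round(m.LD, 2) == ld
        assert round(m.C, 2) == c

    def test_internally_inconsistent_printed_cells_flagged(self):
        # the printed summer linkage density and winter connectance do not
        # equal L/S and L/S^2 for the printed S and L; the computed values
        # must disagree with those printed cells
        summer = complexity(web_with(70, 921, np.random.default_rng(2)))
        assert round(summer.LD, 2) == 13.16 != 13.20
        winter = complexity(web_with(59, 646, np.random.default_rng(3)))
        assert round(winter.C, 2) == 0.19 != 0.16

    def test_edgeless_web(self):
        web = web_from_matrix(np.zeros((5, 5)))
        assert complexity(web) == (5, 0, 0.0, 0.0)


class TestClustering:
    def test_triangle_and_star(self):
        tri = make_web([("a", "b"), ("b", "c"), ("a", "c")])
        assert clustering_coefficient(tri) == 1.0
        star = make_web([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])
        assert clustering_coefficient(star) == 0.0

    def test_five_node_hand_enumeration(self):
        # local values a:1, b:1, c:1/3, d:0, e:0 -> mean 7/15
        web = make_web([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e")])
        assert clustering_coefficient(web) == pytest.approx(7 / 15)


class TestPathLength:
    def test_three_node_path(self):
        web = make_web([("a", "b"), ("b", "c")])
        cpl, excluded = characteristic_path_length(web)
        assert cpl == pytest.approx(4 / 3)
        assert excluded == 0

    def test_complete_graph(self):
        edges = [(a, b) for a, b in itertools.combinations("abcd", 2)]
        web = make_web(edges)
        assert characteristic_path_length(web)[0] == 1.0

    def test_disconnected_pairs_reported(self):
        web = make_web([("a", "b"), ("c", "d")])
        cpl, excluded = characteristic_path_length(web)
        assert cpl == 1.0
        assert excluded == 4

    def test_fully_isolated_nodes_raise(self):
        web = web_from_matrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="reachable"):
            characteristic_path_length(web)


class TestTrophicLevels:
    def test_chain(self, chain_web):
        tl, mean = trophic_levels(chain_web)
        assert tl.tolist() == [1.0, 2.0, 3.0]
        assert mean == 2.0

    def test_intraguild_predation(self, igp_web):
        tl, _ = trophic_levels(igp_web)
        by_id = dict(zip(igp_web.node_ids, tl))
        assert by_id["c"] == pytest.approx(2.5)

    def test_feeding_loop_solved_exactly(self):
        # a basal; b eats {a, c}; c eats b: TL_b = 1 + (1 + TL_c)/2 and
        # TL_c = 1 + TL_b have the unique solution TL_b = 4, TL_c = 5
        web = make_web([("a", "b"), ("c", "b"), ("b", "c")])
        tl, _ = trophic_levels(web)
        by_id = dict(zip(web.node_ids, tl))
        assert by_id["a"] == pytest.approx(1.0)
        assert by_id["b"] == pytest.approx(4.0)
        assert by_id["c"] == pytest.approx(5.0)

    def test_basal_free_cycle_names_nodes(self):
        # u and v feed only on each other, with no path to a basal
        # resource; the singular system must name them
        web = make_web([("a", "b"), ("u", "v"), ("v", "u")])
        with pytest.raises(ValueError) as err:
            trophic_levels(web)
        assert "u" in str(err.value) and "v" in str(err.value)

    def test_oracle_equivalence_on_enumerated_acyclic_webs(self):
        """Linear solve equals recursive prey-averaging on every acyclic
        web with up to 5 nodes (upper-triangular enumeration; metrics are
        node-order invariant so this covers all DAGs)."""
        for n in range(2, 6):
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
            for bits in range(2 ** len(pairs)):
                A = np.zeros((n, n), dtype=np.int8)
                for b, (i, j) in enumerate(pairs):
                    if bits >> b & 1:
                        A[i, j] = 1
                web = web_from_matrix(A)
                tl, _ = trophic_levels(web)
                assert np.allclose(tl, recursive_tl(A), atol=1e-9)

    def test_consumers_of_basal_only_keep_mean_below_two(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n_basal, n_cons = rng.integers(1, 5), rng.integers(1, 5)
            S = int(n_basal + n_cons)
            A = np.zeros((S, S), dtype=np.int8)
            for j in range(n_basal, S):
                prey = rng.choice(n_basal, size=rng.integers(1, n_basal + 1), replace=False)
                A[prey, j] = 1
            _, mean = trophic_levels(web_from_matrix(A))
            assert mean <= 2.0 + 1e-12


class TestOmnivory:
    def test_chain_has_none(self, chain_web):
        assert omnivory(chain_web) == 0.0

    def test_igp_single_omnivore(self, igp_web):
        assert omnivory(igp_web) == pytest.approx(1 / 3)

    def test_matches_brute_force_on_generated_web(self):
        rng = np.random.default_rng(5)
        web = web_with(60, 400, rng)
        tl, _ = trophic_levels(web, on_singular="lstsq")
        A = web.adjacency
        expected = 0
        for j in range(web.S):
            prey_tls = tl[np.flatnonzero(A[:, j])]
            if len(prey_tls) >= 2 and prey_tls.max() - prey_tls.min() > 1e-9:
                expected += 1
        assert omnivory(web, on_singular="lstsq") == pytest.approx(expected / web.S)


class TestModularity:
    def test_single_clique_scores_zero(self):
        edges = [(a, b) for a, b in itertools.combinations("abcd", 2)]
        q, parts = modularity(make_web(edges))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert len(parts) == 1

    def test_two_disconnected_triangles(self):
        web = make_web(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        q, parts = modularity(web)
        assert q == pytest.approx(0.5)
        assert {frozenset(p) for p in parts} == {
            frozenset({"a", "b", "c"}),
            frozenset({"x", "y", "z"}),
        }

    def test_deterministic_across_runs(self, season_webs):
        web = season_webs["autumn"]
        q1, p1 = modularity(web)
        q2, p2 = modularity(web)
        assert q1 == q2 and p1 == p2


class TestDegreesAndInvariance:
    def test_ad_identity(self):
        web = make_web([("a", "b")])
        assert degree_stats(web).AD == 1.0
        rng = np.random.default_rng(6)
        for _ in range(5):
            w = web_with(20, int(rng.integers(10, 60)), rng)
            assert degree_stats(w).AD == pytest.approx(2 * w.L / w.S)

    def test_edgeless_ad_zero(self):
        web = web_from_matrix(np.zeros((4, 4)))
        assert degree_stats(web).AD == 0.0

    def test_node_permutation_changes_nothing(self, season_webs):
        web = season_webs["winter"]
        rng = np.random.default_rng(7)
        order = list(web.node_ids)
        rng.shuffle(order)
        shuffled = web.relabelled(order)
        m1, m2 = compute_all(web), compute_all(shuffled)
        for field in ("S", "L", "LD", "C", "CC", "CPL", "meanTL", "O"):
            assert getattr(m1, field) == pytest.approx(getattr(m2, field))
        tl1 = dict(zip(web.node_ids, m1.TL))
        tl2 = dict(zip(shuffled.node_ids, m2.TL))
        assert all(tl1[k] == pytest.approx(tl2[k]) for k in tl1)

    def test_removing_an_edge_never_raises_complexity(self):
        rng = np.random.default_rng(8)
        web = web_with(15, 40, rng)
        i, j = next(zip(*np.nonzero(web.adjacency)))
        A = web.adjacency.copy()
        A[i, j] = 0
        smaller = FoodWeb(web.nodes, A)
        for field in ("L", "LD", "C"):
            assert getattr(complexity(smaller), field) <= getattr(
                complexity(web), field
            )
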