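"""Per-sample diversity, sub-networks, Int, regressions, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from microweb import (
    interaction_proportion,
    metric_correlations,
    regress_feature,
    sample_subweb,
    shannon,
)

from conftest import make_web


class TestShannon:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((1, 1, 1, 1), np.log(4)),
            ((5, 0, 0), 0.0),
            ((2, 1, 1), -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))),
        ],
    )
    def test_known_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon([0, 0])

    def test_uniform_maximizes_for_fixed_richness(self):
        # all integer compositions of 12 into n<=6 positive parts
        for n in range(2, 7):
            best = shannon([12 / n] * n)
            for comp in itertools.product(range(1, 13), repeat=n):
                if sum(comp) != 12:
                    continue
                assert shannon(comp) <= best + 1e-12


BACT = {"bacteria": "bacteria"}


class TestSampleSubweb:
    def test_full_sample_returns_whole_web(self, igp_web):
        sub, missing = sample_subweb(igp_web, {"a", "b", "c"})
        assert sub == igp_web
        assert missing == []

    def test_consumer_plus_aggregate_keeps_their_edge(self):
        web = make_web(
            [("bacteria", "p"), ("a", "p")],
            guilds={"p": {"B"}, "a": {"P"}},
            compartments=BACT,
        )
        sub, _ = sample_subweb(web, {"p"})
        assert set(sub.node_ids) == {"p", "bacteria"}
        assert sub.L == 1

    def test_absent_taxa_ignored_but_reported(self, igp_web):
        sub, missing = sample_subweb(igp_web, {"a", "ghost"})
        assert missing == ["ghost"]
        assert "a" in sub

    def test_random_subsets_induce_consistent_subgraphs(self, season_webs):
        web = season_webs["spring"]
        rng = np.random.default_rng(0)
        ids = web.node_ids
        parent_edges = set(web.trophic_links())
        for _ in range(100):
            take = {i for i in ids if rng.random() < 0.5}
            if not take:
                continue
            sub, _ = sample_subweb(web, take)
            kept = set(sub.node_ids)
            for prey, pred in sub.trophic_links():
                assert (prey, pred) in parent_edges
                assert prey in kept and pred in kept


class TestInteractionProportion:
    def test_all_edges_qualify(self):
        web = make_web(
            [("bacteria", "p"), ("bacteria", "q")],
            guilds={"p": {"B"}, "q": {"B"}},
            compartments=BACT,
        )
        assert interaction_proportion(web) == 1.0

    def test_no_bacterivore_present(self):
        web = make_web(
            [("bacteria", "q")], guilds={"q": {"R"}}, compartments=BACT
        )
        assert interaction_proportion(web) == 0.0

    def test_one_of_four_edges(self):
        web = make_web(
            [("bacteria", "p"), ("a", "p"), ("a", "q"), ("q", "r")],
            guilds={"p": {"B"}, "q": {"R"}, "r": {"R"}, "a": {"P"}},
            compartments=BACT,
        )
        assert interaction_proportion(web) == 0.25

    def test_linkless_subweb_rejected(self):
        web = make_web([], nodes=["p"], guilds={"p": {"B"}})
        with pytest.raises(ValueError, match="linkless"):
            interaction_proportion(web)

    def test_invariant_to_duplicating_irrelevant_isolated_node(self):
        edges = [("bacteria", "p"), ("a", "q")]
        base = make_web(edges, guilds={"p": {"B"}, "q": {"R"}, "a": {"P"}},
                        compartments=BACT)
        bigger = make_web(
            edges, nodes=["bacteria", "p", "a", "q", "lonely"],
            guilds={"p": {"B"}, "q": {"R"}, "a": {"P"}, "lonely": {"P"}},
            compartments=BACT,
        )
        assert interaction_proportion(base) == interaction_proportion(bigger)


class TestRegression:
    def test_exact_line(self):
        x = np.arange(5.0)
        r = regress_feature(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        r = regress_feature([1, 2, 3, 4], [5, 5, 5, 5])
        assert r.slope == 0.0 and r.r_squared == 0.0

    def test_four_point_closed_form(self):
        r = regress_feature([1, 2, 3, 4], [2, 1, 4, 3])
        assert r.slope == pytest.approx(0.6)
        assert r.r_squared == pytest.approx(0.36)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            regress_feature([2, 2, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 3"):
            regress_feature([1, 2], [1, 2])


class TestCorrelations:
    def _frame(self, **cols):
        base = {
            "L": [1, 2, 3, 4, 5],
            "LD": [1, 2, 3, 4, 5],
            "C": [1, 2, 3, 4, 5],
            "meanTL": [1, 2, 3, 4, 5],
            "O": [5, 4, 3, 2, 1],
            "Mod": [1, 3, 2, 5, 4],
            "QSS": [1, 1, 1, 1, 1],
        }
        base.update(cols)
        return pd.DataFrame(base)

    def test_monotone_and_reversed_pairs(self):
        rho, p = metric_correlations(self._frame())
        assert rho.loc["L", "meanTL"] == pytest.approx(1.0)
        assert rho.loc["L", "O"] == pytest.approx(-1.0)

    def test_hand_ranked_pair(self):
        rho, _ = metric_correlations(self._frame())
        assert rho.loc["L", "Mod"] == pytest.approx(0.8)

    def test_constant_column_reported_missing(self):
        rho, p = metric_correlations(self._frame())
        assert np.isnan(rho.loc["L", "QSS"]) and np.isnan(p.loc["L", "QSS"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="4 rows"):
            metric_correlations(self._frame().head(3))
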