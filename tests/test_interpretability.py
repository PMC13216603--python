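"""Cell ranking, top-fraction selection, panels, and enrichment statistics."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from caremil.bag_store import InstanceBag
from caremil.interpretability import (bonferroni_flags, build_attention_panel,
                                      chi_squared_2x2, enrichment_report,
                                      enrichment_table, log_odds_ratio,
                                      pooled_enrichment, rank_cells,
                                      select_top_fraction,
                                      top_fraction_permutation_test)


class TestRanking:
    def test_descending_order(self):
        assert rank_cells(np.array([0.1, 0.7, 0.2])).tolist() == [1, 2, 0]

    def test_ties_broken_by_index(self):
        assert rank_cells(np.ones(5)).tolist() == [0, 1, 2, 3, 4]

    def test_reversed_scores_reverse_ranking(self, rng):
        s = rng.random(20)
        fwd = rank_cells(s)
        # strictly distinct scores: reversing the array reverses positions
        rev = rank_cells(s[::-1])
        assert np.array_equal(19 - fwd, rev)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rank_cells(np.array([0.5, np.nan]))


class TestTopFraction:
    @pytest.mark.parametrize("n,fraction,expected", [
        (100, 0.10, 10), (101, 0.10, 11), (5, 0.10, 1), (8, 1.0, 8)])
    def test_ceil_rule(self, n, fraction, expected):
        assert len(select_top_fraction(np.arange(n), fraction)) == expected

    def test_empty_ranking_rejected(self):
        with pytest.raises(ValueError):
            select_top_fraction(np.array([]), 0.1)


class TestPanel:
    def test_three_rows_of_requested_size(self, rng):
        n = 50
        bag = InstanceBag("S", rng.normal(size=(n, 4)),
                          [f"c{i}" for i in range(n)])
        scores = rng.random(n)
        panel = build_attention_panel(bag, scores, n_per_row=10, rng=rng)
        assert len(panel["top_row"]) == 10
        assert len(panel["bottom_row"]) == 10
        assert len(set(panel["random_row"])) == 10
        order = rank_cells(scores)
        assert panel["top_row"] == [bag.cell_ids[i] for i in order[:10]]
        assert panel["bottom_row"] == [bag.cell_ids[i] for i in order[::-1][:10]]

    def test_small_bag_truncates(self, rng):
        bag = InstanceBag("S", rng.normal(size=(4, 3)), list("abcd"))
        panel = build_attention_panel(bag, rng.random(4), n_per_row=10,
                                      rng=rng)
        assert len(panel["top_row"]) == 4

    def test_fixed_rng_reproducible(self, rng):
        bag = InstanceBag("S", rng.normal(size=(30, 3)),
                          [f"c{i}" for i in range(30)])
        scores = rng.random(30)
        a = build_attention_panel(bag, scores, rng=np.random.default_rng(7))
        b = build_attention_panel(bag, scores, rng=np.random.default_rng(7))
        assert a == b


class TestEnrichmentTable:
    def test_hand_computed_table(self):
        # 100 cells, 20 of type A (8 in the top-10 set)
        types = ["A"] * 20 + ["B"] * 80
        top = list(range(8)) + [50, 51]
        tables = enrichment_table(types, np.array(top))
        assert tables["A"] == (8, 2, 12, 78)
        rep = enrichment_report(types, np.array(top))
        row = rep.table.set_index("cell_type").loc["A"]
        assert row["enrichment_ratio"] == pytest.approx(4.0)

    def test_top_set_everything_gives_ratio_one(self):
        types = list("AAABBC")
        rep = enrichment_report(types, np.arange(6))
        assert np.allclose(rep.table["enrichment_ratio"], 1.0)

    def test_absent_type_has_no_row(self):
        tables = enrichment_table(["A", "A"], np.array([0]))
        assert set(tables) == {"A"}

    def test_tables_sum_to_n(self, rng):
        types = rng.choice(list("ABCD"), size=60).tolist()
        top = rng.choice(60, size=12, replace=False)
        for tab in enrichment_table(types, top).values():
            assert sum(tab) == 60

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError, match="range"):
            enrichment_table(["A", "B"], np.array([5]))


class TestChiSquared:
    def test_matches_expected_counts_oracle(self):
        a, b, c, d = 8, 2, 12, 78
        N = a + b + c + d
        # independent oracle: explicit observed-vs-expected summation
        obs = np.array([[a, b], [c, d]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / N
        stat_oracle = ((obs - exp) ** 2 / exp).sum()
        stat, p, degen = chi_squared_2x2((a, b, c, d))
        assert stat == pytest.approx(stat_oracle, abs=1e-12)
        assert not degen

    def test_independent_table_is_zero(self):
        stat, p, degen = chi_squared_2x2((5, 5, 5, 5))
        assert stat == 0.0 and p == 1.0 and not degen

    def test_perfect_association_equals_n(self):
        stat, p, _ = chi_squared_2x2((10, 0, 0, 10))
        assert stat == pytest.approx(20.0)

    def test_zero_marginal_flagged_degenerate(self):
        stat, p, degen = chi_squared_2x2((0, 0, 5, 5))
        assert (stat, p, degen) == (0.0, 1.0, True)

    def test_agrees_with_generic_pearson_on_random_tables(self, rng):
        for _ in range(200):
            tab = rng.integers(1, 60, size=4)
            stat, p, degen = chi_squared_2x2(tuple(tab))
            ref = chi2_contingency(tab.reshape(2, 2), correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestBonferroniAndLogOdds:
    def test_threshold_divided_by_m(self):
        assert bonferroni_flags([0.001, 0.04], 0.05) == [True, False]

    def test_single_test_plain_alpha(self):
        assert bonferroni_flags([0.04], 0.05) == [True]

    def test_all_one_never_significant(self):
        assert bonferroni_flags([1.0] * 5) == [False] * 5

    def test_log_odds_direct_evaluation(self):
        expected = math.log((8.5 * 78.5) / (2.5 * 12.5))
        assert log_odds_ratio((8, 2, 12, 78)) == pytest.approx(expected)
        assert expected == pytest.approx(3.06, abs=0.01)

    def test_log_odds_symmetry_zero(self):
        assert log_odds_ratio((5, 5, 5, 5)) == 0.0

    def test_haldane_correction_case(self):
        assert log_odds_ratio((1, 0, 0, 1)) == pytest.approx(math.log(9.0))


class TestPooledEnrichment:
    def test_pooling_two_identical_slides_doubles_counts(self, rng):
        types = ["A"] * 20 + ["B"] * 80
        X = rng.normal(size=(100, 3))
        bag = InstanceBag("S", X, [f"c{i}" for i in range(100)],
                          cell_types=types)
        scores = np.zeros(100)
        scores[:8] = 1.0
        scores[50:52] = 0.5
        scores += rng.random(100) * 1e-6
        scores /= scores.sum()
        rep = pooled_enrichment([bag, bag], [scores, scores], "AML",
                                fraction=0.10)
        row = rep.table.set_index("cell_type").loc["A"]
        assert (row["a"], row["b"]) == (16, 4)

    def test_missing_cell_types_rejected(self, rng):
        bag = InstanceBag("S", rng.normal(size=(5, 2)), list("abcde"))
        with pytest.raises(ValueError, match="cell_types"):
            pooled_enrichment([bag], [np.full(5, 0.2)], "AML")


class TestOverlayFigure:
    def test_renders_scatter_with_marker_types(self, rng):
        from caremil.interpretability import attention_overlay_figure
        emb2d = rng.normal(size=(60, 2))
        scores = rng.random(60)
        types = (["blast"] * 20 + ["lymphocyte"] * 40)
        ax = attention_overlay_figure(emb2d, scores, types,
                                      marker_type="blast", fraction=0.25)
        assert len(ax.collections) >= 2


class TestPermutationTest:
    def test_concentrated_attention_on_flagged_cells_significant(self, rng):
        masks, scores = [], []
        for _ in range(5):
            mask = np.zeros(80, dtype=bool)
            mask[:20] = True
            s = rng.random(80) * 0.1
            s[:20] += 1.0   # flagged cells get the attention
            masks.append(mask)
            scores.append(s / s.sum())
        res = top_fraction_permutation_test(masks, scores, fraction=0.25,
                                            n_perm=199, seed=0)
        assert res["p_value"] < 0.05
        assert res["observed"] > res["null_mean"]

    def test_random_attention_not_significant(self, rng):
        masks = [np.zeros(60, dtype=bool) for _ in range(4)]
        for m in masks:
            m[:15] = True
        scores = [rng.random(60) for _ in range(4)]
        res = top_fraction_permutation_test(masks, scores, fraction=0.25,
                                            n_perm=199, seed=1)
        assert res["p_value"] > 0.01
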