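import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doseffect.io import ValidationError
from doseffect.stats import (
    bh_adjust,
    cochran_armitage_trend,
    de_by_chromosome,
    differential_expression,
    expressed_gene_flag,
    fisher_exact_2x2,
    format_pvalue,
    gene_set_enrichment,
    hypergeometric_overlap,
    two_proportion_test,
)
from doseffect.io import GeneSetCollection

from conftest import make_annotation, make_matrix
from oracles import fisher_enumeration_p, trend_permutation_p


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_with_cumulative_minimum(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_sorted_input_gives_nondecreasing_output(self):
        p = np.linspace(0.001, 0.9, 25)
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj >= p).all()

    @settings(max_examples=30)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_permutation_equivariance(self, p):
        rng = np.random.default_rng(len(p))
        perm = rng.permutation(len(p))
        direct = bh_adjust(p)
        permuted = bh_adjust(np.asarray(p)[perm])
        inverse = np.empty(len(p))
        inverse[perm] = permuted
        np.testing.assert_allclose(direct, inverse)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestFisherExact:
    def test_symmetric_table(self):
        res = fisher_exact_2x2(5, 5, 5, 5)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_enumerated_small_table(self):
        # all tables with margins (4,4)/(4,4): two-sided p = 34/70
        res = fisher_exact_2x2(3, 1, 1, 3)
        assert res.pvalue == pytest.approx(34 / 70, abs=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        res = fisher_exact_2x2(5, 0, 2, 7)
        assert res.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 2.5))

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(0, 0, 0, 0)

    @settings(max_examples=60)
    @given(
        st.tuples(
            st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
        ).filter(lambda t: sum(t) > 0 and min(t[0] + t[1], t[2] + t[3], t[0] + t[2], t[1] + t[3]) > 0)
    )
    def test_matches_margin_fixed_enumeration(self, cells):
        a, b, c, d = cells
        assert fisher_exact_2x2(a, b, c, d).pvalue == pytest.approx(
            fisher_enumeration_p(a, b, c, d), abs=1e-9
        )


class TestTwoProportion:
    def test_expressed_gene_fractions_from_cohort_counts(self):
        # 51.4% of 4702 vs 49.2% of 8134 expressed genes differ at p ~ 0.014
        res = two_proportion_test(2418, 4702, 3999, 8134)
        assert res.pvalue == pytest.approx(0.014, abs=0.001)

    def test_equal_proportions_give_p_one(self):
        assert two_proportion_test(30, 100, 30, 100).pvalue == pytest.approx(1.0)

    def test_z_formula(self):
        # z = 0.20 / sqrt(0.4 * 0.6 * (1/100 + 1/100))
        res = two_proportion_test(30, 100, 50, 100)
        assert res.pvalue == pytest.approx(0.0039, abs=0.0002)

    def test_degenerate_margins_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert two_proportion_test(0, 10, 0, 10).pvalue == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            two_proportion_test(11, 10, 1, 10)


class TestHypergeometricOverlap:
    def test_delegates_to_fisher(self):
        assert hypergeometric_overlap(4, 4, 3, 8).pvalue == pytest.approx(
            fisher_exact_2x2(3, 1, 1, 3).pvalue
        )

    def test_independence_overlap_is_not_significant(self):
        # expectation: 200 * 200 / 1000 = 40 overlapping genes
        res = hypergeometric_overlap(200, 200, 40, 1000)
        assert res.pvalue > 0.9

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_overlap(4, 4, 5, 100)
        with pytest.raises(ValidationError):
            hypergeometric_overlap(60, 60, 0, 100)


class TestCochranArmitage:
    def test_constant_proportions_give_p_one(self):
        res = cochran_armitage_trend([[5, 5, 5], [5, 5, 5]])
        assert res.z == 0.0
        assert res.pvalue == 1.0

    def test_small_table_close_to_exact_permutation(self):
        table = [[1, 2, 3], [3, 2, 1]]
        asym = cochran_armitage_trend(table)
        exact = trend_permutation_p(table)
        assert asym.pvalue == pytest.approx(exact, abs=0.01)

    def test_exact_method_matches_independent_permutation_oracle(self):
        for table in ([[1, 2, 3], [3, 2, 1]], [[0, 2, 4], [4, 2, 0]], [[2, 2, 2], [1, 3, 2]]):
            ours = cochran_armitage_trend(table, method="exact").pvalue
            assert ours == pytest.approx(trend_permutation_p(table), abs=1e-9)

    def test_strong_monotone_trend_is_significant(self):
        res = cochran_armitage_trend([[10, 40, 90], [190, 160, 110]])
        assert res.pvalue < 1e-6
        assert res.z > 0

    def test_zero_row_margin_rejected(self):
        with pytest.raises(ValidationError, match="zero row"):
            cochran_armitage_trend([[0, 0, 0], [5, 5, 5]])

    def test_needs_three_columns(self):
        with pytest.raises(ValidationError):
            cochran_armitage_trend([[1, 2], [2, 1]])


class TestDifferentialExpression:
    def _groups(self, n_a, n_b):
        labels = ["A"] * n_a + ["B"] * n_b
        samples = [f"s{i}" for i in range(n_a + n_b)]
        return pd.Series(labels, index=samples), samples

    def test_identical_values_give_null_result(self):
        groups, samples = self._groups(3, 3)
        m = make_matrix(np.ones((4, 6)) * [[1], [2], [3], [4]], list("wxyz"), samples, "expression")
        res = differential_expression(m, groups)
        assert (res.table["t"] == 0).all()
        assert (res.table["pvalue"] == 1).all()

    def test_small_group_rejected(self):
        groups, samples = self._groups(1, 5)
        m = make_matrix(np.random.default_rng(0).normal(size=(3, 6)), list("abc"), samples, "expression")
        with pytest.raises(ValidationError, match=">= 2 samples"):
            differential_expression(m, groups)

    def test_planted_shifts_recovered(self):
        rng = np.random.default_rng(101)
        n_genes, n_a, n_b = 2000, 30, 30
        x = rng.normal(0, 1, (n_genes, n_a + n_b))
        x[:100, :n_a] += 3.0  # 3-sd shift in the first 100 genes
        groups, samples = self._groups(n_a, n_b)
        m = make_matrix(x, [f"g{i}" for i in range(n_genes)], samples, "expression")
        res = differential_expression(m, groups)
        planted = res.table.iloc[:100]
        assert planted["significant"].sum() >= 95
        assert (planted.loc[planted["significant"], "direction"] == "up_in_a").all()
        assert res.table.iloc[100:]["significant"].sum() <= 5

    def test_direction_from_mean_difference(self):
        groups, samples = self._groups(3, 3)
        x = np.array([[5, 5, 5, 1, 1, 1], [1, 1, 1, 5, 5, 5]], dtype=float)
        x += np.random.default_rng(2).normal(0, 0.1, x.shape)
        m = make_matrix(x, ["up", "down"], samples, "expression")
        res = differential_expression(m, groups)
        assert res.table.loc["up", "direction"] == "up_in_a"
        assert res.table.loc["down", "direction"] == "down_in_a"


class TestExpressedGeneFlag:
    def test_top_half_flagged(self):
        m = make_matrix([[1.0], [2.0], [3.0], [4.0]], list("abcd"), ["s1"], "expression")
        assert list(expressed_gene_flag(m)) == [False, False, True, True]

    def test_all_equal_medians_all_flagged(self):
        m = make_matrix(np.ones((3, 2)), list("abc"), ["s1", "s2"], "expression")
        assert expressed_gene_flag(m).all()

    @settings(max_examples=25)
    @given(st.lists(st.floats(1, 100), min_size=2, max_size=30, unique=True))
    def test_distinct_medians_split_into_near_halves(self, medians):
        m = make_matrix([[v] for v in medians],
                        [f"g{i}" for i in range(len(medians))], ["s1"], "expression")
        flags = expressed_gene_flag(m)
        assert abs(int(flags.sum()) - (len(medians) - int(flags.sum()))) <= 1


class TestDeByChromosome:
    def _de_result(self, genes, significant, direction):
        table = pd.DataFrame(
            {
                "mean_a": 1.0,
                "mean_b": 0.0,
                "t": 1.0,
                "pvalue": 0.5,
                "p_adj": 0.5,
                "direction": direction,
                "significant": significant,
            },
            index=genes,
        )
        from doseffect.stats import DeResult

        return DeResult(table=table, group_a="HMM", group_b="NHMM", alpha=0.05)

    def test_trisomy_enrichment_from_counts(self):
        genes = [f"g{i}" for i in range(20)]
        ann = make_annotation(genes, ["9"] * 10 + ["10"] * 10)
        de = self._de_result(genes, [True] * 10 + [False] * 10, ["up_in_a"] * 20)
        out = de_by_chromosome(de, ann)
        assert out.counts.loc["9", "n_up"] == 10
        assert out.counts.loc["10", "n_up"] == 0
        assert out.up_enrichment.pvalue == pytest.approx(
            fisher_exact_2x2(10, 0, 0, 10).pvalue
        )

    def test_no_significant_genes_skips_enrichment(self):
        genes = ["a", "b", "c"]
        ann = make_annotation(genes, ["1", "2", "3"])
        de = self._de_result(genes, [False] * 3, ["up_in_a"] * 3)
        out = de_by_chromosome(de, ann)
        assert out.up_enrichment is None
        assert (out.counts["n_up"] == 0).all()

    def test_counts_invariant_to_gene_order(self):
        genes = [f"g{i}" for i in range(8)]
        ann = make_annotation(genes, ["3", "3", "4", "4", "5", "5", "6", "6"])
        de1 = self._de_result(genes, [True] * 4 + [False] * 4, ["up_in_a"] * 8)
        rev = genes[::-1]
        de2 = self._de_result(rev, [False] * 4 + [True] * 4, ["up_in_a"] * 8)
        out1 = de_by_chromosome(de1, ann)
        out2 = de_by_chromosome(de2, ann)
        pd.testing.assert_frame_equal(out1.counts, out2.counts)


class TestGeneSetEnrichment:
    def test_enriched_set_ranks_first_and_bh_applied(self):
        universe = [f"g{i}" for i in range(100)]
        query = universe[:20]
        sets = GeneSetCollection(
            {
                "hit": frozenset(universe[:15]),
                "miss": frozenset(universe[50:65]),
                "outside": frozenset(["zzz1", "zzz2"]),
            }
        )
        out = gene_set_enrichment(query, sets, universe)
        assert out.index[0] == "hit"
        assert (out["p_adj"] >= out["pvalue"] - 1e-12).all()
        assert "outside" not in out.index

    def test_empty_query_rejected(self):
        sets = GeneSetCollection({"s": frozenset(["a"])})
        with pytest.raises(ValidationError):
            gene_set_enrichment(["not_in_universe"], sets, ["a", "b"])


def test_pvalue_display_floor():
    assert format_pvalue(1e-20) == "< 2.2e-16"
    assert format_pvalue(0.014) == "0.014"
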