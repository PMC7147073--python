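import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gonadiso import synthetic as syn
from gonadiso.core_io import CountMatrix, PathwayMap, SampleDesign
from gonadiso.expression import (ExpressionCategory, _exact_conditional_p,
                                 abundance_bin, bh_adjust, classify_expression,
                                 compute_fpkm, crosstab_panel, de_classify,
                                 nb_de_test, pathway_enrichment)


def two_sample_design():
    return SampleDesign({"t1": "testis", "o1": "ovary"})


class TestFpkm:
    def test_direct_formula(self):
        # library size is the column sum: 10 + 999_990 = 1e6
        counts = CountMatrix(pd.DataFrame({"s": [10, 999_990]},
                                          index=["a", "filler"]))
        lengths = pd.Series({"a": 2000, "filler": 1000})
        fpkm = compute_fpkm(counts, lengths)
        assert fpkm.loc["a", "s"] == pytest.approx(5.0)

    def test_zero_count_gives_zero(self):
        counts = CountMatrix(pd.DataFrame({"s": [0, 100]}, index=["a", "b"]))
        fpkm = compute_fpkm(counts, pd.Series({"a": 500, "b": 500}))
        assert fpkm.loc["a", "s"] == 0.0

    def test_linearity_in_count_and_length(self):
        base = CountMatrix(pd.DataFrame({"s": [10, 10**6]}, index=["a", "f"]))
        doubled = CountMatrix(pd.DataFrame({"s": [20, 10**6 - 10]},
                                           index=["a", "f"]))
        lengths = pd.Series({"a": 2000, "f": 1000})
        f1 = compute_fpkm(base, lengths).loc["a", "s"]
        f2 = compute_fpkm(doubled, lengths).loc["a", "s"]
        assert f2 == pytest.approx(2 * f1, rel=1e-4)
        halved_len = compute_fpkm(base, pd.Series({"a": 4000, "f": 1000}))
        assert halved_len.loc["a", "s"] == pytest.approx(f1 / 2)

    def test_zero_library_errors(self):
        counts = CountMatrix(pd.DataFrame({"s": [0]}, index=["a"]))
        with pytest.raises(ValueError, match="library"):
            compute_fpkm(counts, pd.Series({"a": 100}))


class TestClassifyExpression:
    def _classify(self, testis, ovary):
        fpkm = pd.DataFrame({"t1": testis, "o1": ovary},
                            index=[f"g{i}" for i in range(len(testis))])
        return classify_expression(fpkm, two_sample_design())

    def test_below_threshold_both_groups_not_expressed(self):
        cats = self._classify([0.05], [0.0])
        assert cats.category["g0"] == "not_expressed"

    def test_ovary_specific_mid_bin(self):
        cats = self._classify([0.05], [5.0])
        assert cats.category["g0"] == "ovary_specific"
        assert cats.abundance_bin["g0"] == "mid"

    def test_shared_when_both_above_threshold(self):
        cats = self._classify([0.5], [0.5])
        assert cats.category["g0"] == "shared"

    def test_categories_partition_the_set(self):
        rng = np.random.default_rng(0)
        fpkm = pd.DataFrame({"t1": rng.exponential(1, 500),
                             "o1": rng.exponential(1, 500)},
                            index=[f"g{i}" for i in range(500)])
        cats = classify_expression(fpkm, two_sample_design())
        assert not cats.category.isna().any()
        summary = cats.summary()
        assert summary["n"].sum() == 500

    def test_bins_sum_to_specific_count(self):
        rng = np.random.default_rng(1)
        fpkm = pd.DataFrame({"t1": rng.exponential(3, 400),
                             "o1": np.zeros(400)},
                            index=[f"g{i}" for i in range(400)])
        cats = classify_expression(fpkm, two_sample_design())
        summary = cats.summary().set_index("category")
        n_spec = summary.loc["testis_specific", "n"]
        bins = summary.loc["testis_specific", ["low", "mid", "high"]].sum()
        assert bins == n_spec

    @pytest.mark.parametrize("fpkm,expected", [
        (0.05, None), (1.0, "low"), (2.0, "low"), (5.0, "mid"),
        (10.0, "mid"), (11.0, "high"),
    ])
    def test_bin_boundaries_fall_low(self, fpkm, expected):
        assert abundance_bin(fpkm) == expected


class TestExactConditionalTest:
    def test_balanced_split_equal_weights_p_one(self):
        assert _exact_conditional_p(10, 10, 1, 1, 0.0) == pytest.approx(1.0)

    def test_poisson_mode_matches_binomial_enumeration(self):
        # group weights 3:7, totals 30 vs 40
        got = _exact_conditional_p(30, 40, 3, 7, 0.0)
        pmf = stats.binom.pmf(np.arange(71), 70, 0.3)
        want = pmf[pmf <= pmf[30] * (1 + 1e-10)].sum()
        assert got == pytest.approx(want, rel=1e-9)

    def test_nb_mode_matches_direct_enumeration(self):
        na, nb, phi = 3.0, 4.0, 0.2
        t = 60
        mu = t / (na + nb)
        ra, rb = na / phi, nb / phi
        pa, pb = ra / (ra + na * mu), rb / (rb + nb * mu)
        k = np.arange(t + 1)
        joint = stats.nbinom.pmf(k, ra, pa) * stats.nbinom.pmf(t - k, rb, pb)
        joint /= joint.sum()
        want = joint[joint <= joint[45] * (1 + 1e-10)].sum()
        assert _exact_conditional_p(45, 15, na, nb, phi) == pytest.approx(want, rel=1e-6)

    def test_all_zero_transcript_gets_p_one(self, design):
        counts = CountMatrix(pd.DataFrame(
            {s: [0, 10] for s in design.samples}, index=["z", "x"]))
        res = nb_de_test(counts, design, dispersion_mode="poisson")
        assert res.loc["z", "p"] == 1.0
        assert res.loc["z", "log2fc"] == 0.0

    def test_identical_groups_not_significant(self):
        design = syn.default_design(3, 3)
        counts = CountMatrix(pd.DataFrame(
            {s: [50, 100] for s in design.samples}, index=["a", "b"]))
        res = nb_de_test(counts, design, dispersion_mode="poisson")
        assert res.loc["a", "p"] == pytest.approx(1.0, abs=0.05)


class TestBenjaminiHochberg:
    def test_hand_worked_step_up(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 100)
        _, want, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), want)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_and_bounded(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestDeClassify:
    def _fixture(self, testis_fpkm, ovary_fpkm, p):
        n = len(p)
        idx = [f"g{i}" for i in range(n)]
        stats_table = pd.DataFrame({"p": p, "log2fc": 0.0}, index=idx)
        fpkm = pd.DataFrame({"t1": testis_fpkm, "o1": ovary_fpkm}, index=idx)
        design = two_sample_design()
        cats = classify_expression(fpkm, design)
        return de_classify(stats_table, cats, design)

    def test_testis_specific_gene_flagged_inf(self):
        # Amh-like: solid testis expression, silent ovary
        de = self._fixture([8.0], [0.0], [1e-6])
        row = de.table.loc["g0"]
        assert row["call"] == "up_testis"
        assert row["tissue_specific"]
        assert row["log2fc_display"] == "inf"

    def test_subthreshold_fold_change_not_called(self):
        # log2fc ~0.9 with tiny FDR
        de = self._fixture([2.0], [3.92], [1e-6])
        assert abs(de.table.loc["g0", "log2fc"]) < 1.0
        assert de.table.loc["g0", "call"] == "not_DE"

    def test_boundary_fold_change_exactly_one_excluded(self):
        # (3.9+0.1)/(1.9+0.1) = 2 -> log2fc exactly 1.0, strict inequality
        de = self._fixture([1.9], [3.9], [1e-6])
        assert de.table.loc["g0", "log2fc"] == pytest.approx(1.0)
        assert de.table.loc["g0", "call"] == "not_DE"

    def test_fdr_gate_applies(self):
        de = self._fixture([1.0, 1.0], [8.0, 8.0], [0.5, 0.5])
        assert (de.table["call"] == "not_DE").all()


class TestPathwayEnrichment:
    def test_exact_combinatorial_value(self):
        universe = [f"u{i}" for i in range(20)]
        pathways = PathwayMap({"pw": frozenset(universe[:5])}, frozenset(universe))
        de_ids = universe[:5] + universe[10:15]
        res = pathway_enrichment(de_ids, universe, pathways)
        want = math.comb(15, 5) / math.comb(20, 10)
        assert res.loc["pw", "p"] == pytest.approx(want, rel=1e-9)
        assert res.loc["pw", "overlap"] == 5

    def test_de_equals_universe_gives_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        pathways = PathwayMap({"pw": frozenset(universe[:4])}, frozenset(universe))
        res = pathway_enrichment(universe, universe, pathways)
        assert res.loc["pw", "p"] == pytest.approx(1.0)

    def test_empty_de_set_all_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        pathways = PathwayMap({"pw": frozenset(universe[:4])}, frozenset(universe))
        res = pathway_enrichment([], universe, pathways)
        assert (res["p"] == 1.0).all()

    def test_corrected_p_at_least_raw(self):
        universe = [f"u{i}" for i in range(30)]
        pathways = PathwayMap({f"pw{j}": frozenset(universe[j:j + 6])
                               for j in range(5)}, frozenset(universe))
        res = pathway_enrichment(universe[:8], universe, pathways)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_de_outside_universe_rejected(self):
        pathways = PathwayMap({"pw": frozenset(["a"])}, frozenset(["a", "b"]))
        with pytest.raises(ValueError):
            pathway_enrichment(["z"], ["a", "b"], pathways)


class TestCrosstabPanel:
    def _de(self, calls):
        idx = list(calls)
        table = pd.DataFrame({
            "call": list(calls.values()), "log2fc": 0.0, "p": 0.5,
            "fdr": 0.5, "tissue_specific": False}, index=idx)
        from gonadiso.expression import DEResult
        return DEResult(table, ("testis", "ovary"))

    def test_empty_de_gives_zero_deus(self):
        de = self._de({"a": "not_DE", "b": "not_DE"})
        terms = PathwayMap({"term": frozenset(["a", "b"])}, frozenset(["a", "b"]))
        out = crosstab_panel(de, terms)
        assert out.loc["term", "n_unigenes"] == 2
        assert out.loc["term", "n_DEUs"] == 0

    def test_counts_by_enumeration(self):
        de = self._de({"a": "up_ovary", "b": "not_DE", "c": "up_testis"})
        terms = PathwayMap({"t1": frozenset(["a", "b"]),
                            "t2": frozenset(["a", "b", "c"])},
                           frozenset(["a", "b", "c"]))
        out = crosstab_panel(de, terms)
        assert out.loc["t1", "n_DEUs"] == 1
        assert out.loc["t2", "n_DEUs"] == 2

    def test_member_outside_universe_rejected(self):
        de = self._de({"a": "up_ovary"})
        terms = PathwayMap({"t": frozenset(["a", "ghost"])},
                           frozenset(["a", "ghost"]))
        with pytest.raises(ValueError):
            crosstab_panel(de, terms, universe_ids=["a"])
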