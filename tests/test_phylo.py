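import numpy as np
import pandas as pd
import pytest

from gonadiso.core_io import PanelAnnotation, Transcript, TranscriptSet
from gonadiso.lncrna import find_longest_orf
from gonadiso.phylo import (DistanceMatrix, bootstrap_support, distance_matrix,
                            filter_columns, nj_tree, p_distance, protein_mw,
                            summarize_panel, translate_orf)

WATER_KDA = 0.01802


class TestTranslateOrf:
    def test_minimal_orf(self):
        t = Transcript("t", "ATGTAA")
        orf = find_longest_orf(t)
        rec = translate_orf(orf, t)
        assert rec.protein == "M"
        assert rec.length_aa == 1

    def test_1290_nt_orf_gives_429_aa(self):
        body = "".join(["GCT"] * 428)
        t = Transcript("t", "C" * 604 + "ATG" + body + "TGA" + "C" * 1597)
        orf = find_longest_orf(t)
        rec = translate_orf(orf, t)
        assert orf.length == 1290
        assert rec.length_aa == 429
        assert (rec.utr5_len, rec.utr3_len) == (604, 1597)

    def test_utr_arithmetic_sums_to_full_length(self):
        body = "".join(["GCT"] * 442)
        t = Transcript("t", "A" * 367 + "ATG" + body + "TAA" + "A" * 1174)
        rec = translate_orf(find_longest_orf(t), t)
        assert rec.full_length == 367 + 1332 + 1174 == 2873
        assert rec.full_length == t.length


class TestProteinMw:
    def test_single_glycine(self):
        assert protein_mw("G") == pytest.approx(0.07507, abs=1e-4)

    def test_diglycine(self):
        assert protein_mw("GG") == pytest.approx(0.13212, abs=1e-4)

    def test_additivity_minus_water(self):
        a, b = "MKV", "GAW"
        assert protein_mw(a + b) == pytest.approx(
            protein_mw(a) + protein_mw(b) - WATER_KDA, abs=1e-4)

    def test_nonstandard_residue_named(self):
        with pytest.raises(ValueError, match="B"):
            protein_mw("GAB")


class TestPDistance:
    def test_identical_sequences_zero(self):
        assert p_distance("MKV" * 10, "MKV" * 10) == (0.0, 30)

    def test_two_mismatches_in_100(self):
        a = "A" * 100
        b = "A" * 98 + "WW"
        dist, used = p_distance(a, b)
        assert dist == pytest.approx(0.02)
        assert used == 100

    def test_gap_columns_excluded_pairwise(self):
        a = "A" * 100
        b = "A" * 99 + "-"
        dist, used = p_distance(a, b)
        assert used == 99
        assert dist == 0.0

    def test_all_gap_errors(self):
        with pytest.raises(ValueError):
            p_distance("---", "AAA")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            p_distance("AA", "AAA")


class TestPartialDeletion:
    def test_low_coverage_columns_dropped(self):
        aln = {"a": "AC-A", "b": "AC-A", "c": "ACAA", "d": "AC-A"}
        filtered = filter_columns(aln, coverage=0.95)
        assert filtered["a"] == "ACA"

    def test_full_coverage_keeps_all(self):
        aln = {"a": "ACDE", "b": "ACDE"}
        assert filter_columns(aln, 0.95) == aln


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(["x", "y", "z"], m))
        lengths = {c.name: bl for c, bl in tree.children}
        assert lengths == pytest.approx({"x": 1.0, "y": 2.0, "z": 3.0})

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((A:2,B:3):1,C:4,D:5) -> additive distances
        m = np.array([[0, 5, 7, 8], [5, 0, 8, 9],
                      [7, 8, 0, 9], [8, 9, 9, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), m))
        got = tree.leaf_distances()
        assert np.allclose(got.loc[list("ABCD"), list("ABCD")].values, m)
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_five_taxon_additive_path_lengths_reproduced(self):
        rng = np.random.default_rng(5)
        # build a random additive matrix from a caterpillar tree
        bl = rng.uniform(0.5, 3.0, size=7)
        # ((A:bl0,B:bl1):bl4,(C:bl2,D:bl3):bl5,E:bl6)
        ids = list("ABCDE")
        coords = {
            "A": [("u", bl[0] + bl[4])], }
        m = np.zeros((5, 5))
        def path(x, y):
            up = {"A": bl[0] + bl[4], "B": bl[1] + bl[4],
                  "C": bl[2] + bl[5], "D": bl[3] + bl[5], "E": bl[6]}
            side = {"A": "l", "B": "l", "C": "r", "D": "r", "E": "e"}
            if side[x] == side[y]:
                base = {"A": bl[0], "B": bl[1], "C": bl[2], "D": bl[3]}
                return base[x] + base[y]
            return up[x] + up[y]
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    m[i, j] = m[j, i] = path(x, y)
        tree = nj_tree(DistanceMatrix(ids, m))
        got = tree.leaf_distances().loc[ids, ids].values
        assert np.allclose(got, m, atol=1e-9)

    def test_matches_skbio_topology(self):
        import skbio
        rng = np.random.default_rng(11)
        n = 6
        pts = rng.uniform(0, 1, size=(n, 8))
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                m[i, j] = np.abs(pts[i] - pts[j]).sum()
        ids = [f"t{i}" for i in range(n)]
        ours = nj_tree(DistanceMatrix(ids, m))
        sk = skbio.tree.nj(skbio.DistanceMatrix(m, ids))
        sk_bips = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < n - 1:
                if ids[0] in side:
                    side = frozenset(ids) - side
                sk_bips.add(side)
        assert ours.bipartitions() == sk_bips

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_branch_lengths_nonnegative(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(0.1, 1.0, (6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(6)], m))

        def walk(node):
            for c, bl in node.children:
                assert bl >= 0
                walk(c)
        walk(tree)


class TestBootstrap:
    def _congruent_alignment(self):
        # every site supports ((A,B),(C,D)) vs E
        pattern = {"A": "K", "B": "K", "C": "R", "D": "R", "E": "G"}
        noise = {"A": "KKLL", "B": "KKLM", "C": "RRNN", "D": "RRNP", "E": "GGQQ"}
        return {k: pattern[k] * 40 + noise[k] for k in pattern}

    def test_congruent_alignment_full_support(self):
        tree = bootstrap_support(self._congruent_alignment(), n_reps=50, seed=3)
        supports = []

        def walk(node):
            for c, _ in node.children:
                if c.support is not None:
                    supports.append(c.support)
                walk(c)
        walk(tree)
        assert supports and all(s == 100.0 for s in supports)

    def test_deterministic_under_seed(self):
        aln = self._congruent_alignment()
        t1 = bootstrap_support(aln, n_reps=20, seed=9)
        t2 = bootstrap_support(aln, n_reps=20, seed=9)
        assert t1.newick() == t2.newick()

    def test_invariant_to_taxon_order(self):
        aln = self._congruent_alignment()
        shuffled = dict(reversed(list(aln.items())))
        t1 = bootstrap_support(aln, n_reps=20, seed=9)
        t2 = bootstrap_support(shuffled, n_reps=20, seed=9)
        assert t1.bipartitions() == t2.bipartitions()


class TestSummarizePanel:
    def _toy(self):
        orf = "ATG" + "GCT" * 120 + "TAA"
        ts = TranscriptSet([
            Transcript("x1", "CCCC" + orf + "CCCC"),
            Transcript("x2", "CC" + orf + "CC"),
            Transcript("x3", "C" * 600),          # no ORF
            Transcript("y1", "CC" + orf),
        ])
        ann = PanelAnnotation({"x1": "GeneX", "x2": "GeneX", "x3": "GeneX",
                               "y1": "GeneY"})
        return ts, ann

    def test_member_and_orf_counts(self):
        ts, ann = self._toy()
        (gx, gy) = summarize_panel(ann, ts, orf_aa_min=100)
        assert (gx.gene, gx.n_unigenes, gx.n_with_orf) == ("GeneX", 3, 2)
        assert (gy.n_unigenes, gy.n_with_orf) == (1, 1)
        assert gx.length_min == min(ts[m].length for m in gx.members)

    def test_tissue_specific_direction_propagated(self):
        ts, ann = self._toy()
        table = pd.DataFrame({
            "call": ["up_testis", "not_DE", "not_DE", "not_DE"],
            "log2fc": [5.0, 0.1, 0.0, 0.0],
            "p": 0.001, "fdr": 0.001,
            "tissue_specific": [True, False, False, False],
        }, index=["x1", "x2", "x3", "y1"])
        from gonadiso.expression import DEResult
        de = DEResult(table, ("testis", "ovary"))
        gx = summarize_panel(ann, ts, de)[0]
        assert gx.de_call == "up_testis"
        assert gx.tissue_specific

    def test_unknown_transcript_rejected(self):
        ts, _ = self._toy()
        with pytest.raises(ValueError, match="ghost"):
            summarize_panel(PanelAnnotation({"ghost": "GeneZ"}), ts)

    def test_empty_panel_gives_empty_summary(self):
        ts, _ = self._toy()
        assert summarize_panel(PanelAnnotation({}), ts) == []
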