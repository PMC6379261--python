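"""Alignment filtering, distances, NJ/UPGMA trees, bootstrap."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from taxongauge import phylo
from taxongauge import synthetic_data as sd
from taxongauge.phylo import ConcatenatedAlignment, DistanceMatrixP, MarkerAlignment


def _aln(gene, **rows):
    return MarkerAlignment(gene, rows)


class TestGapElimination:
    def test_basic_example(self):
        filtered = phylo.remove_gap_columns(_aln("g", a="A-C", b="AGC"))
        assert filtered.rows == {"a": "AC", "b": "AC"}

    def test_gapless_alignment_unchanged_and_idempotent(self):
        aln = _aln("g", a="ACGT", b="AGGT")
        once = phylo.remove_gap_columns(aln)
        twice = phylo.remove_gap_columns(once)
        assert once.rows == aln.rows == twice.rows

    def test_matches_brute_force_column_scan(self, rng):
        ids = [f"s{i}" for i in range(10)]
        chars = list("ACGT-N")
        matrix = rng.choice(chars, size=(10, 120), p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06])
        rows = {i: "".join(r) for i, r in zip(ids, matrix)}
        filtered = phylo.remove_gap_columns(MarkerAlignment("g", rows))
        bad = sum(
            1
            for col in range(120)
            if any(rows[i][col] in "-.NX" for i in ids)
        )
        assert filtered.length == 120 - bad

    def test_all_columns_gapped_rejected(self):
        with pytest.raises(ValueError, match="no columns"):
            phylo.remove_gap_columns(_aln("g", a="A-N", b="-GN"))


class TestConcatenation:
    def test_mlsa_gene_lengths_sum(self):
        """atpD+leuS+rplB+gyrB filtered lengths produce a 6,333-bp matrix."""
        lengths = {"atpD": 1278, "leuS": 2571, "rplB": 822, "gyrB": 1662}
        tree = TreeNode.read(io.StringIO("(x:0.1,y:0.1);"))
        markers = sd.generate_markers(tree, lengths, seed=1)
        concat = phylo.concatenate([markers[g] for g in ["atpD", "leuS", "rplB", "gyrB"]])
        assert concat.gene_order == ["atpD", "leuS", "rplB", "gyrB"]
        assert concat.total_length == 6333
        assert all(len(s) == 6333 for s in concat.rows.values())

    def test_single_gene_identity(self):
        aln = _aln("g", a="ACGT", b="AGGT")
        concat = phylo.concatenate([aln])
        assert concat.rows == aln.rows

    def test_strain_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="strain sets differ"):
            phylo.concatenate([_aln("g1", a="AC", b="AC"), _aln("g2", a="AC", c="AC")])


class TestPercentIdentity:
    def test_examples(self):
        assert phylo.percent_identity("ACGT", "ACGT") == 100.0
        assert phylo.percent_identity("ACGT", "ACGA") == 75.0

    def test_pairwise_deletion(self):
        assert phylo.percent_identity("AC-T", "ACNT") == 100.0

    def test_no_comparable_columns(self):
        with pytest.raises(ValueError):
            phylo.percent_identity("--", "AC")


class TestDistances:
    def test_identical_rows_zero(self):
        d = phylo.distance_matrix(_aln("g", a="ACGT", b="ACGT", c="ACGA"))
        assert d.values[0, 1] == 0.0

    def test_jc69_closed_form(self):
        # 1 difference in 10 sites: p = 0.10 -> d = 0.107326
        rows = {"a": "ACGTACGTAC", "b": "ACGTACGTAT", "c": "ACGTACGTAC"}
        d = phylo.distance_matrix(MarkerAlignment("g", rows), model="jc69")
        expected = -0.75 * np.log(1 - 4 * 0.10 / 3)
        assert d.values[0, 1] == pytest.approx(expected, abs=1e-9)
        assert d.values[0, 1] == pytest.approx(0.10732, abs=1e-5)

    def test_jc69_saturation_error_names_pair(self):
        rows = {"a": "AAAA", "b": "CCCC", "c": "AAAA"}
        with pytest.raises(ValueError, match="a.*b"):
            phylo.distance_matrix(MarkerAlignment("g", rows), model="jc69")

    def test_symmetry_zero_diagonal(self, rng):
        matrix = rng.choice(list("ACGT"), size=(5, 60))
        rows = {f"s{i}": "".join(r) for i, r in enumerate(matrix)}
        d = phylo.distance_matrix(MarkerAlignment("g", rows))
        np.testing.assert_allclose(d.values, d.values.T)
        np.testing.assert_allclose(np.diag(d.values), 0.0)


class TestTrees:
    def test_nj_three_taxon_closed_form(self):
        d = DistanceMatrixP(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), "p-distance")
        tree = phylo.nj_tree(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_nj_recovers_additive_four_taxon_tree(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) -> additive distances
        d_values = np.array(
            [
                [0, 3, 8, 9],
                [3, 0, 9, 10],
                [8, 9, 0, 9],
                [9, 10, 9, 0],
            ],
            float,
        )
        d = DistanceMatrixP(list("ABCD"), d_values, "p-distance")
        tree = phylo.nj_tree(d)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                        d_values[i, j], abs=1e-6
                    )

    def test_nj_agrees_with_skbio_oracle(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        points = rng.normal(size=(7, 4))
        dist = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(7)]
        ours = phylo.nj_tree(DistanceMatrixP(ids, dist, "p-distance"))
        theirs = skbio_nj(DistanceMatrix(dist, ids))
        assert ours.compare_rfd(theirs) == 0.0

    def test_upgma_is_ultrametric_and_recovers_clock_tree(self):
        tree_in = TreeNode.read(
            io.StringIO("((a:0.05,b:0.05):0.15,(c:0.08,d:0.08):0.12);")
        )
        markers = sd.generate_markers(tree_in, {"g": 4000}, seed=2)
        d = phylo.distance_matrix(markers["g"], model="jc69")
        tree = phylo.upgma_tree(d)
        depths = [tree.distance(t) for t in tree.tips()]
        assert np.ptp(depths) < 1e-9
        assert {t.name for t in tree.find("a").parent.tips()} == {"a", "b"}
        assert {t.name for t in tree.find("c").parent.tips()} == {"c", "d"}

    def test_non_finite_distances_rejected(self):
        bad = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            phylo.nj_tree(DistanceMatrixP(list("abc"), bad, "p-distance"))


@pytest.fixture(scope="module")
def divergent_alignment():
    tree = TreeNode.read(
        io.StringIO("((s1:0.02,s2:0.02):0.4,((s3:0.02,s4:0.02):0.4,(s5:0.02,s6:0.02):0.4):0.1);")
    )
    return sd.generate_markers(tree, {"g": 1500}, seed=3)["g"]


class TestBootstrap:
    def test_high_divergence_gives_high_support(self, divergent_alignment):
        tree = phylo.bootstrap_support(divergent_alignment, phylo.nj_tree, n_replicates=200, seed=4)
        supports = [n.support for n in tree.non_tips() if hasattr(n, "support")]
        assert supports and all(s >= 99.0 for s in supports)

    def test_same_seed_reproducible_and_in_range(self, divergent_alignment):
        t1 = phylo.bootstrap_support(divergent_alignment, phylo.nj_tree, n_replicates=50, seed=5)
        t2 = phylo.bootstrap_support(divergent_alignment, phylo.nj_tree, n_replicates=50, seed=5)
        s1 = [n.support for n in t1.non_tips() if hasattr(n, "support")]
        s2 = [n.support for n in t2.non_tips() if hasattr(n, "support")]
        assert s1 == s2
        assert all(0.0 <= s <= 100.0 for s in s1)

    def test_supports_converge_with_replicates(self, divergent_alignment):
        t_small = phylo.bootstrap_support(divergent_alignment, phylo.nj_tree, n_replicates=100, seed=6)
        t_large = phylo.bootstrap_support(divergent_alignment, phylo.nj_tree, n_replicates=400, seed=7)
        s_small = sorted(n.support for n in t_small.non_tips() if hasattr(n, "support"))
        s_large = sorted(n.support for n in t_large.non_tips() if hasattr(n, "support"))
        assert np.allclose(s_small, s_large, atol=5.0)
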