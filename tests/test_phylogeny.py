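"""Progressive alignment, p-distance, neighbor joining and bootstrap.

NJ is validated two ways: exact reconstruction of additive matrices
derived from random trees (path-length oracle), and topological agreement
with scikit-bio's independent NJ on a non-trivial matrix.
"""

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from comapan.io_core import SeqRecord
from comapan.phylogeny import (
    MultipleAlignment,
    align_family,
    bipartitions,
    bootstrap,
    collapse_low_support,
    concatenate,
    nj,
    p_distance,
    subset_tree,
)
from comapan.simulate import evolve_alignment


def prot(seq, locus="L1", genome="G1"):
    return SeqRecord(genome, locus, "protein", seq)


def random_additive_tree(n_taxa, rng):
    """Random topology by sequential joining; branch lengths in [0.1, 1]."""
    nodes = [TreeNode(name=f"T{i}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        nodes.append(TreeNode(children=[a, b]))
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
    return TreeNode(children=nodes)


def tree_distances(tree, ids):
    d = np.zeros((len(ids), len(ids)))
    tips = {t.name: t for t in tree.tips()}
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            d[i, j] = d[j, i] = tips[a].distance(tips[ids[j]])
    return DistanceMatrix(d, ids=ids)


class TestAlignFamily:
    def test_identical_sequences_gap_free(self):
        recs = [prot("MKVLITG", genome=f"G{i}") for i in range(4)]
        aln = align_family(recs)
        assert all("-" not in row for row in aln.rows)
        assert aln.length == 7

    def test_two_sequences_match_global_oracle(self):
        """A two-member family reduces to plain global alignment: the score
        of the emitted pair equals Biopython's optimal global score."""
        from Bio import Align

        a, b = "MKVLITGGSGFIGSAW", "MKVLITGAGFIGSW"
        aln = align_family([prot(a), prot(b, genome="G2")])
        oracle = Align.PairwiseAligner()
        oracle.mode = "global"
        from Bio.Align import substitution_matrices

        oracle.substitution_matrix = substitution_matrices.load("BLOSUM62")
        oracle.open_gap_score = -12
        oracle.extend_gap_score = -1

        def score_pair(r1, r2):
            from comapan.homology import _MATRIX

            alph = "ARNDCQEGHILKMFPSTWYVBZX*"
            total, in_gap = 0.0, False
            for x, y in zip(r1, r2):
                if x == "-" or y == "-":
                    total += -1 if in_gap else -12
                    in_gap = True
                else:
                    total += _MATRIX[alph.index(x), alph.index(y)]
                    in_gap = False
            return total

        assert score_pair(*aln.rows) == oracle.score(a, b)

    def test_row_order_follows_input_content_invariant(self):
        recs = [prot("MKVLITGGSG", genome=f"G{i}") for i in range(3)]
        recs[1] = prot("MKVLITGASG", genome="G1")
        recs[2] = prot("MKVLITGGSG", genome="G2")
        fwd = align_family(recs)
        rev = align_family(list(reversed(recs)))
        assert dict(zip(fwd.ids, fwd.rows)) == dict(zip(rev.ids, rev.rows))

    def test_single_sequence_passthrough(self):
        aln = align_family([prot("MKV")])
        assert aln.rows == ["MKV"]


class TestConcatenate:
    def test_lengths_add(self):
        a = MultipleAlignment(["x", "y"], ["MKVL", "MKIL"])
        b = MultipleAlignment(["y", "x"], ["GGSGFIGSA", "GGAGFIGSA"])
        cat = concatenate({"F1": a, "F2": b})
        assert cat.length == 13

    def test_taxa_mismatch_names_family(self):
        a = MultipleAlignment(["x", "y"], ["MK", "MK"])
        b = MultipleAlignment(["x", "z"], ["GG", "GG"])
        with pytest.raises(ValueError, match="F2"):
            concatenate({"F1": a, "F2": b})

    def test_self_concatenation_preserves_distances(self):
        a = MultipleAlignment(["x", "y", "z"], ["MKVLAA", "MKILAA", "MKVLGA"])
        single = p_distance(a)
        doubled = p_distance(concatenate({"F1": a, "F2": a}))
        assert np.allclose(single.data, doubled.data)


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment(["a", "b"], ["MKVL", "MKVL"])
        assert p_distance(aln)["a", "b"] == 0.0

    def test_quarter_difference(self):
        aln = MultipleAlignment(["a", "b"], ["AAAA", "AAAT"])
        assert p_distance(aln)["a", "b"] == 0.25

    def test_pairwise_deletion_hand_count(self):
        # columns: (A,A) same, (-,C) gap, (C,X) unknown, (D,A) diff
        # -> comparable {1, 4}, differing {4} -> 1/2
        aln = MultipleAlignment(["a", "b"], ["A-CD", "ACXA"])
        assert p_distance(aln)["a", "b"] == 0.5

    def test_no_comparable_sites_rejected(self):
        aln = MultipleAlignment(["a", "b"], ["A--", "-AA"])
        with pytest.raises(ValueError, match="comparable"):
            p_distance(aln)


class TestNeighborJoining:
    def test_textbook_additive_matrix(self):
        d = DistanceMatrix(
            np.array([[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
                     dtype=float),
            ids=list("ABCD"),
        )
        tree = nj(d)
        for i, a in enumerate("ABCD"):
            for b in "ABCD"[i + 1:]:
                assert tree.find(a).distance(tree.find(b)) == pytest.approx(d[a, b])

    @pytest.mark.parametrize("seed", range(6))
    def test_random_additive_trees_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        truth = random_additive_tree(n, rng)
        ids = sorted(t.name for t in truth.tips())
        dm = tree_distances(truth, ids)
        rec = nj(dm)
        assert rec.compare_rfd(truth) == 0.0
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert rec.find(a).distance(rec.find(b)) == pytest.approx(dm[a, b])

    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float),
                           ids=list("ABC"))
        tree = nj(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": pytest.approx(0.5), "B": pytest.approx(1.5),
                           "C": pytest.approx(2.5)}

    def test_equidistant_ties_deterministic(self):
        d = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("ABCD"))
        trees = [str(nj(d)) for _ in range(3)]
        assert len(set(trees)) == 1

    def test_two_taxa_single_edge(self):
        d = DistanceMatrix(np.array([[0, 3.0], [3.0, 0]]), ids=["A", "B"])
        tree = nj(d)
        assert tree.find("A").distance(tree.find("B")) == pytest.approx(3.0)

    def test_agrees_with_skbio_topology(self, rng):
        """Independent-implementation cross-check on a noisy matrix."""
        truth = random_additive_tree(7, rng)
        ids = sorted(t.name for t in truth.tips())
        dm = tree_distances(truth, ids)
        noisy = dm.data + rng.normal(0, 0.01, dm.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        noisy = np.abs(noisy)
        dmn = DistanceMatrix(noisy, ids=ids)
        assert nj(dmn).compare_rfd(skbio_nj(dmn)) == 0.0

    def test_asymmetric_matrix_rejected(self):
        # skbio's DistanceMatrix is symmetric by construction, so feed a
        # bare duck-typed matrix to exercise the check
        class Fake:
            ids = ["a", "b", "c"]
            data = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)

        with pytest.raises(ValueError, match="symmetric"):
            nj(Fake())


class TestBootstrap:
    def _alignment(self, seed=5, length=2000):
        newick = "((A:0.02,B:0.02):0.03,(C:0.02,D:0.02):0.03,(E:0.02,F:0.02):0.03);"
        tree = TreeNode.read([newick])
        tips = evolve_alignment(tree, length, seed=seed)
        ids = sorted(tips)
        return tree, MultipleAlignment(ids, [tips[k] for k in ids])

    def test_deterministic_under_seed(self):
        _, aln = self._alignment()
        t1 = bootstrap(aln, reps=25, seed=9)
        t2 = bootstrap(aln, reps=25, seed=9)
        assert str(t1) == str(t2)

    def test_strong_signal_full_support_and_topology(self):
        truth, aln = self._alignment(length=10000)
        tree = bootstrap(aln, reps=100, seed=1)
        assert tree.compare_rfd(truth) == 0.0
        supports = [int(n.name) for n in tree.non_tips(include_self=False)
                    if n.name is not None]
        assert supports and all(s == 100 for s in supports)

    def test_single_replicate_supports_binary(self):
        _, aln = self._alignment(length=300)
        tree = bootstrap(aln, reps=1, seed=2)
        supports = {int(n.name) for n in tree.non_tips(include_self=False)
                    if n.name is not None}
        assert supports <= {0, 100}

    def test_supports_invariant_to_taxon_order(self):
        _, aln = self._alignment(length=1500)
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = MultipleAlignment([aln.ids[i] for i in perm],
                                     [aln.rows[i] for i in perm])
        t1 = bootstrap(aln, reps=30, seed=4)
        t2 = bootstrap(shuffled, reps=30, seed=4)

        def support_map(tree):
            out = {}
            all_tips = {t.name for t in tree.tips()}
            ref = min(all_tips)
            for n in tree.non_tips(include_self=False):
                side = {t.name for t in n.tips()}
                if ref in side:
                    side = all_tips - side
                if n.name is not None:
                    out[frozenset(side)] = int(n.name)
            return out

        assert support_map(t1) == support_map(t2)

    def test_invalid_reps(self):
        _, aln = self._alignment(length=300)
        with pytest.raises(ValueError):
            bootstrap(aln, reps=0)


class TestCollapseAndSubset:
    def test_collapse_below_threshold(self):
        tree = TreeNode.read(["((A:1,B:1)55:1,(C:1,D:1)90:1,(E:1,F:1)70:1);"])
        out = collapse_low_support(tree, 60.0)
        supports = [n.name for n in out.non_tips(include_self=False)]
        assert "55" not in supports and "90" in supports
        assert len(list(out.non_tips(include_self=False))) == 2

    def test_subset_tree_recovers_generating_topology(self):
        """Tree-aware families: subset tree reproduces the guide tree."""
        from comapan.orthology import GeneFamily
        from comapan.simulate import SimParams, gen_presence, gen_proteomes

        newick = ("((G01:0.02,G02:0.02):0.04,(G03:0.02,G04:0.02):0.04,"
                  "(G05:0.02,G06:0.02):0.04);")
        guide = TreeNode.read([newick])
        params = SimParams(n_genomes=6, core_families=25, accessory_families=0,
                           unique_mean=0, rng_seed=21)
        ledger = gen_presence(params)
        proteomes = gen_proteomes(ledger, params, tree=guide)
        fams = [GeneFamily(fid, ledger.member_map[fid]) for fid in ledger.family_ids]
        tree = subset_tree([f.family_id for f in fams], fams, proteomes,
                           bootstrap_reps=50, seed=3)
        assert tree.compare_rfd(guide) == 0.0
        supports = [int(n.name) for n in tree.non_tips(include_self=False)
                    if n.name is not None]
        assert all(s >= 90 for s in supports)

    def test_subset_tree_requires_single_copy(self):
        from comapan.orthology import GeneFamily

        fams = [GeneFamily("F1", [("G1", "a"), ("G1", "b"), ("G2", "c")])]
        proteomes = {
            "G1": [prot("MKVL", locus="a", genome="G1"),
                   prot("MKVL", locus="b", genome="G1")],
            "G2": [prot("MKVL", locus="c", genome="G2")],
        }
        with pytest.raises(ValueError, match="single-copy"):
            subset_tree(["F1"], fams, proteomes, genomes=["G1", "G2"],
                        bootstrap_reps=1)
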