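"""Homology graph construction, Markov clustering and family classification.

The MCL checks compare against an independent straight-line implementation
of the algorithm written here (expansion / inflation / prune loop, clusters
read as connected components of the limit matrix's nonzero structure).
"""

import math

import numpy as np
import pytest

from comapan.homology import HomologyPair
from comapan.orthology import (
    GeneFamily,
    HomologyGraph,
    Edge,
    build_graph,
    classify,
    mcl,
    read_families_tsv,
    write_families_tsv,
)


def pair(q, s, evalue, qg=None, sg=None):
    qg = qg or q.split("|")[0]
    sg = sg or s.split("|")[0]
    return HomologyPair(q, s, qg, sg, 100.0, 90.0, 95.0, evalue)


def graph_from_weights(edges):
    """Unit-test helper: a normalized graph straight from (u, v, weight)."""
    nodes = sorted({n for e in edges for n in e[:2]})
    node_genome = {n: n.split("|")[0] for n in nodes}
    es = [
        Edge(u, v, w, node_genome[u], node_genome[v], norm_weight=w)
        for u, v, w in edges
    ]
    return HomologyGraph(nodes, es, node_genome)


class TestBuildGraph:
    def test_two_singleton_genomes_mutual_best(self):
        g = build_graph([pair("A|a1", "B|b1", 1e-100)])
        (edge,) = g.edges
        assert edge.edge_class == "ortholog-candidate"
        assert edge.norm_weight == pytest.approx(1.0)  # self-normalizing mean

    def test_duplicate_pair_inparalog(self):
        pairs = [
            pair("A|a1", "B|b1", 1e-80),
            pair("A|a2", "B|b1", 1e-60),
            pair("A|a1", "A|a2", 1e-90),
        ]
        g = build_graph(pairs)
        classes = {frozenset((e.u, e.v)): e.edge_class for e in g.edges}
        assert classes[frozenset(("A|a1", "A|a2"))] == "inparalog"

    def test_hand_worked_three_genome_table(self):
        """Every class and normalized weight on a 5-edge toy, worked by hand:

        a1-b1 w=100 (RBH), a2-b1 w=50 (one-sided best), a1-c1 w=80 (RBH),
        b1-c1 w=60 (RBH), a1-a2 w=90 (intra, >= a2's best inter 50).
        A-B candidate mean = 100, A-C mean = 80, B-C mean = 60,
        A inparalog mean = 90.
        """
        pairs = [
            pair("A|a1", "B|b1", 1e-100),
            pair("A|a2", "B|b1", 1e-50),
            pair("A|a1", "C|c1", 1e-80),
            pair("B|b1", "C|c1", 1e-60),
            pair("A|a1", "A|a2", 1e-90),
        ]
        g = build_graph(pairs)
        by_key = {frozenset((e.u, e.v)): e for e in g.edges}

        e = by_key[frozenset(("A|a1", "B|b1"))]
        assert (e.edge_class, e.norm_weight) == ("ortholog-candidate", pytest.approx(1.0))
        e = by_key[frozenset(("A|a2", "B|b1"))]
        assert (e.edge_class, e.norm_weight) == ("co-ortholog", pytest.approx(0.5))
        e = by_key[frozenset(("A|a1", "C|c1"))]
        assert (e.edge_class, e.norm_weight) == ("ortholog-candidate", pytest.approx(1.0))
        e = by_key[frozenset(("B|b1", "C|c1"))]
        assert (e.edge_class, e.norm_weight) == ("ortholog-candidate", pytest.approx(1.0))
        e = by_key[frozenset(("A|a1", "A|a2"))]
        assert (e.edge_class, e.norm_weight) == ("inparalog", pytest.approx(1.0))

    def test_raw_weight_capped_at_evalue_floor(self):
        g = build_graph([pair("A|a1", "B|b1", 0.0)])
        assert g.edges[0].raw_weight == 300.0

    def test_isolated_loci_become_nodes(self):
        g = build_graph([pair("A|a1", "B|b1", 1e-20)],
                        loci=[("A|a1", "A"), ("B|b1", "B"), ("C|c1", "C")])
        assert "C|c1" in g.nodes


def mcl_oracle(matrix, inflation=1.5, prune=1e-6, tol=1e-8, max_iter=200):
    """Independent MCL semantics: limit matrix, clusters from the nonzero
    structure's connected components."""
    m = np.asarray(matrix, dtype=float)
    loops = m.max(axis=0)
    loops[loops <= 0] = 1.0
    np.fill_diagonal(m, loops)
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = m**inflation
        m[m < prune] = 0.0
        m = m / m.sum(axis=0, keepdims=True)
        if np.max(np.abs(m - prev)) < tol:
            break
    adj = (m + m.T) > 0
    n = len(m)
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(np.flatnonzero(adj[x]))
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestMcl:
    def test_disjoint_triangles_stay_apart(self):
        edges = [("A|1", "A|2", 1.0), ("A|2", "A|3", 1.0), ("A|1", "A|3", 1.0),
                 ("B|4", "B|5", 1.0), ("B|5", "B|6", 1.0), ("B|4", "B|6", 1.0)]
        fams = mcl(graph_from_weights(edges))
        assert sorted(len(f) for f in fams) == [3, 3]

    def test_isolated_node_is_singleton(self):
        g = HomologyGraph(["A|1"], [], {"A|1": "A"})
        fams = mcl(g)
        assert len(fams) == 1 and len(fams[0]) == 1

    def test_barbell_splits_like_oracle(self):
        """Two triangles joined by a weak bridge: implementation and the
        independent oracle agree on the 2-cluster split."""
        names = ["A|1", "A|2", "A|3", "B|4", "B|5", "B|6"]
        edges = [("A|1", "A|2", 1.0), ("A|2", "A|3", 1.0), ("A|1", "A|3", 1.0),
                 ("B|4", "B|5", 1.0), ("B|5", "B|6", 1.0), ("B|4", "B|6", 1.0),
                 ("A|3", "B|4", 0.1)]
        fams = mcl(graph_from_weights(edges))
        got = {
            frozenset(names.index(f"{g}|{l}") for g, l in fam.members)
            for fam in fams
        }
        mat = np.zeros((6, 6))
        for u, v, w in edges:
            i, j = names.index(u), names.index(v)
            mat[i, j] = mat[j, i] = w
        assert got == mcl_oracle(mat)
        assert len(fams) == 2

    def test_families_partition_nodes(self, small_sim):
        from comapan.homology import all_vs_all

        _, ledger, proteomes = small_sim
        pairs = all_vs_all(proteomes, kmer_size=5, min_shared_kmers=3)
        loci = [(r.id, r.genome_id) for recs in proteomes.values() for r in recs]
        g = build_graph(pairs, loci=loci)
        fams = mcl(g)
        all_members = [f"{gm}|{l}" for f in fams for gm, l in f.members]
        assert len(all_members) == len(set(all_members)) == len(loci)

    def test_idempotent_on_converged_clusters(self):
        edges = [("A|1", "A|2", 1.0), ("A|2", "A|3", 1.0), ("A|1", "A|3", 1.0)]
        g = graph_from_weights(edges)
        first = mcl(g)
        second = mcl(g)
        assert [f.members for f in first] == [f.members for f in second]

    def test_invalid_inflation(self):
        with pytest.raises(ValueError):
            mcl(graph_from_weights([("A|1", "B|2", 1.0)]), inflation=1.0)


class TestClassify:
    def test_core_and_single_copy(self):
        fams = [GeneFamily("F1", [("G1", "a"), ("G2", "b"), ("G3", "c")])]
        cls = classify(fams, ["G1", "G2", "G3"])
        assert cls.family_class["F1"] == "core"
        assert cls.single_copy_core == ["F1"]

    def test_multi_copy_core_not_single_copy(self):
        fams = [GeneFamily("F1", [("G1", "a"), ("G1", "a2"), ("G2", "b")])]
        cls = classify(fams, ["G1", "G2"])
        assert cls.family_class["F1"] == "core"
        assert cls.single_copy_core == []

    def test_singleton_is_unique_gene(self):
        fams = [
            GeneFamily("F1", [("G1", "a"), ("G2", "b")]),
            GeneFamily("F2", [("G1", "u1"), ("G1", "u2")]),
        ]
        cls = classify(fams, ["G1", "G2"])
        assert cls.family_class["F2"] == "unique"
        assert cls.unique_gene_counts["G1"] == 2  # unique genes counted as genes
        assert cls.pan_count == 2

    def test_unknown_genome_rejected(self):
        fams = [GeneFamily("F1", [("G9", "a")])]
        with pytest.raises(ValueError):
            classify(fams, ["G1"])

    def test_families_tsv_round_trip(self, tmp_path):
        fams = [
            GeneFamily("F1", [("G1", "a"), ("G2", "b")]),
            GeneFamily("F2", [("G1", "c")]),
        ]
        path = tmp_path / "fams.tsv"
        write_families_tsv(fams, path)
        again = read_families_tsv(path)
        assert [(f.family_id, f.members) for f in again] == [
            (f.family_id, f.members) for f in fams
        ]
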