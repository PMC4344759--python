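"""Ortholog-family inference from filtered homology pairs.

The retained all-vs-all pairs become an undirected weighted graph
(raw weight -log10 E, floored at E = 1e-300).  Edges are classified as
ortholog candidates (reciprocal best inter-genome hits), inparalogs
(within-genome pairs at least as strong as a member's best inter-genome
hit) and co-orthologs (inter-genome edges connecting inparalogs of
ortholog candidates); weights are then normalized per genome pair by the
mean ortholog-candidate weight (per genome by the mean inparalog weight for
within-genome edges) and the normalized graph is partitioned by Markov
clustering into gene families.

Families are classified against the genome list: core families span every
genome, unique genes sit in families confined to one genome, and the pan
genome is the set of all families including singletons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .homology import HomologyPair

EVALUE_FLOOR = 1e-300
RAW_WEIGHT_CAP = 300.0


@dataclass
class Edge:
    u: str
    v: str
    raw_weight: float
    genome_u: str
    genome_v: str
    edge_class: str = "other"
    norm_weight: float = 0.0

    @property
    def is_intra(self) -> bool:
        return self.genome_u == self.genome_v


@dataclass
class HomologyGraph:
    nodes: list[str]
    edges: list[Edge]
    node_genome: dict[str, str]

    def adjacency(self) -> dict[str, list[Edge]]:
        adj: dict[str, list[Edge]] = {n: [] for n in self.nodes}
        for e in self.edges:
            adj[e.u].append(e)
            adj[e.v].append(e)
        return adj


def build_graph(
    pairs: list[HomologyPair], loci: list[tuple[str, str]] | None = None
) -> HomologyGraph:
    """Assemble, classify and normalize the homology graph.

    ``loci`` optionally supplies the full (record_id, genome_id) universe so
    that proteins without any retained hit appear as isolated nodes and
    survive as singleton families.
    """
    if not pairs and not loci:
        raise ValueError("no pairs and no locus universe given")

    node_genome: dict[str, str] = {}
    if loci:
        for rid, gid in loci:
            node_genome[rid] = gid

    edges: list[Edge] = []
    seen: set[frozenset] = set()
    for p in pairs:
        key = frozenset((p.query_id, p.subject_id))
        if key in seen:
            continue
        seen.add(key)
        w = min(RAW_WEIGHT_CAP, -math.log10(max(p.evalue, EVALUE_FLOOR)))
        edges.append(Edge(p.query_id, p.subject_id, w, p.query_genome, p.subject_genome))
        node_genome.setdefault(p.query_id, p.query_genome)
        node_genome.setdefault(p.subject_id, p.subject_genome)

    nodes = sorted(node_genome)
    graph = HomologyGraph(nodes, edges, node_genome)
    _classify_edges(graph)
    _normalize_weights(graph)
    return graph


def _classify_edges(graph: HomologyGraph) -> None:
    # Best inter-genome weight per (node, partner genome) and overall.
    best_to: dict[tuple[str, str], float] = {}
    best_inter: dict[str, float] = {}
    for e in graph.edges:
        if e.is_intra:
            continue
        for node, other_genome in ((e.u, e.genome_v), (e.v, e.genome_u)):
            key = (node, other_genome)
            if e.raw_weight > best_to.get(key, -1.0):
                best_to[key] = e.raw_weight
            if e.raw_weight > best_inter.get(node, -1.0):
                best_inter[node] = e.raw_weight

    # Ortholog candidates: reciprocal best hits between two genomes
    # (ties all count as best).
    for e in graph.edges:
        if e.is_intra:
            continue
        if (
            e.raw_weight >= best_to[(e.u, e.genome_v)]
            and e.raw_weight >= best_to[(e.v, e.genome_u)]
        ):
            e.edge_class = "ortholog-candidate"

    # Inparalogs: within-genome edge at least as strong as either member's
    # best inter-genome hit, or both members lack inter-genome hits.
    for e in graph.edges:
        if not e.is_intra:
            continue
        bu = best_inter.get(e.u)
        bv = best_inter.get(e.v)
        if bu is None and bv is None:
            e.edge_class = "inparalog"
        elif (bu is not None and e.raw_weight >= bu) or (
            bv is not None and e.raw_weight >= bv
        ):
            e.edge_class = "inparalog"

    # Co-orthologs: inter-genome edges joining the inparalog closure of
    # ortholog-candidate nodes on both sides.
    ortho_nodes = {
        n for e in graph.edges if e.edge_class == "ortholog-candidate" for n in (e.u, e.v)
    }
    closure = set(ortho_nodes)
    for e in graph.edges:
        if e.edge_class == "inparalog" and (e.u in ortho_nodes or e.v in ortho_nodes):
            closure.update((e.u, e.v))
    for e in graph.edges:
        if e.is_intra or e.edge_class == "ortholog-candidate":
            continue
        if e.u in closure and e.v in closure:
            e.edge_class = "co-ortholog"


def _normalize_weights(graph: HomologyGraph) -> None:
    pair_sums: dict[frozenset, list[float]] = {}
    intra_sums: dict[str, list[float]] = {}
    for e in graph.edges:
        if e.is_intra:
            if e.edge_class == "inparalog":
                intra_sums.setdefault(e.genome_u, []).append(e.raw_weight)
        elif e.edge_class == "ortholog-candidate":
            pair_sums.setdefault(frozenset((e.genome_u, e.genome_v)), []).append(
                e.raw_weight
            )
    pair_mean = {k: sum(v) / len(v) for k, v in pair_sums.items()}
    intra_mean = {k: sum(v) / len(v) for k, v in intra_sums.items()}
    for e in graph.edges:
        if e.is_intra:
            factor = intra_mean.get(e.genome_u, 1.0)
        else:
            factor = pair_mean.get(frozenset((e.genome_u, e.genome_v)), 1.0)
        e.norm_weight = e.raw_weight / factor


@dataclass
class GeneFamily:
    """An ortholog family: loci grouped across (and within) genomes."""

    family_id: str
    members: list[tuple[str, str]]  # (genome_id, locus_id)

    @property
    def genome_span(self) -> set[str]:
        return {g for g, _ in self.members}

    @property
    def copy_profile(self) -> dict[str, int]:
        prof: dict[str, int] = {}
        for g, _ in self.members:
            prof[g] = prof.get(g, 0) + 1
        return prof

    def __len__(self) -> int:
        return len(self.members)


def mcl(
    graph: HomologyGraph,
    inflation: float = 1.5,
    prune: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> list[GeneFamily]:
    """Markov clustering of the normalized homology graph.

    Each connected component is clustered independently (expansion cannot
    cross components): add self-loops at the node's max incident weight,
    column-normalize, then alternate expansion (matrix square) and inflation
    (elementwise power + column renormalization) with pruning of entries
    below ``prune``, until the matrix moves less than ``tol``.  Clusters are
    read off the attractor structure of the limit matrix; overlaps resolve
    to the cluster holding more attractor mass, then lexicographic node ID.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")

    nodes = graph.nodes
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    from scipy import sparse as sp

    rows, cols, vals = [], [], []
    for e in graph.edges:
        i, j = index[e.u], index[e.v]
        rows += [i, j]
        cols += [j, i]
        vals += [e.norm_weight, e.norm_weight]
    adj = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    n_comp, labels = connected_components(adj, directed=False)
    clusters: list[list[str]] = []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        sub_nodes = [nodes[i] for i in idx]
        if len(idx) == 1:
            clusters.append(sub_nodes)
            continue
        m = adj[np.ix_(idx, idx)].toarray().astype(float)
        loops = m.max(axis=0)
        loops[loops <= 0] = 1.0
        np.fill_diagonal(m, loops)
        clusters.extend(_mcl_dense(m, sub_nodes, inflation, prune, tol, max_iter))

    clusters = [sorted(c) for c in clusters]
    clusters.sort(key=lambda c: c[0])
    families = []
    for k, members in enumerate(clusters, start=1):
        fam_members = [tuple(rid.split("|", 1)) for rid in members]
        families.append(GeneFamily(f"FAM{k:05d}", fam_members))
    return families


def _mcl_dense(
    m: np.ndarray,
    sub_nodes: list[str],
    inflation: float,
    prune: float,
    tol: float,
    max_iter: int,
) -> list[list[str]]:
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = m**inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.max(np.abs(m - prev)) < tol:
            break

    k = len(sub_nodes)
    attractors = [i for i in range(k) if m[i, i] > prune]
    if not attractors:  # degenerate; treat strongest row as attractor
        attractors = [int(np.argmax(m.sum(axis=1)))]

    # Union attractors that support each other into attractor systems.
    parent = list(range(len(attractors)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pos = {a: ai for ai, a in enumerate(attractors)}
    for ai, a in enumerate(attractors):
        for b in attractors:
            if m[a, b] > 0 or m[b, a] > 0:
                ra, rb = find(ai), find(pos[b])
                if ra != rb:
                    parent[rb] = ra

    systems: dict[int, list[int]] = {}
    for ai, a in enumerate(attractors):
        systems.setdefault(find(ai), []).append(a)

    sys_list = sorted(systems.values(), key=lambda s: sub_nodes[min(s)])
    assignment: dict[int, int] = {}
    for j in range(k):
        masses = [sum(m[a, j] for a in s) for s in sys_list]
        best = max(masses)
        if best <= 0:
            # no attractor claims this node; make it a singleton cluster
            assignment[j] = -1 - j
            continue
        # ties resolve to the system containing the smallest node ID
        assignment[j] = int(np.flatnonzero(np.isclose(masses, best))[0])

    out: dict[int, list[str]] = {}
    for j, c in assignment.items():
        out.setdefault(c, []).append(sub_nodes[j])
    return list(out.values())


@dataclass
class PangenomeClassification:
    """Presence/absence view of the families plus core/accessory/unique calls."""

    presence: pd.DataFrame  # genomes x families, bool
    counts: pd.DataFrame  # genomes x families, int copy counts
    family_class: pd.Series  # family -> core | accessory | unique
    single_copy_core: list[str] = field(default_factory=list)
    unique_gene_counts: pd.Series | None = None

    @property
    def core_count(self) -> int:
        return int((self.family_class == "core").sum())

    @property
    def pan_count(self) -> int:
        return int(len(self.family_class))


def classify(families: list[GeneFamily], genome_list: list[str]) -> PangenomeClassification:
    """Core/accessory/unique classification and the single-copy core set.

    Core families span every genome; unique genes are loci of families
    confined to a single genome (counted as genes, not families); the pan
    genome is every family including singletons; single-copy core families
    have exactly one member in each genome.
    """
    gset = set(genome_list)
    for fam in families:
        extra = fam.genome_span - gset
        if extra:
            raise ValueError(f"family {fam.family_id} names unknown genomes {sorted(extra)}")

    fam_ids = [f.family_id for f in families]
    counts = pd.DataFrame(0, index=list(genome_list), columns=fam_ids, dtype=int)
    for fam in families:
        for g, _ in fam.members:
            counts.loc[g, fam.family_id] += 1
    presence = counts > 0

    g = len(genome_list)
    classes = {}
    single_copy = []
    unique_counts = pd.Series(0, index=list(genome_list))
    for fam in families:
        span = len(fam.genome_span)
        if span == g:
            classes[fam.family_id] = "core"
            if all(c == 1 for c in fam.copy_profile.values()):
                single_copy.append(fam.family_id)
        elif span == 1:
            classes[fam.family_id] = "unique"
            unique_counts[next(iter(fam.genome_span))] += len(fam)
        else:
            classes[fam.family_id] = "accessory"

    return PangenomeClassification(
        presence, counts, pd.Series(classes), single_copy, unique_counts
    )


def write_families_tsv(families: list[GeneFamily], path) -> None:
    rows = [
        {"family_id": f.family_id, "genome": g, "locus": l}
        for f in families
        for g, l in f.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_families_tsv(path) -> list[GeneFamily]:
    df = pd.read_csv(path, sep="\t")
    fams = []
    for fid, grp in df.groupby("family_id", sort=True):
        fams.append(GeneFamily(str(fid), list(zip(grp["genome"], grp["locus"]))))
    return fams
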