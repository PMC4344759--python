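"""Concatenated single-copy phylogenomics: progressive protein alignment,
p-distances with pairwise deletion, neighbor-joining and column bootstrap.

The aligner is a deterministic progressive MSA: a guide tree is built by
neighbor-joining on pairwise global-alignment p-distances, then profiles
are merged bottom-up with BLOSUM62 sum-of-pairs column scores and affine
gaps (open 11, extend 1).  Distances between aligned rows are p-distances
under pairwise deletion (gap and X columns dropped per pair).  Trees come
from the Saitou-Nei neighbor-joining algorithm with the standard
Q-criterion, lexicographic tie-breaking and negative branch estimates
clamped to zero.  Bootstrap supports are the percentage of column-resampled
replicates containing each internal bipartition of the point-estimate tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from skbio import DistanceMatrix, TreeNode

from .homology import GAP_EXTEND, GAP_OPEN, _MATRIX
from .io_core import SeqRecord

log = logging.getLogger("comapan")

_ALPHA = "ACDEFGHIKLMNPQRSTVWYX-"  # 20 AA + unknown + gap
_AIDX = {c: i for i, c in enumerate(_ALPHA)}
_GAP = _AIDX["-"]


def _profile_score_matrix() -> np.ndarray:
    """22x22 column-score matrix: BLOSUM62 (X neutral) with gap rows zero."""
    from Bio.Align import substitution_matrices

    blos = substitution_matrices.load("BLOSUM62")
    order = blos.alphabet
    s = np.zeros((22, 22))
    for i, a in enumerate(_ALPHA[:21]):
        for j, b in enumerate(_ALPHA[:21]):
            if a == "X" or b == "X":
                s[i, j] = 0.0
            else:
                s[i, j] = _MATRIX[order.index(a), order.index(b)]
    return s


_PSM = _profile_score_matrix()


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows keyed by taxon/record ID (order preserved)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def matrix(self) -> np.ndarray:
        """(n, L) uint8 view of the rows."""
        return np.frombuffer("".join(self.rows).encode(), dtype=np.uint8).reshape(
            len(self.rows), self.length
        )


@njit(cache=True)
def _affine_profile_dp(S, gap_open, gap_ext):  # pragma: no cover - jitted
    n1, n2 = S.shape
    NEG = -1e30
    M = np.full((n1 + 1, n2 + 1), NEG)
    Ix = np.full((n1 + 1, n2 + 1), NEG)  # gap in profile 2 (consume profile 1)
    Iy = np.full((n1 + 1, n2 + 1), NEG)  # gap in profile 1
    ptrM = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    ptrX = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    ptrY = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        Ix[i, 0] = -(gap_open + i * gap_ext)
        ptrX[i, 0] = 1
    for j in range(1, n2 + 1):
        Iy[0, j] = -(gap_open + j * gap_ext)
        ptrY[0, j] = 2
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            best = M[i - 1, j - 1]
            p = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 2
            M[i, j] = S[i - 1, j - 1] + best
            ptrM[i, j] = p

            a = M[i - 1, j] - gap_open - gap_ext
            b = Ix[i - 1, j] - gap_ext
            if a >= b:
                Ix[i, j] = a
                ptrX[i, j] = 0
            else:
                Ix[i, j] = b
                ptrX[i, j] = 1

            a = M[i, j - 1] - gap_open - gap_ext
            b = Iy[i, j - 1] - gap_ext
            if a >= b:
                Iy[i, j] = a
                ptrY[i, j] = 0
            else:
                Iy[i, j] = b
                ptrY[i, j] = 2

    # traceback; state 0=M, 1=Ix, 2=Iy
    state = 0
    best = M[n1, n2]
    if Ix[n1, n2] > best:
        best = Ix[n1, n2]
        state = 1
    if Iy[n1, n2] > best:
        best = Iy[n1, n2]
        state = 2
    ops = np.empty(n1 + n2, dtype=np.int8)
    k = 0
    i, j = n1, n2
    while i > 0 or j > 0:
        if state == 0:
            prev = ptrM[i, j]
            ops[k] = 0
            i -= 1
            j -= 1
            state = prev
        elif state == 1:
            prev = ptrX[i, j]
            ops[k] = 1
            i -= 1
            state = prev
        else:
            prev = ptrY[i, j]
            ops[k] = 2
            j -= 1
            state = prev
        k += 1
    return ops[:k][::-1].copy(), best


def _counts(rows: list[str]) -> np.ndarray:
    mat = np.zeros((len(rows[0]), 22))
    for r in rows:
        for pos, ch in enumerate(r):
            mat[pos, _AIDX[ch]] += 1
    return mat


def _merge(p1: MultipleAlignment, p2: MultipleAlignment) -> MultipleAlignment:
    c1 = _counts(p1.rows) / len(p1.rows)
    c2 = _counts(p2.rows) / len(p2.rows)
    s = c1 @ _PSM @ c2.T
    ops, _ = _affine_profile_dp(s, float(GAP_OPEN), float(GAP_EXTEND))
    rows1 = ["" for _ in p1.rows]
    rows2 = ["" for _ in p2.rows]
    i = j = 0
    out1: list[list[str]] = [[] for _ in p1.rows]
    out2: list[list[str]] = [[] for _ in p2.rows]
    for op in ops:
        if op == 0:
            for k, r in enumerate(p1.rows):
                out1[k].append(r[i])
            for k, r in enumerate(p2.rows):
                out2[k].append(r[j])
            i += 1
            j += 1
        elif op == 1:  # consume profile 1, gap in profile 2
            for k, r in enumerate(p1.rows):
                out1[k].append(r[i])
            for k in range(len(p2.rows)):
                out2[k].append("-")
            i += 1
        else:
            for k in range(len(p1.rows)):
                out1[k].append("-")
            for k, r in enumerate(p2.rows):
                out2[k].append(r[j])
            j += 1
    rows1 = ["".join(x) for x in out1]
    rows2 = ["".join(x) for x in out2]
    return MultipleAlignment(p1.ids + p2.ids, rows1 + rows2)


def _pairwise_pdist(a: str, b: str) -> float:
    """p-distance of the global alignment of two unaligned sequences."""
    aln = _merge(
        MultipleAlignment(["a"], [a]), MultipleAlignment(["b"], [b])
    )
    x, y = aln.rows
    comp = sum(1 for u, v in zip(x, y) if u != "-" and v != "-")
    diff = sum(1 for u, v in zip(x, y) if u != "-" and v != "-" and u != v)
    return diff / comp if comp else 1.0


def align_family(members: list[SeqRecord]) -> MultipleAlignment:
    """Progressive alignment of one gene family, guide-tree ordered.

    Deterministic: the guide tree comes from NJ on pairwise global-alignment
    p-distances with lexicographic tie-breaks, and profile merges follow the
    guide tree with children visited in order of their smallest member ID.
    Row order of the result follows the input order.
    """
    if not members:
        raise ValueError("empty family")
    if len(members) == 1:
        return MultipleAlignment([members[0].id], [members[0].sequence])
    by_id = {m.id: m for m in members}
    ids = sorted(by_id)
    if len(ids) == 2:
        merged = _merge(
            MultipleAlignment([ids[0]], [by_id[ids[0]].sequence]),
            MultipleAlignment([ids[1]], [by_id[ids[1]].sequence]),
        )
    else:
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _pairwise_pdist(
                    by_id[ids[i]].sequence, by_id[ids[j]].sequence
                )
        guide = nj(DistanceMatrix(d, ids=ids))
        merged = _merge_by_tree(guide, by_id)
    # restore input row order
    order = [m.id for m in members]
    rows = [merged.row(rid) for rid in order]
    return MultipleAlignment(order, rows)


def _merge_by_tree(tree: TreeNode, by_id: dict[str, SeqRecord]) -> MultipleAlignment:
    def build(node: TreeNode) -> MultipleAlignment:
        if node.is_tip():
            return MultipleAlignment([node.name], [by_id[node.name].sequence])
        subs = sorted(
            (build(c) for c in node.children), key=lambda a: min(a.ids)
        )
        acc = subs[0]
        for nxt in subs[1:]:
            acc = _merge(acc, nxt)
        return acc

    return build(tree)


def concatenate(alignments: dict[str, MultipleAlignment]) -> MultipleAlignment:
    """Row-wise concatenation over families sharing an identical taxon set.

    ``alignments`` maps family_id -> alignment whose row IDs are taxa
    (genome IDs); concatenation follows sorted family_id order.
    """
    fam_ids = sorted(alignments)
    if not fam_ids:
        raise ValueError("nothing to concatenate")
    taxa = sorted(alignments[fam_ids[0]].ids)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    for fid in fam_ids:
        aln = alignments[fid]
        if sorted(aln.ids) != taxa:
            raise ValueError(f"family {fid} does not cover the common taxon set")
        for t in taxa:
            parts[t].append(aln.row(t))
    return MultipleAlignment(taxa, ["".join(parts[t]) for t in taxa])


def _pair_masks(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Per-pair boolean (comparable, differing) site masks; X and gap are
    missing data (pairwise deletion)."""
    gap = ord("-")
    unk = ord("X")
    n = mat.shape[0]
    ok = (mat != gap) & (mat != unk)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    comp = np.empty((len(pairs), mat.shape[1]), dtype=bool)
    diff = np.empty_like(comp)
    for k, (i, j) in enumerate(pairs):
        c = ok[i] & ok[j]
        comp[k] = c
        diff[k] = c & (mat[i] != mat[j])
    return comp, diff, pairs


def p_distance(alignment: MultipleAlignment) -> DistanceMatrix:
    """Pairwise-deletion p-distances between all rows."""
    if len(alignment.ids) < 2:
        raise ValueError("need at least 2 rows")
    mat = alignment.matrix()
    comp, diff, pairs = _pair_masks(mat)
    n = len(alignment.ids)
    d = np.zeros((n, n))
    ncomp = comp.sum(axis=1)
    ndiff = diff.sum(axis=1)
    for k, (i, j) in enumerate(pairs):
        if ncomp[k] == 0:
            raise ValueError(
                f"no comparable sites between {alignment.ids[i]} and {alignment.ids[j]}"
            )
        d[i, j] = d[j, i] = ndiff[k] / ncomp[k]
    return DistanceMatrix(d, ids=alignment.ids)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the Q-criterion.

    Ties on Q resolve by the lexicographically smallest (label, label) pair,
    where a cluster's label is its smallest leaf name.  Negative branch
    estimates are clamped to zero with the deficit logged.  The result is
    unrooted (trifurcating root) for >= 3 taxa; two taxa yield a single
    edge of the given length split across a degree-2 root.
    """
    ids = list(dm.ids)
    d = np.array(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        a = TreeNode(name=ids[0], length=d[0, 1] / 2)
        b = TreeNode(name=ids[1], length=d[0, 1] / 2)
        return TreeNode(children=[a, b])

    nodes: list[TreeNode] = [TreeNode(name=t) for t in ids]
    labels = list(ids)
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_idx = n

    def dget(i, j):
        return dist[(i, j)] if i <= j else dist[(j, i)]

    while len(active) > 3:
        r = len(active)
        rsum = {i: sum(dget(i, k) for k in active if k != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (r - 2) * dget(i, j) - rsum[i] - rsum[j]
                pair_key = tuple(sorted((labels[i], labels[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = dget(i, j)
        vi = dij / 2 + (rsum[i] - rsum[j]) / (2 * (r - 2))
        vj = dij - vi
        vi, vj = _clamp(vi), _clamp(vj)
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = vi, vj
        parent = TreeNode(children=[ni, nj_])
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        for k in active:
            if k in (i, j):
                continue
            dist[tuple(sorted((k, next_idx)))] = 0.5 * (
                dget(i, k) + dget(j, k) - dij
            )
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1

    a, b, c = active
    va = _clamp((dget(a, b) + dget(a, c) - dget(b, c)) / 2)
    vb = _clamp((dget(a, b) + dget(b, c) - dget(a, c)) / 2)
    vc = _clamp((dget(a, c) + dget(b, c) - dget(a, b)) / 2)
    for idx, v in ((a, va), (b, vb), (c, vc)):
        nodes[idx].length = v
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def _clamp(v: float) -> float:
    if v < 0:
        log.debug("negative NJ branch length %.6g clamped to 0", v)
        return 0.0
    return v


# ---------------------------------------------------------------------------
# Bootstrap and bipartitions
# ---------------------------------------------------------------------------

def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the side not containing the
    lexicographically smallest taxon."""
    tips = sorted(t.name for t in tree.tips())
    ref = tips[0]
    all_tips = set(tips)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            out.add(frozenset(side))
    return out


def bootstrap(
    alignment: MultipleAlignment, reps: int = 1000, seed: int = 0
) -> TreeNode:
    """NJ point-estimate tree with integer bootstrap supports.

    Columns are resampled with replacement ``reps`` times; each replicate is
    re-run through p-distance + NJ, and each internal edge of the point tree
    gets the percentage of replicates containing its bipartition, rounded to
    the nearest integer and stored as the internal node name.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    tree = nj(p_distance(alignment))
    n = len(alignment.ids)
    if n < 4:
        return tree

    mat = alignment.matrix()
    comp, diff, pairs = _pair_masks(mat)
    compf = comp.astype(np.float64)
    difff = diff.astype(np.float64)
    L = alignment.length
    rng = np.random.default_rng(seed)

    point_bips = bipartitions(tree)
    hits = {bp: 0 for bp in point_bips}
    for _ in range(reps):
        w = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(np.float64)
        ncomp = compf @ w
        if np.any(ncomp == 0):
            raise ValueError("bootstrap replicate with no comparable sites for a pair")
        ndiff = difff @ w
        d = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            d[i, j] = d[j, i] = ndiff[k] / ncomp[k]
        rep_bips = bipartitions(nj(DistanceMatrix(d, ids=alignment.ids)))
        for bp in point_bips:
            if bp in rep_bips:
                hits[bp] += 1

    all_tips = set(alignment.ids)
    ref = min(all_tips)
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= n - 2:
            node.name = str(round(100.0 * hits[frozenset(side)] / reps))
    return tree


def collapse_low_support(tree: TreeNode, threshold: float = 60.0) -> TreeNode:
    """Collapse internal edges whose support is below ``threshold`` into
    polytomies (branch length folds into the children)."""
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.non_tips(include_self=False)):
            if node.name is None:
                continue
            try:
                support = float(node.name)
            except ValueError:
                continue
            if support < threshold:
                parent = node.parent
                for child in list(node.children):
                    if child.length is not None and node.length is not None:
                        child.length += node.length
                    parent.append(child)
                parent.remove(node)
                changed = True
                break
    return tree


def subset_tree(
    family_ids: list[str],
    families,
    proteomes: dict[str, list[SeqRecord]],
    genomes: list[str] | None = None,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    collapse_below: float | None = None,
) -> TreeNode:
    """Align selected single-copy families, concatenate, and build the
    bootstrapped NJ tree (optionally collapsing weak edges).

    ``families`` is the GeneFamily list from orthology; every selected
    family must be single-copy across the included genomes.
    """
    fam_by_id = {f.family_id: f for f in families}
    if genomes is None:
        genomes = sorted({g for fid in family_ids for g, _ in fam_by_id[fid].members})
    rec_index = {
        (r.genome_id, r.locus_id): r for recs in proteomes.values() for r in recs
    }
    alignments: dict[str, MultipleAlignment] = {}
    for fid in family_ids:
        fam = fam_by_id[fid]
        profile = fam.copy_profile
        for g in genomes:
            if profile.get(g, 0) != 1:
                raise ValueError(f"family {fid} is not single-copy in genome {g}")
        members = [rec_index[(g, l)] for g, l in fam.members if g in set(genomes)]
        aln = align_family(members)
        # re-key rows by genome for concatenation
        alignments[fid] = MultipleAlignment(
            [rid.split("|", 1)[0] for rid in aln.ids], aln.rows
        )
    supermatrix = concatenate(alignments)
    tree = bootstrap(supermatrix, reps=bootstrap_reps, seed=seed)
    if collapse_below is not None:
        tree = collapse_low_support(tree, collapse_below)
    return tree
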