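"""All-vs-all protein homology search.

Pairwise comparison is optimal Smith-Waterman local alignment under
BLOSUM62 with affine gaps (a gap of length k costs 11 + k), delegated to
Bio.Align.PairwiseAligner.  Significance follows Karlin-Altschul statistics
with the standard gapped BLOSUM62 constants (lambda = 0.267, K = 0.041),
with the pooled database residue count as the search-space size.  Retained
pairs feed the orthology graph downstream.

Unknown residues (X) are mismatch-neutral: every X pairing scores 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import sparse

from .io_core import SeqRecord, Thresholds

KA_LAMBDA = 0.267
KA_K = 0.041

GAP_OPEN = 11
GAP_EXTEND = 1


def _blosum62_x_neutral():
    m = substitution_matrices.load("BLOSUM62")
    arr = m.copy()
    xi = m.alphabet.index("X")
    arr[xi, :] = 0.0
    arr[:, xi] = 0.0
    return arr


_MATRIX = _blosum62_x_neutral()


def _make_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = _MATRIX
    # first gap position costs open+extend, each further position extend
    al.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    al.extend_gap_score = -GAP_EXTEND
    return al


@dataclass
class AlignmentHit:
    """One filtered local-alignment hit between two proteins."""

    query_id: str
    subject_id: str
    score: float
    identity_pct: float
    match_pct: float
    evalue: float


def evalue_from_score(score: float, m: int, n: int) -> float:
    """Karlin-Altschul expected number of chance hits at this score."""
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def local_align(
    a: SeqRecord,
    b: SeqRecord,
    db_length: int | None = None,
    match_denominator: str = "shorter",
) -> AlignmentHit | None:
    """Optimal local alignment of two proteins; ``None`` if no positive score.

    identity_pct is computed over all aligned columns (internal gaps
    included); match_pct over aligned columns relative to the shorter
    sequence (``match_denominator="query"`` switches to the query length,
    the convention used for fragment-guarding marker searches).
    """
    if a.alphabet != "protein" or b.alphabet != "protein":
        raise ValueError("local_align expects protein records")
    if not a.sequence or not b.sequence:
        raise ValueError("empty sequence")
    aligner = _make_aligner()
    score = aligner.score(a.sequence, b.sequence)
    if score <= 0:
        return None
    aln = aligner.align(a.sequence, b.sequence)[0]
    qrow, srow = str(aln[0]), str(aln[1])
    columns = len(qrow)
    ident = sum(1 for x, y in zip(qrow, srow) if x == y and x != "-")
    identity_pct = 100.0 * ident / columns
    denom = len(a) if match_denominator == "query" else min(len(a), len(b))
    match_pct = min(100.0, 100.0 * columns / denom)
    n = db_length if db_length is not None else len(b)
    return AlignmentHit(
        a.id, b.id, float(score), identity_pct, match_pct,
        evalue_from_score(float(score), len(a), n),
    )


@dataclass
class HomologyPair:
    """A retained, symmetrized homology pair (best direction kept)."""

    query_id: str
    subject_id: str
    query_genome: str
    subject_genome: str
    score: float
    identity_pct: float
    match_pct: float
    evalue: float


def _kmer_candidates(
    seqs: Sequence[str], k: int, min_shared: int, block: int = 2000
) -> set[tuple[int, int]]:
    """Unordered index pairs sharing at least ``min_shared`` distinct k-mers,
    computed blockwise through a sparse k-mer incidence product."""
    vocab: dict[str, int] = {}
    indptr = [0]
    indices: list[int] = []
    for s in seqs:
        kmers = {s[i : i + k] for i in range(len(s) - k + 1)}
        for km in kmers:
            indices.append(vocab.setdefault(km, len(vocab)))
        indptr.append(len(indices))
    x = sparse.csr_matrix(
        (np.ones(len(indices), dtype=np.int32), np.array(indices), np.array(indptr)),
        shape=(len(seqs), len(vocab)),
    )
    out: set[tuple[int, int]] = set()
    for start in range(0, len(seqs), block):
        s = x[start : start + block] @ x.T
        s = s.tocoo()
        mask = s.data >= min_shared
        for i, j in zip(s.row[mask] + start, s.col[mask]):
            if i < j:
                out.add((int(i), int(j)))
    return out


def all_vs_all(
    proteomes: dict[str, list[SeqRecord]],
    thresholds: Thresholds | None = None,
    prefilter: bool = True,
    kmer_size: int = 4,
    min_shared_kmers: int = 1,
) -> list[HomologyPair]:
    """Pool every protein, compare all pairs (within- and cross-genome,
    self-pairs excluded) and retain pairs with
    E <= evalue_max AND match_pct >= match_min AND identity_pct > identity_min.

    Per unordered pair only the better of the two search directions is kept
    (the direction with the shorter query minimizes the E-value; score,
    identity and match are direction-symmetric).  Output is sorted by
    (query_id, subject_id).

    The k-mer prefilter is purely a speedup; candidate pairs must share at
    least ``min_shared_kmers`` distinct ``kmer_size``-mers.
    """
    if thresholds is None:
        thresholds = Thresholds()
    if len(proteomes) < 2:
        raise ValueError("all_vs_all needs at least two proteomes")
    for gid, records in proteomes.items():
        if len(records) < 1:
            raise ValueError(f"proteome {gid} has no proteins")

    pool: list[SeqRecord] = [r for gid in proteomes for r in proteomes[gid]]
    db_length = sum(len(r) for r in pool)
    n = len(pool)

    if prefilter:
        cand: Iterable[tuple[int, int]] = sorted(
            _kmer_candidates([r.sequence for r in pool], kmer_size, min_shared_kmers)
        )
    else:
        cand = ((i, j) for i in range(n) for j in range(i + 1, n))

    aligner = _make_aligner()
    # E-value threshold in score units: the best direction uses the shorter
    # sequence as query, so a pair can only pass if its score clears this.
    retained: list[HomologyPair] = []
    for i, j in cand:
        a, b = pool[i], pool[j]
        score = aligner.score(a.sequence, b.sequence)
        if score <= 0:
            continue
        m = min(len(a), len(b))
        ev = evalue_from_score(float(score), m, db_length)
        if ev > thresholds.evalue_max:
            continue
        aln = aligner.align(a.sequence, b.sequence)[0]
        qrow, srow = str(aln[0]), str(aln[1])
        columns = len(qrow)
        ident = sum(1 for x, y in zip(qrow, srow) if x == y and x != "-")
        identity_pct = 100.0 * ident / columns
        match_pct = min(100.0, 100.0 * columns / m)
        if match_pct < thresholds.match_min or identity_pct <= thresholds.identity_min:
            continue
        q, s = (a, b) if len(a) <= len(b) else (b, a)
        retained.append(
            HomologyPair(
                q.id, s.id, q.genome_id, s.genome_id,
                float(score), identity_pct, match_pct, ev,
            )
        )
    retained.sort(key=lambda p: (p.query_id, p.subject_id))
    return retained


def write_pairs_tsv(pairs: list[HomologyPair], path) -> None:
    import pandas as pd

    pd.DataFrame([vars(p) for p in pairs]).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[HomologyPair]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [HomologyPair(**row) for row in df.to_dict("records")]
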