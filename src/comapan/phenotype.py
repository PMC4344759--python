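"""Marker/cluster presence search and genotype-phenotype concordance.

A marker query is "present" in a proteome when some protein clears all
three thresholds (default E <= 1e-5, identity >= 50 %, match >= 70 %).
Match here is computed on the QUERY length — the guard is against
fragmentary hits to a known query — which deliberately differs from the
shorter-sequence convention used in the orthology all-vs-all stage.

Genotypes are called from a marker map (trait -> required gene markers,
'+' iff all present) and compared cell-by-cell against the phenotype
matrix; the concordance report lists the discordant (trait, strain) cells
and the percentage of agreeing cells to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .homology import local_align
from .io_core import SeqRecord, Thresholds

MARKER_THRESHOLDS = Thresholds(evalue_max=1e-5, identity_min=50.0, match_min=70.0)


@dataclass
class MarkerHit:
    query_id: str
    present: bool
    best_subject: str | None = None
    identity_pct: float = 0.0
    match_pct: float = 0.0
    evalue: float = float("inf")


def search_markers(
    queries: list[SeqRecord],
    proteome: list[SeqRecord],
    thresholds: Thresholds = MARKER_THRESHOLDS,
) -> list[MarkerHit]:
    """Search each query against a proteome; presence = any protein passes
    evalue <= max AND identity >= min AND query-relative match >= min."""
    if not queries:
        raise ValueError("empty query set")
    db_length = sum(len(r) for r in proteome)
    hits = []
    for q in queries:
        best: MarkerHit = MarkerHit(q.id, present=False)
        for target in proteome:
            aln = local_align(q, target, db_length=db_length, match_denominator="query")
            if aln is None:
                continue
            passes = (
                aln.evalue <= thresholds.evalue_max
                and aln.identity_pct >= thresholds.identity_min
                and aln.match_pct >= thresholds.match_min
            )
            if passes and (not best.present or aln.evalue < best.evalue):
                best = MarkerHit(
                    q.id, True, target.id, aln.identity_pct, aln.match_pct, aln.evalue
                )
            elif not best.present and aln.evalue < best.evalue:
                best = MarkerHit(
                    q.id, False, target.id, aln.identity_pct, aln.match_pct, aln.evalue
                )
        hits.append(best)
    return hits


@dataclass
class ClusterDefinition:
    """An ordered gene cluster and its completeness rule ("all" or
    ("all-but-k", k): complete-with-exceptions when at most k members are
    missing)."""

    cluster_id: str
    members: list[SeqRecord]
    rule: tuple[str, int] | str = "all"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster needs at least one member")


@dataclass
class ClusterStatus:
    genome_id: str
    status: str  # complete | complete-with-exceptions | partial | absent
    missing: list[str] = field(default_factory=list)


def cluster_presence(
    cluster: ClusterDefinition,
    proteomes: dict[str, list[SeqRecord]],
    thresholds: Thresholds = MARKER_THRESHOLDS,
) -> dict[str, ClusterStatus]:
    """Per-genome completeness of a gene cluster."""
    out: dict[str, ClusterStatus] = {}
    for genome_id, proteome in proteomes.items():
        hits = search_markers(cluster.members, proteome, thresholds)
        missing = [h.query_id for h in hits if not h.present]
        n_missing = len(missing)
        if n_missing == 0:
            status = "complete"
        elif n_missing == len(cluster.members):
            status = "absent"
        elif (
            isinstance(cluster.rule, tuple)
            and cluster.rule[0] == "all-but-k"
            and n_missing <= cluster.rule[1]
        ):
            status = "complete-with-exceptions"
        else:
            status = "partial"
        out[genome_id] = ClusterStatus(genome_id, status, missing)
    return out


def call_genotypes(
    marker_map: dict[str, list[str]], presence: pd.DataFrame
) -> pd.DataFrame:
    """Trait x strain '+'/'-' matrix: '+' iff every required marker of the
    trait is present in that strain.

    ``presence`` is a marker x strain boolean table.
    """
    strains = list(presence.columns)
    rows = {}
    for trait, markers in marker_map.items():
        if not markers:
            raise ValueError(f"trait {trait!r} has an empty marker requirement")
        missing = [m for m in markers if m not in presence.index]
        if missing:
            raise KeyError(f"markers {missing} for trait {trait!r} not in presence table")
        all_present = presence.loc[markers].all(axis=0)
        rows[trait] = ["+" if all_present[s] else "-" for s in strains]
    return pd.DataFrame.from_dict(rows, orient="index", columns=strains)


@dataclass
class ConcordanceReport:
    total_cells: int
    concordant: int
    discordant: list[tuple[str, str]]

    @property
    def percent(self) -> float:
        return round(100.0 * self.concordant / self.total_cells, 1)


def concordance(pheno: pd.DataFrame, geno: pd.DataFrame) -> ConcordanceReport:
    """Cell-by-cell agreement between phenotype and genotype matrices."""
    if pheno.shape != geno.shape or list(pheno.index) != list(geno.index) or list(
        pheno.columns
    ) != list(geno.columns):
        raise ValueError("phenotype and genotype matrices must share shape and indexing")
    mismatch = pheno != geno
    discordant = [
        (trait, strain)
        for trait in pheno.index
        for strain in pheno.columns
        if mismatch.loc[trait, strain]
    ]
    total = int(pheno.size)
    return ConcordanceReport(total, total - len(discordant), discordant)
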