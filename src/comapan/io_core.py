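"""Readers, writers and shared plumbing for the pipeline.

Sequences live in per-genome collections of :class:`SeqRecord`; the full
record ID is ``"genome|locus"`` with ``|`` reserved as the separator so that
provenance survives pooling proteins from many genomes.  Matrices travel as
TSV with a header row and an index column; trees as Newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from skbio import TreeNode

log = logging.getLogger("comapan")

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

_ALPHABETS = {"protein": PROTEIN_ALPHABET, "nucleotide": NUCLEOTIDE_ALPHABET}


@dataclass
class SeqRecord:
    """A genome-scoped sequence with a stable ``genome|locus`` identity."""

    genome_id: str
    locus_id: str
    alphabet: str  # "protein" | "nucleotide"
    sequence: str

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if "|" in self.genome_id or "|" in self.locus_id:
            raise ValueError("'|' is reserved as the genome|locus separator")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.genome_id}|{self.locus_id}")
        bad = set(self.sequence) - _ALPHABETS[self.alphabet]
        if bad:
            raise ValueError(
                f"illegal {self.alphabet} characters {sorted(bad)} in record "
                f"{self.genome_id}|{self.locus_id}"
            )

    @property
    def id(self) -> str:
        return f"{self.genome_id}|{self.locus_id}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Thresholds:
    """Homology-retention cutoffs for one search stage."""

    evalue_max: float = 1e-5
    identity_min: float = 50.0
    match_min: float = 50.0

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        for name in ("identity_min", "match_min"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")


@dataclass
class RunConfig:
    """All tunables of a documented run, defaulting to the published values.

    ``orthology`` thresholds gate the all-vs-all homology pairs that seed
    Markov clustering (E <= 1e-5, match >= 50 %, identity > 50 %);
    ``marker_search`` gates virulence-factor / marker queries
    (E <= 1e-5, identity >= 50 %, match >= 70 % of the query).
    """

    orthology: Thresholds = field(default_factory=Thresholds)
    marker_search: Thresholds = field(
        default_factory=lambda: Thresholds(1e-5, 50.0, 70.0)
    )
    mcl_inflation: float = 1.5
    permutations: int = 1000
    bootstrap_reps: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mcl_inflation <= 1:
            raise ValueError("mcl_inflation must be > 1")
        if self.permutations < 1 or self.bootstrap_reps < 1:
            raise ValueError("permutations and bootstrap_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("orthology", "marker_search"):
            if key in raw:
                raw[key] = Thresholds(**raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        out = {
            "orthology": vars(self.orthology),
            "marker_search": vars(self.marker_search),
            "mcl_inflation": self.mcl_inflation,
            "permutations": self.permutations,
            "bootstrap_reps": self.bootstrap_reps,
            "rng_seed": self.rng_seed,
        }
        Path(path).write_text(yaml.safe_dump(out))


def read_fasta(path: str | Path, alphabet: str, genome_id: str | None = None) -> list[SeqRecord]:
    """Parse a FASTA file into :class:`SeqRecord` objects, order preserved.

    Headers of the form ``genome|locus`` carry their own provenance;
    plain headers become loci of ``genome_id``.
    """
    records: list[SeqRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" in rec.id:
            gid, _, lid = rec.id.partition("|")
        else:
            if genome_id is None:
                raise ValueError(
                    f"record {rec.id!r} has no 'genome|locus' header and no "
                    "genome_id was supplied"
                )
            gid, lid = genome_id, rec.id
        if (gid, lid) in seen:
            raise ValueError(f"duplicate locus {lid!r} in genome {gid!r}")
        seen.add((gid, lid))
        records.append(SeqRecord(gid, lid, alphabet, str(rec.seq)))
    return records


def write_fasta(records: list[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i : i + 80] + "\n")


def write_tsv_matrix(matrix, row_ids, col_ids, path: str | Path) -> None:
    """Write a matrix as TSV (header row of column IDs, index of row IDs)."""
    import numpy as np

    arr = np.asarray(matrix)
    if arr.size == 0:
        arr = arr.reshape(len(row_ids), len(col_ids))
    if arr.shape != (len(row_ids), len(col_ids)):
        raise ValueError(
            f"matrix shape {arr.shape} does not match "
            f"({len(row_ids)}, {len(col_ids)}) IDs"
        )
    pd.DataFrame(arr, index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t"
    )


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree; integer internal-node names act as supports."""
    for leaf in tree.tips():
        if leaf.name is None or leaf.name == "":
            raise ValueError("tree has an unlabeled leaf")
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
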