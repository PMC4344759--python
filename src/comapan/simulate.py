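"""Synthetic pan-genome generator with a ground-truth ledger.

The generator emulates a small clonal-species genome collection: a large
shared core, accessory families whose per-genome presence frequencies are
drawn from a U-shaped Beta distribution (so gene-accumulation curves stay
non-trivial and the fitted Heap's exponent is < 1), and a Poisson number of
strictly private (unique) genes per genome.  Proteins within a family
diverge from a common ancestor by i.i.d. substitutions only — no indels —
so within-family identity stays far above the orthology cutoffs while
cross-family identity sits at random background.  Nucleotide genomes are
reverse-translated with codon choice tuned to a target G+C content.

Every generated locus is recorded in a :class:`PanGenomeLedger`, the ground
truth that downstream recovery tests compare against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_core import SeqRecord

log = logging.getLogger("comapan")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# Approximate background amino-acid frequencies of bacterial proteomes.
AA_FREQS = np.array(
    [0.089, 0.012, 0.054, 0.059, 0.039, 0.079, 0.021, 0.057, 0.051, 0.099,
     0.024, 0.039, 0.046, 0.038, 0.056, 0.060, 0.054, 0.070, 0.013, 0.031]
)
AA_FREQS = AA_FREQS / AA_FREQS.sum()

# Standard codon table, stops removed, keyed by amino acid.
_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
    return _CODONS


@dataclass
class SimParams:
    """Knobs of the synthetic species; defaults emulate a ~14-strain
    collection with ~61.4 % GC, ~310-residue proteins and a few-percent
    within-species protein divergence."""

    n_genomes: int = 14
    core_families: int = 3600
    accessory_families: int = 5600
    unique_mean: float = 70.0
    presence_beta_shape: tuple[float, float] = (0.5, 0.5)
    protein_divergence: float = 0.02
    mean_protein_length: int = 310
    gc_target: float = 0.614
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.core_families < 0 or self.accessory_families < 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.protein_divergence < 0.5:
            raise ValueError("protein_divergence must lie in [0, 0.5)")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must lie in (0, 1)")
        if self.unique_mean < 0:
            raise ValueError("unique_mean must be >= 0")

    @classmethod
    def reduced(cls, rng_seed: int = 0) -> "SimParams":
        """A ~1,000-protein-per-genome configuration used for full-pipeline
        recovery runs (same structure, smaller gene pool)."""
        return cls(
            core_families=650,
            accessory_families=600,
            unique_mean=20.0,
            rng_seed=rng_seed,
        )


@dataclass
class PanGenomeLedger:
    """Ground truth of a simulated pan-genome."""

    genome_ids: list[str]
    family_ids: list[str]
    family_class: dict[str, str]  # family -> core | accessory | unique
    presence: pd.DataFrame  # genomes x families, bool
    member_map: dict[str, list[tuple[str, str]]]  # family -> [(genome, locus)]

    def __post_init__(self) -> None:
        pres = self.presence
        g = len(self.genome_ids)
        for fid in self.family_ids:
            span = int(pres[fid].sum())
            cls = self.family_class[fid]
            if cls == "core" and span != g:
                raise ValueError(f"core family {fid} missing from some genome")
            if cls == "unique" and span != 1:
                raise ValueError(f"unique family {fid} spans {span} genomes")
            if span != len(self.member_map[fid]):
                raise ValueError(f"presence/member_map mismatch for {fid}")

    @property
    def core_count(self) -> int:
        return sum(1 for f in self.family_ids if self.family_class[f] == "core")

    @property
    def pan_count(self) -> int:
        return len(self.family_ids)

    def unique_gene_counts(self) -> pd.Series:
        counts = pd.Series(0, index=self.genome_ids)
        for fid in self.family_ids:
            if self.family_class[fid] == "unique":
                genome = self.member_map[fid][0][0]
                counts[genome] += 1
        return counts

    def locus_to_family(self) -> dict[str, str]:
        """Full record ID (genome|locus) -> family ID."""
        out = {}
        for fid, members in self.member_map.items():
            for genome, locus in members:
                out[f"{genome}|{locus}"] = fid
        return out


def gen_presence(params: SimParams) -> PanGenomeLedger:
    """Draw the genome x family incidence structure.

    Core families are present everywhere; accessory presence is Bernoulli
    with a family-specific frequency drawn from Beta(a, b), redrawn until the
    realized span lies in [2, G-1] so ledger classes stay unambiguous;
    unique-gene counts are Poisson per genome.
    """
    rng = np.random.default_rng(params.rng_seed)
    g = params.n_genomes
    genomes = [f"G{i + 1:02d}" for i in range(g)]
    a, b = params.presence_beta_shape

    fam_ids: list[str] = []
    fam_class: dict[str, str] = {}
    columns: list[np.ndarray] = []

    def add_family(cls: str, pattern: np.ndarray) -> None:
        fid = f"F{len(fam_ids) + 1:06d}"
        fam_ids.append(fid)
        fam_class[fid] = cls
        columns.append(pattern)

    for _ in range(params.core_families):
        add_family("core", np.ones(g, dtype=bool))

    for _ in range(params.accessory_families):
        while True:
            freq = rng.beta(a, b)
            pattern = rng.random(g) < freq
            if 2 <= pattern.sum() <= g - 1 or g <= 2:
                break
        add_family("accessory", pattern)

    unique_counts = rng.poisson(params.unique_mean, size=g)
    for gi, n_uni in enumerate(unique_counts):
        for _ in range(n_uni):
            pattern = np.zeros(g, dtype=bool)
            pattern[gi] = True
            add_family("unique", pattern)

    presence = pd.DataFrame(
        np.column_stack(columns) if columns else np.zeros((g, 0), dtype=bool),
        index=genomes,
        columns=fam_ids,
    )

    # Per-genome locus numbering follows family-ID order.
    member_map: dict[str, list[tuple[str, str]]] = {f: [] for f in fam_ids}
    for genome in genomes:
        counter = 0
        for fid in fam_ids:
            if presence.loc[genome, fid]:
                counter += 1
                member_map[fid].append((genome, f"L{counter:05d}"))

    return PanGenomeLedger(genomes, fam_ids, fam_class, presence, member_map)


def _mutate(seq_idx: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p, drawing the replacement from
    the background excluding the current residue."""
    out = seq_idx.copy()
    hit = np.flatnonzero(rng.random(len(out)) < p)
    for i in hit:
        while True:
            repl = rng.choice(20, p=AA_FREQS)
            if repl != out[i]:
                out[i] = repl
                break
    return out


def _idx_to_seq(idx: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in idx)


def gen_proteomes(
    ledger: PanGenomeLedger,
    params: SimParams,
    tree: TreeNode | None = None,
) -> dict[str, list[SeqRecord]]:
    """Sample one ancestral protein per family and derive the member copies.

    Default mode is star-wise: every member accumulates i.i.d. substitutions
    at rate ``protein_divergence`` independently from the ancestor.  With a
    guide ``tree`` (tip names = genome IDs, branch lengths = substitution
    probabilities per site) the family evolves along the tree instead, which
    plants a recoverable phylogenetic signal.
    """
    rng = np.random.default_rng(params.rng_seed + 1)
    shape = 20.0
    proteomes: dict[str, list[SeqRecord]] = {g: [] for g in ledger.genome_ids}

    for fid in ledger.family_ids:
        members = ledger.member_map[fid]
        length = max(50, int(rng.gamma(shape, params.mean_protein_length / shape)))
        ancestor = rng.choice(20, size=length, p=AA_FREQS)
        if tree is None:
            tip_seqs = {
                genome: _mutate(ancestor, params.protein_divergence, rng)
                for genome, _ in members
            }
        else:
            tip_seqs = _evolve_down(tree, ancestor, rng)
        for genome, locus in members:
            proteomes[genome].append(
                SeqRecord(genome, locus, "protein", _idx_to_seq(tip_seqs[genome]))
            )
    return proteomes


def _evolve_down(
    tree: TreeNode, ancestor: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    tips: dict[str, np.ndarray] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            p = child.length or 0.0
            derived = _mutate(seq, p, rng)
            if child.is_tip():
                tips[child.name] = derived
            else:
                walk(child, derived)

    walk(tree, ancestor)
    return tips


def evolve_alignment(
    tree: TreeNode, length: int, seed: int, root_rate: float = 0.0
) -> dict[str, str]:
    """Simulate a gap-free protein alignment along ``tree`` (tip name ->
    row).  Branch lengths are per-site substitution probabilities."""
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(20, size=length, p=AA_FREQS)
    if root_rate:
        ancestor = _mutate(ancestor, root_rate, rng)
    tips = _evolve_down(tree, ancestor, rng)
    return {name: _idx_to_seq(idx) for name, idx in tips.items()}


def _codon_weights(q: float) -> dict[str, np.ndarray]:
    table = _codon_table()
    out = {}
    for aa, codons in table.items():
        gc = np.array([c.count("G") + c.count("C") for c in codons], dtype=float)
        w = q**gc
        out[aa] = w / w.sum()
    return out


def _expected_coding_gc(aa_counts: np.ndarray, q: float) -> tuple[float, float]:
    """(expected GC bases, total bases) of the coding fraction under q."""
    table = _codon_table()
    weights = _codon_weights(q)
    gc_bases = 0.0
    for ai, aa in enumerate(AMINO_ACIDS):
        codons = table[aa]
        gc = np.array([c.count("G") + c.count("C") for c in codons], dtype=float)
        gc_bases += aa_counts[ai] * float(weights[aa] @ gc)
    return gc_bases, float(aa_counts.sum() * 3)


def gen_genomes(
    proteomes: dict[str, list[SeqRecord]],
    params: SimParams,
    spacer_range: tuple[int, int] = (50, 200),
) -> dict[str, SeqRecord]:
    """Reverse-translate each proteome into one nucleotide pseudo-chromosome.

    Synonymous-codon choice is biased (weight q^GC per codon, q solved by
    bisection) so that coding plus spacer G+C lands on ``gc_target``.
    """
    rng = np.random.default_rng(params.rng_seed + 2)
    genomes: dict[str, SeqRecord] = {}
    gc = params.gc_target
    for genome_id, records in proteomes.items():
        if not records:
            log.warning("genome %s has an empty proteome; emitting spacer only", genome_id)
            n = int(rng.integers(*spacer_range))
            seq = _random_spacer(n, gc, rng)
            genomes[genome_id] = SeqRecord(genome_id, "chromosome", "nucleotide", seq)
            continue

        aa_counts = np.zeros(20)
        for rec in records:
            for ch in rec.sequence:
                aa_counts[AMINO_ACIDS.index(ch)] += 1

        # Spacers are drawn at gc_target exactly, so tune q on coding alone.
        lo, hi = 0.05, 20.0
        for _ in range(60):
            q = (lo + hi) / 2
            gc_bases, total = _expected_coding_gc(aa_counts, q)
            if gc_bases / total < gc:
                lo = q
            else:
                hi = q
        weights = _codon_weights(q)
        table = _codon_table()

        parts: list[str] = []
        for rec in records:
            parts.append(_random_spacer(int(rng.integers(*spacer_range)), gc, rng))
            # vectorized synonymous-codon draw, grouped by amino acid
            seq = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
            codons = np.empty(len(seq), dtype=object)
            for aa in AMINO_ACIDS:
                pos = np.flatnonzero(seq == ord(aa))
                if len(pos) == 0:
                    continue
                opts = np.array(table[aa], dtype=object)
                codons[pos] = opts[rng.choice(len(opts), size=len(pos), p=weights[aa])]
            parts.append("".join(codons))
        parts.append(_random_spacer(int(rng.integers(*spacer_range)), gc, rng))
        genomes[genome_id] = SeqRecord(
            genome_id, "chromosome", "nucleotide", "".join(parts)
        )
    return genomes


def _random_spacer(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def gc_content(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# Phenotype / genotype fixture (packaged observational data, not simulation)
# ---------------------------------------------------------------------------

def _fixture_path():
    return resources.files("comapan") / "data" / "fixture_fig4"


def gen_pheno_fixture() -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]], pd.DataFrame]:
    """Load the packaged 31-trait x 11-strain phenotype/genotype fixture.

    Returns ``(phenotypes, genotypes, marker_map, marker_presence)`` where
    the matrices hold '+'/'-' calls, ``marker_map`` maps each trait to its
    required marker genes, and ``marker_presence`` is the marker x strain
    boolean table from which :func:`comapan.phenotype.call_genotypes`
    reproduces the genotype matrix.
    """
    base = _fixture_path()
    pheno = pd.read_csv(base / "phenotypes.tsv", sep="\t", index_col=0)
    geno = pd.read_csv(base / "genotypes.tsv", sep="\t", index_col=0)
    markers = pd.read_csv(base / "marker_map.tsv", sep="\t", index_col=0)
    marker_map = {t: row["markers"].split(",") for t, row in markers.iterrows()}
    presence = pd.read_csv(base / "marker_presence.tsv", sep="\t", index_col=0)
    return pheno, geno, marker_map, presence.astype(bool)


# ---------------------------------------------------------------------------
# Sampling-site coordinates
# ---------------------------------------------------------------------------

def gen_coords(
    n_sites: int,
    strains_per_site: int,
    seed: int = 0,
    min_separation_km: float = 100.0,
    jitter_deg: float = 0.05,
) -> pd.DataFrame:
    """Clustered strain coordinates: sites at least ``min_separation_km``
    apart, strains jittered around their site center.

    Returns a table with columns strain, site, lat, lon.
    """
    from .ani import haversine

    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_sites:
        lat = float(rng.uniform(-60, 60))
        lon = float(rng.uniform(-180, 180))
        if all(haversine(lat, lon, la, lo) >= min_separation_km for la, lo in centers):
            centers.append((lat, lon))
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place sites with the requested separation")

    rows = []
    k = 0
    for si, (lat, lon) in enumerate(centers):
        for _ in range(strains_per_site):
            k += 1
            rows.append(
                {
                    "strain": f"S{k:02d}",
                    "site": f"site{si + 1}",
                    "lat": lat + float(rng.uniform(-jitter_deg, jitter_deg)),
                    "lon": lon + float(rng.uniform(-jitter_deg, jitter_deg)),
                }
            )
    return pd.DataFrame(rows).set_index("strain")
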