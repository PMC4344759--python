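# Methods

This note documents the models and procedures implemented in `comapan`,
the parameter choices that matter, what the synthetic data does and does
not emulate, and the numerical conventions that pin down reproducibility.

## Homology search

All proteins from all genomes are pooled and compared pairwise (within-
and cross-genome; self-pairs excluded). Each pair is scored by optimal
Smith–Waterman local alignment under BLOSUM62 with affine gaps: a gap of
length *k* costs 11 + *k* (the BLAST reading of "open 11 / extend 1").
Unknown residues (X) are mismatch-neutral — every X pairing scores 0.
Significance uses Karlin–Altschul statistics, E = K·m·n·e^(−λS), with the
standard gapped BLOSUM62 constants λ = 0.267 and K = 0.041, m the query
length and n the pooled database residue count. This is a documented
approximation: it reproduces the *form* of a database search statistic,
not the bit-for-bit output of any particular search tool.

A pair is retained when E ≤ 1e-5 AND match ≥ 50 % AND identity > 50 %,
where identity is counted over all aligned columns (internal gaps
included) and match is the aligned column count relative to the shorter
sequence. The shorter-sequence convention for "match" is a deliberate
choice: the cutoff then guards symmetric domain coverage (the marker
search below deliberately uses the query length instead). Per unordered
pair, the better search direction (shorter query, hence smaller E) is
kept.

An optional k-mer prefilter (default: at least one shared 4-mer) skips
alignment of pairs that cannot be homologous at these thresholds. It is
purely a speedup and a test asserts it does not change the retained set;
large runs use k = 5 with ≥ 3 shared 5-mers, which at within-species
divergence leaves true pairs untouched (they share hundreds of 5-mers)
while discarding almost all random pairs.

## Ortholog families

Retained pairs form an undirected graph whose raw edge weight is
−log10 E (E floored at 1e-300, so weights cap at 300). Edges are
classified in the reciprocal-best-hit tradition: **ortholog candidates**
are mutual best inter-genome hits (ties all count as best); **inparalogs**
are within-genome edges at least as strong as either member's best
inter-genome hit, or joining two proteins with no inter-genome hits at
all; **co-orthologs** are inter-genome edges connecting the inparalog
closure of ortholog-candidate nodes on both sides. Inter-genome weights
are normalized by the mean ortholog-candidate weight of their genome
pair; within-genome weights by the genome's mean inparalog weight; a
missing normalization pool falls back to factor 1. The inparalog
normalization pool is *all* inparalog edges of a genome rather than only
those connected to orthologs — simpler to state and test, and negligibly
different at within-species divergence.

Markov clustering runs per connected component (expansion cannot cross
components, so this is exact, and it keeps the matrices small): add
self-loops at each node's maximum incident weight, column-normalize,
then alternate expansion (matrix square) and inflation (elementwise
power 1.5, column renormalization), pruning entries below 1e-6, until
the matrix moves by less than 1e-8 (cap 200 iterations). Clusters are
read off the attractor structure; a node claimed by several attractor
systems goes to the one holding more of its mass, ties to the system
containing the smallest node ID. Proteins with no retained edges are
singleton families — required so that the pan-genome is "all families
plus single genes". The pruning and convergence constants were chosen so
that small hand-checkable graphs (disjoint triangles, barbells) converge
to their obvious partitions exactly.

Classification: core families span every genome; unique genes are loci
of single-genome families (counted as genes, not families); single-copy
core families have exactly one member per genome and form the
concatenation set for phylogeny.

## Accumulation curves and Heap's law

For a random ordering of the G genomes, new(N) is the number of families
present in the N-th genome and absent from the first N−1. The curve
samples `permutations` orderings (default 1,000, seeded); when the
request covers all G! orderings it enumerates them exactly instead.
Medians use the lower-middle order statistic, so integer counts stay
integers. The fit is ordinary least squares of log(median) on log(N) for
N = 2..G — the linearized form is deterministic and exactly invertible
on noiseless power-law inputs, which gives a clean test surface (a
nonlinear fit adds no information at the precision these curves have).
α = −slope, κ = e^intercept; α ≤ 1 (with a 1e-9 float-noise guard at the
boundary) classifies the pan-genome open. Non-positive medians raise an
error rather than being silently dropped: the power law is undefined at
zero and silent exclusion would bias α.

## Phylogeny

Single-copy families are aligned with a deterministic progressive
aligner: pairwise global-alignment p-distances → NJ guide tree →
profile–profile merges (sum-of-pairs BLOSUM62 column scores, affine
gaps 11/1, existing gaps score 0, fixed tie-break order). Children merge
in order of their smallest member ID, so the alignment is invariant to
input order. This replaces a heuristic MSA tool by design: the
downstream statistics (p-distance, NJ) dominate the result and are
exactly specified, while MSA heuristics are not; on the indel-free
synthetic families the alignment is trivially gap-free anyway.

p-distances use pairwise deletion: a site contributes for a pair only if
both rows have a residue there, with X treated as missing data; zero
comparable sites is an error. Neighbor joining is the Saitou–Nei
algorithm with the Q-criterion, lexicographic tie-breaking on cluster
labels (a cluster is labeled by its smallest leaf), and negative branch
estimates clamped to zero with the deficit logged. On additive matrices
this reconstructs the generating tree exactly, which the tests exploit
as an oracle. Bootstrap resamples alignment columns with replacement
(precomputed per-pair difference/comparable masks make each replicate a
matrix–vector product), rebuilds the NJ tree, and attaches to each
internal edge of the point-estimate tree the percentage of replicates
containing its bipartition, rounded to an integer — supports annotate
the point tree, not a consensus. Edges under a support threshold
(typically 60) can be collapsed into polytomies.

## Average nucleotide identity and geography

ANIb cuts the query genome into consecutive non-overlapping 1,020-nt
fragments, discarding the trailing remnant. Each fragment is aligned to
the subject on both strands under match +1 / mismatch −1 / gap open 5 /
extend 2 (gap of length k costs 5 + 2k) and retained if identity ≥ 30 %
over an aligned region covering ≥ 70 % of the fragment; the direction's
ANI is the mean identity of retained fragments and the reported ANI is
the mean of both directions. The fragment size and 30/70 retention rule
follow the ANIb literature defaults. For tractability the best subject
locus is first found with a fast edit-distance scan (seed) and the
optimal local alignment is computed inside a ±160-nt window around it
(extend); at within-species divergence this recovers the unrestricted
alignment, and the self-identity, strand-invariance and
mutation-monotonicity tests exercise exactly this path.

Geographic distances are great-circle (haversine, Earth radius
6,371 km). Distance decay is OLS of ANI on distance within user-defined
strain-pair groups (e.g. within-region vs cross-continent); groups with
fewer than 3 pairs are skipped with a warning.

## Genotype–phenotype concordance

A marker query is present in a proteome when some protein clears
E ≤ 1e-5, identity ≥ 50 % and match ≥ 70 % **of the query length** — the
query-relative convention guards against fragmentary hits to a known
gene and deliberately differs from the orthology stage. Cluster
completeness is per-genome: complete / partial (missing members named) /
absent, with an "all-but-k" rule for clusters that tolerate known
dropouts. Genotypes are '+' for a trait iff every required marker is
present; concordance is the fraction of trait × strain cells where
genotype equals phenotype, reported to one decimal with the discordant
cells listed.

The packaged fixture encodes a 31-trait × 11-strain matrix typical of
this species: 16 uniformly positive traits (nitrate reduction, urease,
testosterone/4HBA/organic-acid utilization, penicillin-class and Cu/Zn
resistance), 12 uniformly negative traits (sugar utilization and
hydrolysis tests, tetracycline), mercury resistance in 6 of 11 strains,
and two phenotype-positive/genotype-negative cells (arginine
dihydrolase in one strain, kanamycin resistance in another), giving
99.4 % concordance. Two rows beyond the canonically listed ones (citrate
and decanoate utilization, both positive) complete the 31; the marker
gene lists attached to each trait are plausible gene symbols chosen for
the fixture, not a curated annotation. Numeric phenotypes (MICs,
inhibition zones) are expected to be binarized by user-supplied cutoffs
before entry; a weakly positive reaction counts as '+'.

## Synthetic data

The generator emulates a ~14-strain clonal species: a fixed core, an
accessory pool whose per-family presence frequency is drawn from
Beta(0.5, 0.5) (U-shaped, so both rare and near-core accessory families
exist), and Poisson-distributed private genes per genome. Accessory
presence patterns are redrawn until their realized span lies in
[2, G−1]: without this, a sizeable fraction of accessory draws would
realize as present-everywhere (or nowhere) and the ledger's class labels
would disagree with any downstream classifier, making recovery
unmeasurable. Proteins evolve from a per-family ancestor (length
Gamma-distributed around 310 residues, background amino-acid
frequencies) by i.i.d. substitutions at rate ε (default 0.02),
star-wise by default or along a supplied tree when a recoverable
phylogenetic signal is wanted. Genomes are reverse-translations with
synonymous-codon weights q^GC, q solved by bisection so that coding plus
random spacers hit the GC target (default 61.4 %, landing within ±0.5
points).

What the generator does **not** emulate: indels (substitutions only, so
within-family alignments are gap-free), operon/synteny structure,
horizontal transfer, paralog expansions (families are single-copy), or
rearrangements. Consequently, recovery tests validate the clustering,
counting and tree machinery — not robustness to fragmented assemblies or
complex gene-family evolution.

Problem sizes: the full-pipeline recovery runs use 14 genomes with a
scaled gene pool (650 core / 600 accessory / Poisson-20 private, about
1,000 proteins per genome), which keeps the all-vs-all stage to a few
minutes while preserving the structure of the default configuration.

A note on openness: with this i.i.d. presence model the fitted α depends
on the ratio of accessory turnover to private-gene supply and on the
pool size. At the scaled analysis size, α lands below 1 (open) for
almost all seeds; at the full default pool size (5,600 accessory
families) the accumulation curve decays faster than a κN^(−α) with
α ≤ 1 can follow and the fit lands near 1.4. The Beta-Bernoulli model is
a convenient test harness, not a calibrated model of gene flux — real
open pan-genomes stay open because new strains keep importing genes
from an effectively unbounded pool, a process this generator does not
simulate.

## Known limitations

- E-values are analytic Karlin–Altschul approximations; absolute values
  differ from any specific search tool, though the retained-pair set is
  insensitive to this at within-species identity levels.
- The MCL attractor-overlap tie-break (mass, then smallest node ID) is
  one of several defensible conventions; it matters only on symmetric
  toy graphs.
- The ANIb seed-and-extend search can in principle miss a repeat-induced
  secondary locus that an exhaustive scan would prefer; irrelevant on
  the repeat-free synthetic genomes it is tested on.
- The progressive aligner is adequate for high-identity protein families
  (its design target); it is not a general-purpose MSA tool and has no
  iterative refinement.
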