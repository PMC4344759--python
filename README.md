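# comapan

Comparative pan-genomics of bacterial strain collections, modeled on the
analyses typically run for an environmental species such as *Comamonas
testosteroni*: a species whose strains degrade steroids and aromatic
compounds, resist multiple heavy metals and drugs, and barely touch
sugars. Given per-strain proteomes and genomes, the package answers the
questions such a study asks:

- **Which genes are shared?** All-vs-all protein homology
  (Smith–Waterman, BLOSUM62, Karlin–Altschul E-values; pairs kept at
  E ≤ 1e-5, match ≥ 50 %, identity > 50 %) feeds a normalized homology
  graph that Markov clustering (inflation 1.5) partitions into ortholog
  families; families are classified core / accessory / unique and the
  single-copy core is extracted.
- **Is the pan-genome open?** Gene accumulation over random genome
  orderings gives median new-gene counts *n*(*N*), fitted with Heap's law
  *n* = κ·*N*<sup>−α</sup> (log–log least squares); α ≤ 1 calls the
  pan-genome open.
- **How are the strains related?** Single-copy families are aligned
  (deterministic progressive MSA), concatenated into a supermatrix, and a
  neighbor-joining tree is built on p-distances with column-bootstrap
  supports; weakly supported edges can be collapsed into polytomies.
- **Does genome similarity decay with distance?** Fragment-based average
  nucleotide identity (ANIb: 1,020-nt fragments, 30 % identity / 70 %
  coverage retention) is regressed on great-circle distances between
  sampling sites.
- **Do genotypes explain phenotypes?** Marker searches (E ≤ 1e-5,
  identity ≥ 50 %, query match ≥ 70 %) and a trait → required-genes map
  produce a genotype matrix that is scored cell-by-cell against observed
  phenotypes; the packaged 31-trait × 11-strain fixture reproduces the
  characteristic 99.4 % concordance with its two known exceptions.

A synthetic-data module generates genomes with known family structure
(core + Beta-Bernoulli accessory + private genes, star- or tree-evolved
proteins, GC-tuned nucleotide sequences) and a ground-truth ledger, so
every stage of the pipeline is testable end-to-end by recovery.

## Worked example

```python
from comapan.simulate import SimParams, gen_presence, gen_proteomes
from comapan.homology import all_vs_all
from comapan import orthology, pangenome

params = SimParams(n_genomes=6, core_families=60, accessory_families=40,
                   unique_mean=5, rng_seed=42)
ledger = gen_presence(params)
proteomes = gen_proteomes(ledger, params)

pairs = all_vs_all(proteomes)
loci = [(r.id, r.genome_id) for recs in proteomes.values() for r in recs]
graph = orthology.build_graph(pairs, loci=loci)
families = orthology.mcl(graph, inflation=1.5)
cls = orthology.classify(families, ledger.genome_ids)

curve = pangenome.accumulate(cls.presence, permutations=500, seed=42)
fit = pangenome.fit_heaps(curve.medians()[1:])
```

prints (via the obvious `print` statements):

```
retained homology pairs : 1102
gene families (pan)     : 129  (ledger: 129)
core families           : 60  (ledger: 60)
single-copy core        : 60
median new genes by N   : [87, 14, 9, 6, 5, 5]
Heap's fit              : kappa=26.9, alpha=1.005 -> closed
```

The clustering recovers the simulated family structure exactly (129/129
families, 60/60 core). The first median is the first genome's own family
count; the fit uses N ≥ 2. Note that openness is a property of the gene
pool being sampled: tiny simulations like this one often fit α near or
just above 1, while the larger 14-genome runs used in the tests land
clearly below 1 (open).

Every stage is also exposed on the command line (`comapan --help`):
`simulate`, `allvall`, `cluster`, `pangenome`, `tree`, `ani`, `decay`,
`search`, `pheno`.

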