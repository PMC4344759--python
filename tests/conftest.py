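import numpy as np
import pytest
from sklearn.metrics import rand_score

from comapan import orthology, pangenome
from comapan.homology import all_vs_all
from comapan.simulate import SimParams, gen_presence, gen_proteomes


@pytest.fixture(scope="session")
def small_sim():
    """A 5-genome synthetic pan-genome small enough for exhaustive checks."""
    params = SimParams(
        n_genomes=5, core_families=30, accessory_families=20, unique_mean=3, rng_seed=1
    )
    ledger = gen_presence(params)
    proteomes = gen_proteomes(ledger, params)
    return params, ledger, proteomes


def run_pipeline(proteomes, ledger, kmer_size=5, min_shared_kmers=3, seed=0):
    """Proteomes -> families -> classification + ledger comparison metrics."""
    pairs = all_vs_all(proteomes, kmer_size=kmer_size, min_shared_kmers=min_shared_kmers)
    loci = [(r.id, r.genome_id) for recs in proteomes.values() for r in recs]
    graph = orthology.build_graph(pairs, loci=loci)
    families = orthology.mcl(graph, inflation=1.5)
    classification = orthology.classify(families, ledger.genome_ids)

    truth = ledger.locus_to_family()
    inferred = {}
    for fam in families:
        for g, l in fam.members:
            inferred[f"{g}|{l}"] = fam.family_id
    keys = sorted(truth)
    rand = rand_score([truth[k] for k in keys], [inferred[k] for k in keys])

    curve = pangenome.accumulate(classification.presence, permutations=200, seed=seed)
    fit = pangenome.fit_heaps(curve.medians()[1:])
    return {
        "pairs": pairs,
        "families": families,
        "classification": classification,
        "rand_index": rand,
        "heaps_fit": fit,
    }


@pytest.fixture(scope="session")
def reduced_pipeline():
    """Full-scale recovery run: 14 genomes at ~1,000 proteins each.

    Session-scoped because the all-vs-all stage dominates the suite's
    runtime; several tests read different facets of the same run.
    """
    params = SimParams.reduced(rng_seed=11)
    ledger = gen_presence(params)
    proteomes = gen_proteomes(ledger, params)
    result = run_pipeline(proteomes, ledger, seed=11)
    result["ledger"] = ledger
    result["params"] = params
    result["proteomes"] = proteomes
    return result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
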