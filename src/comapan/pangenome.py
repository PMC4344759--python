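"""Gene accumulation curves and Heap's-law openness.

New-gene counts follow the genome-permutation scheme: for a random ordering
of the G genomes, new(N) is the number of families present in the N-th
genome but absent from the first N-1.  Medians of new(N) across orderings
are fitted with the power law n = kappa * N^(-alpha) by ordinary least
squares on log-log coordinates; the pan-genome is called open when
alpha <= 1 and closed otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd


@dataclass
class AccumulationCurve:
    """Per-permutation pan/core/new-gene trajectories and their medians."""

    n_values: np.ndarray  # 1..G
    new_genes: np.ndarray  # (permutations, G)
    pan_sizes: np.ndarray  # (permutations, G)
    core_sizes: np.ndarray  # (permutations, G)

    def medians(self) -> np.ndarray:
        """Lower-middle order-statistic median of new(N) per N (integer in,
        integer out)."""
        s = np.sort(self.new_genes, axis=0)
        return s[(s.shape[0] - 1) // 2]


@dataclass
class HeapsFit:
    kappa: float
    alpha: float
    r_squared: float

    @property
    def openness(self) -> str:
        # open iff alpha <= 1; tiny tolerance guards the exact boundary
        # against float noise from the log-log regression
        return "open" if self.alpha <= 1 + 1e-9 else "closed"


def accumulate(
    presence: pd.DataFrame, permutations: int = 1000, seed: int = 0
) -> AccumulationCurve:
    """Accumulation trajectories over genome orderings.

    When ``permutations >= G!`` every ordering is enumerated exactly once;
    otherwise ``permutations`` orderings are sampled uniformly with the
    given seed.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    mat = presence.to_numpy(dtype=bool)
    g = mat.shape[0]
    if g < 2:
        raise ValueError("need at least 2 genomes")

    total = math.factorial(g)
    if permutations >= total:
        orders = [np.array(p) for p in iter_permutations(range(g))]
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(g) for _ in range(permutations)]

    new = np.empty((len(orders), g), dtype=int)
    pan = np.empty_like(new)
    core = np.empty_like(new)
    for k, order in enumerate(orders):
        seen = np.zeros(mat.shape[1], dtype=bool)
        inter = np.ones(mat.shape[1], dtype=bool)
        for step, gi in enumerate(order):
            row = mat[gi]
            new[k, step] = int((row & ~seen).sum())
            seen |= row
            inter &= row
            pan[k, step] = int(seen.sum())
            core[k, step] = int(inter.sum())
    return AccumulationCurve(np.arange(1, g + 1), new, pan, core)


def fit_heaps(medians, n_values=None) -> HeapsFit:
    """OLS fit of log(median) on log(N); alpha = -slope, kappa = exp(intercept).

    ``medians`` are the new-gene medians for N = 2..G (N = 1 is the first
    genome itself and is excluded).  Any non-positive median is an error:
    the power law is undefined there and silent exclusion would bias alpha.
    """
    med = np.asarray(medians, dtype=float)
    if n_values is None:
        n_values = np.arange(2, len(med) + 2)
    n_values = np.asarray(n_values, dtype=float)
    if len(med) < 2:
        raise ValueError("need at least 2 points to fit")
    if np.any(med <= 0):
        raise ValueError(
            "non-positive median new-gene count; exclude those N explicitly "
            "or add genomes — the power law is undefined at 0"
        )
    x = np.log(n_values)
    y = np.log(med)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return HeapsFit(kappa=float(np.exp(intercept)), alpha=float(-slope), r_squared=r2)


def heaps_medians(kappa: float, alpha: float, n_max: int) -> np.ndarray:
    """Noiseless power-law medians kappa * N^(-alpha) for N = 2..n_max."""
    n = np.arange(2, n_max + 1, dtype=float)
    return kappa * n ** (-alpha)


def summary_ratios(pan: int, core: int, mean_genome_genes: float) -> dict:
    """Headline ratios as conventionally printed: pan/core to 1 decimal,
    core share of the pan as an integer percent, pan over the mean per-genome
    gene count as an integer multiple."""
    return {
        "pan_core_ratio": round(pan / core, 1),
        "core_pan_pct": round(100.0 * core / pan),
        "pan_mean_genome_ratio": round(pan / mean_genome_genes),
    }


def summarize(classification, gene_counts: pd.Series | None = None) -> dict:
    """Full pan/core summary of a :class:`~comapan.orthology.PangenomeClassification`.

    ``gene_counts`` optionally supplies per-genome total gene counts (defaults
    to the classification's own copy-count row sums).
    """
    counts = classification.counts
    if gene_counts is None:
        gene_counts = counts.sum(axis=1)
    pan = classification.pan_count
    core = classification.core_count
    core_fams = classification.family_class[classification.family_class == "core"].index
    per_genome_families = (counts > 0).sum(axis=1)
    core_fraction = (counts[core_fams] > 0).sum(axis=1) / per_genome_families

    uniq = classification.unique_gene_counts
    out = {
        "pan_families": pan,
        "core_families": core,
        "single_copy_core": len(classification.single_copy_core),
        "per_genome_family_counts": per_genome_families.to_dict(),
        "unique_gene_counts": uniq.to_dict(),
        "unique_gene_pct": (100.0 * uniq / gene_counts).round(1).to_dict(),
        "core_fraction_per_genome": core_fraction.round(3).to_dict(),
    }
    out.update(summary_ratios(pan, core, float(gene_counts.mean())))
    return out
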