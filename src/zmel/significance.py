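"""Combined per-gene significance across mutation modalities, and pathway
enrichment.

Each modality i (substitutions, indels, amplifications, homozygous
deletions) occurs at its own background frequency, so recurrence is
assessed per modality and combined multiplicatively.  For gene j hit by
x_ij of the n_i samples in modality i, the combined statistic is

    p_j = prod_i P(X >= x_ij),   X ~ Binomial(n_i, q_i),

where q_i is the per-gene background hit probability for the modality,
estimated from the per-sample event counts m_k and the number of genes N:

    q_i = (1/n_i) * sum_k [1 - (1 - 1/N)^{m_k}],

i.e. the average probability that a given gene is struck at least once
when sample k scatters m_k events uniformly over N genes.  A modality with
x = 0 contributes a factor of 1.

Gene-set (pathway) enrichment over the genes selected at p_j < alpha uses
a one-sided hypergeometric tail, swept over a minimum per-gene mutation
count threshold N_min = 1..10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneSet

__all__ = [
    "MODALITIES",
    "modality_rate",
    "binomial_upper_tail",
    "combined_gene_pvalue",
    "gene_significance_table",
    "select_significant_genes",
    "pathway_enrichment",
]

MODALITIES = ("substitution", "indel", "amplification", "homozygous_deletion")


def modality_rate(m_k: Sequence[int], n_i: int | None = None, N: int = 1) -> float:
    """Background per-gene hit probability q_i for one modality.

    ``m_k`` are per-sample event counts, ``N`` the number of genes in the
    genome.  ``n_i`` defaults to ``len(m_k)``.
    """
    m = np.asarray(m_k, dtype=float)
    if n_i is None:
        n_i = len(m)
    if n_i < 1 or N < 1:
        raise ValueError("n_i and N must be >= 1")
    return float(np.sum(1.0 - (1.0 - 1.0 / N) ** m) / n_i)


def binomial_upper_tail(x: int, n: int, q: float) -> float:
    """P(X >= x) for X ~ Binomial(n, q); x = 0 gives 1."""
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0,1], got {q}")
    if x < 0 or x > n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    if x == 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, q))


def combined_gene_pvalue(
    x_ij: Mapping[str, int], n_i: Mapping[str, int], q_i: Mapping[str, float]
) -> float:
    """Product over modalities of the per-modality binomial upper tails."""
    p = 1.0
    for modality, x in x_ij.items():
        p *= binomial_upper_tail(x, n_i[modality], q_i[modality])
    return p


@dataclass
class GeneSignificance:
    gene_id: str
    tails: dict[str, float]
    p_combined: float


def gene_significance_table(
    hits: Mapping[str, Mapping[str, int]],
    events_per_sample: Mapping[str, Sequence[int]],
    n_genes: int,
    n_samples: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Combined significance for every gene.

    Parameters
    ----------
    hits : {modality: {gene_id: x_ij}}
        Number of samples with the gene mutated, per modality.
    events_per_sample : {modality: [m_k, ...]}
        Per-sample event counts used for the background rate q_i.
    n_genes : int
        N, the number of genes in the genome.
    n_samples : optional {modality: n_i}
        Defaults to ``len(events_per_sample[modality])``.

    Returns a DataFrame indexed by gene with one tail column per modality,
    the combined ``p_combined``, and the total mutation count ``n_events``.
    """
    q = {}
    n = {}
    for modality, m_k in events_per_sample.items():
        n[modality] = (
            n_samples[modality] if n_samples is not None else len(list(m_k))
        )
        q[modality] = modality_rate(m_k, n[modality], n_genes)
    genes = sorted({g for per_gene in hits.values() for g in per_gene})
    rows = []
    for gene in genes:
        tails = {}
        total = 0
        for modality in hits:
            x = int(hits[modality].get(gene, 0))
            total += x
            tails[f"tail_{modality}"] = binomial_upper_tail(x, n[modality], q[modality])
        p = float(np.prod(list(tails.values())))
        rows.append({"gene_id": gene, **tails, "p_combined": p, "n_events": total})
    df = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["p_combined", "n_events"]
    )
    return df.sort_values("p_combined") if len(df) else df


def select_significant_genes(
    significances: pd.DataFrame | Mapping[str, float], alpha: float = 0.05
) -> set[str]:
    """Genes with combined p strictly below ``alpha``."""
    if isinstance(significances, pd.DataFrame):
        pvals = significances["p_combined"]
        return set(pvals.index[pvals < alpha])
    return {g for g, p in significances.items() if p < alpha}


def pathway_enrichment(
    selected_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
    mutation_counts: Mapping[str, int] | None = None,
    thresholds: Sequence[int] = range(1, 11),
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment per set, swept over thresholds.

    At threshold N_min, the tested gene list is the selected genes carrying
    at least N_min mutations (``mutation_counts``; all thresholds see the
    full list when counts are not supplied).  Sets disjoint from the
    universe are skipped with a warning column in the log.

    Returns a DataFrame indexed by set_id with one column per threshold
    holding P(overlap >= observed).
    """
    universe = set(universe)
    selected = set(selected_genes)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    M = len(universe)
    out = {}
    for n_min in thresholds:
        if mutation_counts is None:
            chosen = selected
        else:
            chosen = {g for g in selected if mutation_counts.get(g, 0) >= n_min}
        col = {}
        for gs in gene_sets:
            set_in_universe = gs.gene_ids & universe
            if not set_in_universe:
                continue
            k = len(chosen & set_in_universe)
            # P(X >= k), X ~ Hypergeom(M, |set|, |chosen|)
            col[gs.set_id] = (
                1.0
                if k == 0
                else float(stats.hypergeom.sf(k - 1, M, len(set_in_universe), len(chosen)))
            )
        out[f"N>={n_min}"] = col
    return pd.DataFrame(out)
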