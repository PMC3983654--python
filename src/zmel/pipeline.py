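"""Glue that assembles the combined-significance inputs from a cohort.

The combined per-gene statistic needs, per modality (substitutions,
indels, amplifications, homozygous deletions): how many samples hit each
gene (x_ij), the per-sample event counts (m_k, for the background rate
q_i) and the modality group size n_i.  This module derives all of that
from a mutation catalog, called copy-number segments and gene models.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .annotate import GeneIndex, annotate_catalog
from .cnv import CnaCall, call_cna, recurrence_profile
from .types import (
    CopyNumberSegment,
    GeneInterval,
    MutationRecord,
    SampleMetadata,
)

__all__ = ["modality_inputs", "modality_inputs_from_files"]


def modality_inputs(
    mutations: Sequence[MutationRecord],
    calls: Sequence[CnaCall],
    samples: Sequence[SampleMetadata],
    gene_models: GeneIndex | Sequence[GeneInterval],
) -> tuple[dict, dict, dict, int]:
    """Build (hits, events_per_sample, n_samples, n_genes).

    Mutation records must already carry ``gene_id`` (run
    :func:`zmel.annotate.annotate_catalog` first); records that map to no
    gene count toward the per-sample event totals but hit no gene.
    """
    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    sample_ids = [m.sample_id for m in samples]
    n = len(sample_ids)

    def _hits_and_events(records: Iterable[MutationRecord]) -> tuple[dict, list[int]]:
        per_gene_samples: dict[str, set[str]] = {}
        per_sample_events = dict.fromkeys(sample_ids, 0)
        for r in records:
            if r.sample_id in per_sample_events:
                per_sample_events[r.sample_id] += 1
            if r.gene_id:
                per_gene_samples.setdefault(r.gene_id, set()).add(r.sample_id)
        return (
            {g: len(s) for g, s in per_gene_samples.items()},
            [per_sample_events[s] for s in sample_ids],
        )

    sub_hits, sub_events = _hits_and_events([r for r in mutations if r.is_snv])
    ind_hits, ind_events = _hits_and_events([r for r in mutations if not r.is_snv])

    matrix = recurrence_profile(calls, index)
    cna_hits = {}
    cna_events = {}
    for modality, key in (("amplification", "amplification"),
                          ("homozygous_deletion", "deletion")):
        rec = matrix.recurrence(key)
        cna_hits[modality] = {g: int(c) for g, c in rec.items() if c > 0}
        df = matrix.hits[key]
        counts = dict.fromkeys(sample_ids, 0)
        for c in calls:
            wanted = "amplification" if modality == "amplification" else "homozygous_deletion"
            if c.call == wanted and c.segment.sample_id in counts:
                counts[c.segment.sample_id] += 1
        cna_events[modality] = [counts[s] for s in sample_ids]
        del df

    hits = {
        "substitution": sub_hits,
        "indel": ind_hits,
        "amplification": cna_hits["amplification"],
        "homozygous_deletion": cna_hits["homozygous_deletion"],
    }
    events = {
        "substitution": sub_events,
        "indel": ind_events,
        "amplification": cna_events["amplification"],
        "homozygous_deletion": cna_events["homozygous_deletion"],
    }
    n_samples = dict.fromkeys(hits, n)
    return hits, events, n_samples, len(index.genes)


def modality_inputs_from_files(
    mutations_path: str,
    segments_path: str,
    sheet_path: str,
    genes_path: str,
    genome_path: str,
) -> tuple[dict, dict, dict, int]:
    """File-based wrapper: read, annotate, call CNAs, assemble inputs."""
    from . import io as zio

    mutations = zio.read_mutations(mutations_path)
    segments = zio.read_segments(segments_path)
    samples = zio.read_sample_sheet(sheet_path)
    genes = zio.read_gene_models(genes_path)
    genome = zio.read_fasta(genome_path)
    annotate_catalog(mutations, genes, genome)
    ploidies = {m.sample_id: m.ploidy for m in samples}
    calls = call_cna(segments, ploidies)
    return modality_inputs(mutations, calls, samples, genes)
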