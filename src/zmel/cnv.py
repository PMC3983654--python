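"""Copy-number calling, recurrence profiling and permutation enrichment.

Amplifications and homozygous deletions are called from per-sample integer
copy-number segments with ploidy-gated thresholds: a segment is an
amplification at copy number >= 5 in near-diploid samples (ploidy < 2.7)
or >= 8 in higher-ploidy samples; a homozygous deletion is copy number 0.
Only segments under 10 Mb enter the analysis.

Recurrence enrichment is assessed by a length-preserving permutation test:
within each sample, every called segment is re-placed uniformly at random
across the concatenated target (exome) space, keeping its length and
contiguity; per-gene recurrence is recomputed each round and the empirical
p-value is the add-one estimator (#permutations with recurrence >= observed
+ 1) / (n_perm + 1), Bonferroni-adjusted over the genes tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import GeneIndex
from .types import CopyNumberSegment, GeneInterval

__all__ = [
    "CnaCall",
    "call_cna",
    "GeneHitMatrix",
    "recurrence_profile",
    "PermutationResult",
    "permutation_enrichment",
    "subgroup_association",
]

logger = logging.getLogger(__name__)

MAX_SEGMENT_LENGTH = 10_000_000  # segments at or over 10 Mb are dropped
PLOIDY_CUTOFF = 2.7
AMP_CN_DIPLOID = 5
AMP_CN_POLYPLOID = 8


@dataclass(frozen=True)
class CnaCall:
    segment: CopyNumberSegment
    call: str  # amplification | homozygous_deletion | none


def call_cna(
    segments: Iterable[CopyNumberSegment],
    ploidies: dict[str, float],
) -> list[CnaCall]:
    """Apply the ploidy-gated amplification/deletion thresholds.

    ``ploidies`` maps sample_id -> tumor ploidy; a missing sample is an
    error.  Segments >= 10 Mb are dropped (count logged).
    """
    calls = []
    n_dropped = 0
    for seg in segments:
        if seg.sample_id not in ploidies:
            raise ValueError(f"no ploidy for sample {seg.sample_id!r}")
        if seg.length >= MAX_SEGMENT_LENGTH:
            n_dropped += 1
            continue
        ploidy = ploidies[seg.sample_id]
        threshold = AMP_CN_DIPLOID if ploidy < PLOIDY_CUTOFF else AMP_CN_POLYPLOID
        if seg.copy_number == 0:
            call = "homozygous_deletion"
        elif seg.copy_number >= threshold:
            call = "amplification"
        else:
            call = "none"
        calls.append(CnaCall(seg, call))
    if n_dropped:
        logger.info("dropped %d segments >= 10 Mb", n_dropped)
    return calls


@dataclass
class GeneHitMatrix:
    """Boolean genes x samples hit matrices per modality."""

    hits: dict[str, pd.DataFrame] = field(default_factory=dict)

    def recurrence(self, modality: str) -> pd.Series:
        """Per-gene recurrence counts (row sums), sorted descending."""
        df = self.hits[modality]
        return df.sum(axis=1).sort_values(ascending=False)


_MODALITY_OF_CALL = {"amplification": "amplification", "homozygous_deletion": "deletion"}


def recurrence_profile(
    calls: Iterable[CnaCall],
    gene_models: GeneIndex | Sequence[GeneInterval],
) -> GeneHitMatrix:
    """Per-gene x per-sample hit matrix: >= 1 bp overlap with a called segment."""
    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    calls = list(calls)
    samples = sorted({c.segment.sample_id for c in calls})
    gene_ids = [g.gene_id for g in index.genes]
    matrices = {
        m: pd.DataFrame(False, index=gene_ids, columns=samples)
        for m in ("amplification", "deletion")
    }
    for c in calls:
        modality = _MODALITY_OF_CALL.get(c.call)
        if modality is None:
            continue
        seg = c.segment
        for gene in index.overlapping(seg.chrom, seg.start, seg.end):
            matrices[modality].loc[gene.gene_id, seg.sample_id] = True
    return GeneHitMatrix(hits=matrices)


@dataclass
class PermutationResult:
    """Per-gene empirical and Bonferroni-adjusted permutation p-values."""

    pvalues: pd.Series
    adjusted: pd.Series
    observed: pd.Series
    n_permutations: int
    n_genes_tested: int
    seed: int


def _concat_space(
    target_regions: Sequence[tuple[str, int, int]]
) -> tuple[list[tuple[str, int, int, int]], int]:
    """Map genomic target regions to concatenated coordinates.

    Returns ([(chrom, start, end, concat_offset)], total_length); regions
    are taken in the order supplied.
    """
    mapped = []
    offset = 0
    for chrom, start, end in target_regions:
        if end < start:
            raise ValueError(f"invalid target region {chrom}:{start}-{end}")
        mapped.append((chrom, start, end, offset))
        offset += end - start + 1
    return mapped, offset


def _gene_footprints(
    genes: Sequence[GeneInterval],
    mapped: Sequence[tuple[str, int, int, int]],
) -> dict[str, list[tuple[int, int]]]:
    """Half-open concatenated-coordinate pieces covered by each gene."""
    footprints: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        pieces = []
        for chrom, start, end, offset in mapped:
            if chrom != g.chrom:
                continue
            lo, hi = max(start, g.start), min(end, g.end)
            if lo <= hi:
                pieces.append((offset + lo - start, offset + hi - start + 1))
        if pieces:
            footprints[g.gene_id] = pieces
    return footprints


def permutation_enrichment(
    calls_per_sample: dict[str, list[CopyNumberSegment]],
    target_regions: Sequence[tuple[str, int, int]],
    gene_models: GeneIndex | Sequence[GeneInterval],
    n_perm: int = 10_000,
    seed: int = 0,
    bonferroni_n: int | None = None,
    genes_to_test: Sequence[str] | None = None,
) -> PermutationResult:
    """Length-preserving randomization test for per-gene recurrence.

    ``calls_per_sample`` holds, per sample, the segments of one called
    modality (for example all amplification segments).  Each permutation
    re-places every segment uniformly in the concatenated target space
    (length preserved) independently per sample, and recounts how many
    samples hit each gene.  By default every gene overlapping the target
    space is tested; genes with observed recurrence 0 have empirical p = 1
    by construction and are reported without re-simulation.
    """
    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    mapped, total_len = _concat_space(target_regions)
    footprints = _gene_footprints(index.genes, mapped)
    gene_ids = sorted(footprints) if genes_to_test is None else list(genes_to_test)
    for gid in gene_ids:
        if gid not in footprints:
            raise ValueError(f"gene {gid!r} does not overlap the target space")

    # observed recurrence, computed in the same concatenated space
    def _sample_hits(segments: list[tuple[int, int]]) -> dict[str, bool]:
        hits = {}
        for gid in gene_ids:
            hit = False
            for s0, s1 in segments:
                for g0, g1 in footprints[gid]:
                    if s0 < g1 and s1 > g0:
                        hit = True
                        break
                if hit:
                    break
            hits[gid] = hit
        return hits

    rng = np.random.default_rng(seed)
    sample_segments: dict[str, list[int]] = {}
    observed = pd.Series(0, index=gene_ids, dtype=int)
    for sample_id, segments in calls_per_sample.items():
        lengths = []
        concat_obs = []
        for seg in segments:
            if seg.length > total_len:
                raise ValueError(
                    f"segment of length {seg.length} exceeds the {total_len} bp "
                    "target space"
                )
            lengths.append(seg.length)
            for chrom, start, end, offset in mapped:
                if chrom == seg.chrom and seg.start <= end and seg.end >= start:
                    lo, hi = max(start, seg.start), min(end, seg.end)
                    concat_obs.append((offset + lo - start, offset + hi - start + 1))
        sample_segments[sample_id] = lengths
        for gid, hit in _sample_hits(concat_obs).items():
            observed[gid] += int(hit)

    tested = [gid for gid in gene_ids if observed[gid] > 0]
    counts = np.zeros((len(tested), n_perm), dtype=np.int32)
    for sample_id, lengths in sample_segments.items():
        if not lengths:
            continue
        hits = np.zeros((len(tested), n_perm), dtype=bool)
        for length in lengths:
            max_start = total_len - length
            starts = rng.integers(0, max_start + 1, size=n_perm)
            ends = starts + length  # half-open
            for gi, gid in enumerate(tested):
                for g0, g1 in footprints[gid]:
                    hits[gi] |= (starts < g1) & (ends > g0)
        counts += hits
    pvalues = pd.Series(1.0, index=gene_ids)
    for gi, gid in enumerate(tested):
        pvalues[gid] = (np.sum(counts[gi] >= observed[gid]) + 1) / (n_perm + 1)
    n_tested = bonferroni_n if bonferroni_n is not None else len(gene_ids)
    adjusted = (pvalues * n_tested).clip(upper=1.0)
    return PermutationResult(
        pvalues=pvalues,
        adjusted=adjusted,
        observed=observed,
        n_permutations=n_perm,
        n_genes_tested=n_tested,
        seed=seed,
    )


def subgroup_association(
    hit: Sequence[bool],
    in_subgroup: Sequence[bool],
    correction: bool = False,
) -> tuple[float | None, float | None]:
    """Pearson chi-square test of hit status x subgroup membership (2x2).

    Returns (statistic, p).  Degenerate margins (all samples hit, or none)
    give (None, None) with a warning logged.  ``correction`` enables the
    Yates continuity correction (off by default).
    """
    hit = np.asarray(hit, dtype=bool)
    grp = np.asarray(in_subgroup, dtype=bool)
    if hit.shape != grp.shape:
        raise ValueError("hit and subgroup vectors differ in length")
    if len(set(grp.tolist())) < 2:
        raise ValueError("need samples both inside and outside the subgroup")
    table = np.array(
        [
            [np.sum(hit & grp), np.sum(hit & ~grp)],
            [np.sum(~hit & grp), np.sum(~hit & ~grp)],
        ]
    )
    if table.sum(axis=1).min() == 0:
        logger.warning("degenerate margin in subgroup association (all or no hits)")
        return None, None
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)
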