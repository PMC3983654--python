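"""Consequence annotation and somatic-variant filtering.

Annotation is a minimal, strand-aware classifier against the package's own
gene models: codon-level effect inside the CDS (standard genetic code),
splice sites as the canonical +/-2 intronic positions, UTRs by position
relative to the CDS, and start-gain detection in the 5' UTR.  It is not a
full effect predictor — one consequence per record against the single
supplied transcript per gene.

The somatic filters encode the post-processing thresholds used for the
tumor/normal calls: SNVs require normal VAF <= 3%, tumor VAF >= 10% and no
germline variant within 5 bp; indels require >= 15x depth in both tissues
plus split-read/alignment support rules that differ for small (<= 10 bp)
and larger events.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .types import Consequence, GeneInterval, MutationRecord, VariantClass

__all__ = [
    "GeneIndex",
    "annotate_consequence",
    "annotate_catalog",
    "FilterVerdict",
    "somatic_snv_filter",
    "indel_filter",
    "ns_s_ratio",
]

SPLICE_WINDOW = 2  # intronic bases flanking each exon that count as splice site

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GeneIndex:
    """Interval index over gene models for overlap queries."""

    def __init__(self, genes: Iterable[GeneInterval]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in self.genes:
            # interval trees are half-open; genes are 1-based inclusive
            self._trees[g.chrom].addi(g.start, g.end + 1, g)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end + 1)),
                      key=lambda g: (g.start, g.gene_id))

    def by_id(self) -> dict[str, GeneInterval]:
        return {g.gene_id: g for g in self.genes}


def _cds_sequence(gene: GeneInterval, genome: Mapping[str, str]) -> str:
    chrom_seq = genome[gene.chrom]
    cds = "".join(chrom_seq[s - 1 : e] for s, e in gene.coding_exon_pieces)
    return revcomp(cds) if gene.strand == "-" else cds


def _cds_offset(gene: GeneInterval, pos: int) -> int | None:
    """0-based offset of genomic ``pos`` within the gene's CDS, or None."""
    pieces = gene.coding_exon_pieces
    offset = 0
    if gene.strand == "+":
        for s, e in pieces:
            if s <= pos <= e:
                return offset + (pos - s)
            offset += e - s + 1
    else:
        for s, e in reversed(pieces):
            if s <= pos <= e:
                return offset + (e - pos)
            offset += e - s + 1
    return None


def _is_splice_site(gene: GeneInterval, pos: int) -> bool:
    """True when ``pos`` is intronic within SPLICE_WINDOW of an exon edge."""
    if not (gene.start <= pos <= gene.end):
        return False
    if any(s <= pos <= e for s, e in gene.exons):
        return False
    first, last = gene.exons[0][0], gene.exons[-1][1]
    if pos < first or pos > last:
        return False  # inside gene bounds but outside the transcribed span
    for s, e in gene.exons:
        if 0 < s - pos <= SPLICE_WINDOW or 0 < pos - e <= SPLICE_WINDOW:
            return True
    return False


def _snv_consequence(
    record: MutationRecord, gene: GeneInterval, genome: Mapping[str, str]
) -> Consequence:
    pos = record.pos
    if _is_splice_site(gene, pos):
        return Consequence.SPLICE_SITE
    in_exon = any(s <= pos <= e for s, e in gene.exons)
    if not in_exon:
        return Consequence.INTERGENIC  # deep intron: treated as non-coding
    if gene.cds_start is None:
        return Consequence.INTERGENIC
    cds_off = _cds_offset(gene, pos)
    if cds_off is None:
        # exonic but outside the CDS: UTR, oriented by strand
        if gene.strand == "+":
            five_prime = pos < gene.cds_start
        else:
            five_prime = pos > gene.cds_end
        if five_prime and _creates_start(record, gene, genome):
            return Consequence.START_GAINED
        return Consequence.UTR5 if five_prime else Consequence.UTR3
    cds = _cds_sequence(gene, genome)
    codon_i, within = divmod(cds_off, 3)
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return Consequence.INTERGENIC  # truncated terminal codon; unclassifiable
    alt_base = record.alt_allele
    if gene.strand == "-":
        alt_base = alt_base.translate(_COMPLEMENT)
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == "*":
        return Consequence.SYNONYMOUS if alt_aa == "*" else Consequence.STOP_LOST
    if alt_aa == "*":
        return Consequence.NONSENSE
    return Consequence.SYNONYMOUS if ref_aa == alt_aa else Consequence.MISSENSE


def _creates_start(
    record: MutationRecord, gene: GeneInterval, genome: Mapping[str, str]
) -> bool:
    """Does the substitution create an ATG codon on the coding strand?"""
    chrom_seq = genome[gene.chrom]
    lo = max(0, record.pos - 3)
    hi = min(len(chrom_seq), record.pos + 2)
    window = chrom_seq[lo:hi]
    mutated = (
        window[: record.pos - 1 - lo] + record.alt_allele + window[record.pos - lo :]
    )
    if gene.strand == "-":
        window, mutated = revcomp(window), revcomp(mutated)
    return "ATG" in mutated and "ATG" not in window


def annotate_consequence(
    record: MutationRecord,
    gene_models: GeneIndex | Sequence[GeneInterval],
    genome: Mapping[str, str],
) -> Consequence:
    """Classify one mutation against the gene models.

    Raises ``ValueError`` when the record's reference allele disagrees with
    the genome sequence (data-integrity guard).
    """
    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    chrom_seq = genome.get(record.chrom)
    if chrom_seq is not None:
        genome_ref = chrom_seq[record.pos - 1 : record.pos - 1 + len(record.ref_allele)]
        if genome_ref.upper() != record.ref_allele:
            raise ValueError(
                f"reference mismatch at {record.chrom}:{record.pos}: "
                f"record {record.ref_allele!r} vs genome {genome_ref!r}"
            )
    span_end = record.pos + max(len(record.ref_allele) - 1, 0)
    genes = index.overlapping(record.chrom, record.pos, span_end)
    if not genes:
        return Consequence.INTERGENIC
    gene = genes[0]
    record.gene_id = gene.gene_id
    if record.variant_class is not VariantClass.SNV:
        if _is_splice_site(gene, record.pos):
            return Consequence.SPLICE_SITE
        cds_hit = gene.cds_start is not None and any(
            s <= p <= e
            for s, e in gene.coding_exon_pieces
            for p in (record.pos, span_end)
        )
        if not cds_hit:
            return Consequence.INTERGENIC
        indel_len = abs(len(record.alt_allele) - len(record.ref_allele))
        return (
            Consequence.FRAMESHIFT if indel_len % 3 else Consequence.INFRAME_INDEL
        )
    return _snv_consequence(record, gene, genome)


def annotate_catalog(
    records: Iterable[MutationRecord],
    gene_models: GeneIndex | Sequence[GeneInterval],
    genome: Mapping[str, str],
) -> list[MutationRecord]:
    """Annotate every record in place (and return the list)."""
    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    out = []
    for r in records:
        r.consequence = annotate_consequence(r, index, genome)
        out.append(r)
    return out


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reason: str  # machine-readable reason code; "pass" when passed

    def __bool__(self) -> bool:
        return self.passed


def somatic_snv_filter(
    record: MutationRecord,
    germline_sites: Iterable[tuple[str, int]] = (),
    max_normal_vaf: float = 0.03,
    min_tumor_vaf: float = 0.10,
    germline_window: int = 5,
) -> FilterVerdict:
    """Tumor/normal contamination filter for substitution calls.

    Pass requires normal VAF <= ``max_normal_vaf``, tumor VAF >=
    ``min_tumor_vaf`` and no germline SNP/indel within ``germline_window``
    bp of the call.
    """
    if record.tumor_depth == 0 or record.normal_depth == 0:
        return FilterVerdict(False, "no_coverage")
    if record.normal_vaf > max_normal_vaf:
        return FilterVerdict(False, "normal_contamination")
    if record.tumor_vaf < min_tumor_vaf:
        return FilterVerdict(False, "low_tumor_vaf")
    for chrom, pos in germline_sites:
        if chrom == record.chrom and abs(pos - record.pos) <= germline_window:
            return FilterVerdict(False, "germline_proximity")
    return FilterVerdict(True, "pass")


def indel_filter(
    record: MutationRecord,
    pindel_support: int,
    bwa_support: int,
    strand_support: tuple[int, int] = (0, 0),
    in_repeat: bool = False,
    min_depth: int = 15,
    small_indel_max: int = 10,
) -> FilterVerdict:
    """Confidence filter for insertion/deletion calls.

    Both tissues need >= ``min_depth`` reads.  Small indels (length <=
    ``small_indel_max``) need >= 4 split-read (Pindel-style) supporting
    reads and >= 1 from the aligner; larger indels must lie outside repeat
    regions with >= 1 supporting read on each strand.
    """
    if record.tumor_depth < min_depth or record.normal_depth < min_depth:
        return FilterVerdict(False, "low_depth")
    indel_len = abs(len(record.alt_allele) - len(record.ref_allele))
    if indel_len <= small_indel_max:
        if pindel_support < 4:
            return FilterVerdict(False, "insufficient_pindel_support")
        if bwa_support < 1:
            return FilterVerdict(False, "no_bwa_support")
        return FilterVerdict(True, "pass")
    if in_repeat:
        return FilterVerdict(False, "repeat_region")
    if min(strand_support) < 1:
        return FilterVerdict(False, "single_strand_support")
    return FilterVerdict(True, "pass")


def ns_s_ratio(catalog: Iterable[MutationRecord]) -> float | None:
    """Non-synonymous (missense + nonsense) to synonymous count ratio.

    Returns None when the catalog has no synonymous mutation (ratio
    undefined).  Splice-site, UTR and non-coding classes do not enter
    either side of the ratio.
    """
    records = list(catalog)
    ns = sum(
        1 for r in records
        if r.consequence in (Consequence.MISSENSE, Consequence.NONSENSE)
    )
    s = sum(1 for r in records if r.consequence is Consequence.SYNONYMOUS)
    if s == 0:
        return None
    return ns / s
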