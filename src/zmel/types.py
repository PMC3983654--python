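"""Domain types for the zebrafish melanoma exome analysis.

All genomic coordinates on these types are 1-based and inclusive, the
convention shared by VCF, GFF3 and SEG files.  Algorithms convert to 0-based
offsets internally where convenient, never at a type boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "VariantClass",
    "Consequence",
    "MutationRecord",
    "SampleMetadata",
    "CopyNumberSegment",
    "GeneInterval",
    "GeneSet",
    "count_drivers",
]

_BASES = frozenset("ACGT")


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


class Consequence(str, enum.Enum):
    """Functional consequence of a variant on a transcript."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"
    UTR3 = "utr3"
    UTR5 = "utr5"
    START_GAINED = "start_gained"
    STOP_LOST = "stop_lost"
    INTERGENIC = "intergenic"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"


@dataclass
class MutationRecord:
    """One somatic SNV or indel call in one tumor/normal pair.

    ``ref_allele``/``alt_allele`` follow VCF conventions: an SNV has two
    single distinct bases; an insertion has ``len(alt) > len(ref)``; a
    deletion has ``len(ref) > len(alt)``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass
    tumor_depth: int
    tumor_alt_count: int
    normal_depth: int
    normal_alt_count: int
    consequence: Consequence | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.variant_class = VariantClass(self.variant_class)
        if self.consequence is not None:
            self.consequence = Consequence(self.consequence)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        ref, alt = self.ref_allele, self.alt_allele
        if not ref or not alt or set(ref + alt) - _BASES:
            raise ValueError(f"alleles must be non-empty DNA strings: {ref!r}>{alt!r}")
        if self.variant_class is VariantClass.SNV:
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                raise ValueError(f"SNV requires single distinct bases: {ref!r}>{alt!r}")
        elif self.variant_class is VariantClass.INS:
            if len(alt) <= len(ref):
                raise ValueError(f"INS requires len(alt) > len(ref): {ref!r}>{alt!r}")
        elif self.variant_class is VariantClass.DEL:
            if len(ref) <= len(alt):
                raise ValueError(f"DEL requires len(ref) > len(alt): {ref!r}>{alt!r}")
        for tissue, depth, altc in (
            ("tumor", self.tumor_depth, self.tumor_alt_count),
            ("normal", self.normal_depth, self.normal_alt_count),
        ):
            if depth < 0 or altc < 0 or altc > depth:
                raise ValueError(
                    f"{tissue} counts invalid: alt {altc} / depth {depth}"
                )

    @property
    def tumor_vaf(self) -> float | None:
        """Tumor variant allele fraction; None when depth is zero."""
        return self.tumor_alt_count / self.tumor_depth if self.tumor_depth else None

    @property
    def normal_vaf(self) -> float | None:
        return self.normal_alt_count / self.normal_depth if self.normal_depth else None

    @property
    def is_snv(self) -> bool:
        return self.variant_class is VariantClass.SNV


@dataclass
class SampleMetadata:
    """Engineered genotype, age and ploidy of one fish/tumor.

    ``oncogene`` is the melanocyte-restricted initiating transgene (human
    BRAF(V600E) or NRAS(Q61K)); ``p53`` the germline tp53(M214K) zygosity;
    ``mitf`` the germline mitfa status (wild type, null/nacre, or the
    temperature-sensitive hypomorph vc7); ``mitf_rescue`` marks mosaic MITF
    re-expression (miniCoopR) in a mitfa-null background.  ``extra_alleles``
    holds further germline driver alleles (for example ``ptena_het``,
    ``rps29_het``); ``extra_transgenes`` holds co-expressed transgenes of
    unknown oncogenic contribution (KROX20, FOXD3, OCT6, SETDB1, EGFP) which
    are deliberately not counted as drivers.
    """

    sample_id: str
    oncogene: str
    p53: str = "wt"
    mitf: str = "wt"
    mitf_rescue: bool = False
    extra_alleles: list[str] = field(default_factory=list)
    extra_transgenes: list[str] = field(default_factory=list)
    age: float | None = None
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        if self.oncogene not in ("BRAF", "NRAS"):
            raise ValueError(f"oncogene must be BRAF or NRAS, got {self.oncogene!r}")
        if self.p53 not in ("wt", "het", "hom"):
            raise ValueError(f"p53 must be wt/het/hom, got {self.p53!r}")
        if self.mitf not in ("wt", "null", "vc7"):
            raise ValueError(f"mitf must be wt/null/vc7, got {self.mitf!r}")
        if self.mitf_rescue and self.mitf != "null":
            raise ValueError("mitf_rescue requires a mitf-null background")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be positive, got {self.ploidy}")


def count_drivers(meta: SampleMetadata) -> int:
    """Number of engineered initiating driver events in a genotype.

    Each germline driver counts as one event regardless of zygosity: the
    oncogenic transgene, any mutant p53 allele, any non-wild-type mitf
    allele, the mosaic MITF rescue, and each extra germline driver allele.
    Co-expressed transgenes of unknown contribution are not counted, so the
    BRAF;p53-/-;mitf-/-;MITF-rescue genotypes score four drivers whichever
    transcription factor rides along.
    """
    n = 1  # the initiating oncogene
    if meta.p53 in ("het", "hom"):
        n += 1
    if meta.mitf in ("null", "vc7"):
        n += 1
    if meta.mitf_rescue:
        n += 1
    n += len(meta.extra_alleles)
    return n


@dataclass
class CopyNumberSegment:
    """A per-sample genomic interval with an integer total copy number."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid segment coordinates {self.chrom}:{self.start}-{self.end}"
            )
        if self.copy_number < 0:
            raise ValueError(f"copy_number must be >= 0, got {self.copy_number}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneInterval:
    """A protein-coding gene model: exon structure plus CDS bounds.

    ``exons`` are sorted, non-overlapping (start, end) pairs within
    [start, end].  ``cds_start``/``cds_end`` are the genomic bounds of the
    coding region; exonic sequence between them (in transcript order,
    reverse-complemented on the minus strand) is the CDS and is assumed to
    start in frame 0.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid gene bounds {self.start}-{self.end}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise ValueError(f"exons overlap or are unsorted in {self.gene_id}")
            if s < self.start or e > self.end or e < s:
                raise ValueError(f"exon ({s},{e}) outside gene bounds in {self.gene_id}")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")

    @property
    def coding_exon_pieces(self) -> list[tuple[int, int]]:
        """Genomic (start, end) pieces of the CDS in genomic order."""
        if self.cds_start is None:
            return []
        pieces = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                pieces.append((lo, hi))
        return pieces


@dataclass
class GeneSet:
    """A named gene set (one GMT line)."""

    set_id: str
    description: str
    gene_ids: set[str]

    def __post_init__(self) -> None:
        self.gene_ids = set(self.gene_ids)
        if not self.gene_ids:
            raise ValueError(f"gene set {self.set_id!r} is empty")
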