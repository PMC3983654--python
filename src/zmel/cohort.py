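"""Synthetic study-cohort generator.

Generates a complete, self-consistent desk-scale study — genome, gene
models, sample sheet, somatic mutation catalog, copy-number segments, gene
sets and a truth manifest — whose statistical structure mirrors the
engineered zebrafish melanoma cohort it emulates:

* 53 samples with the study's genotype composition (38 BRAF- and 15
  NRAS-driven lines, a 25-sample MITF-rescue subgroup);
* per-sample coding substitution burdens from a negative-binomial model
  whose mean falls with the engineered driver count and rises with age,
  calibrated to a cohort median of 4;
* a 6-class substitution spectrum with C>T dominant (24.4%);
* one hypermutant sample (47 substitutions, every reference base C or G);
* one sample carrying two kataegis-like microclusters (12 mutations within
  4,500 bp and 5 within 5 kb, similar VAFs, mostly C>T) plus dispersed
  background;
* a recurrent 175 kb amplicon implanted in exactly 10 samples of the
  rescue subgroup, covering a five-gene cluster on the chr3 analog;
* 13 short indels (< 5 bp) adjacent to implanted tandem repeats, and an
  excess of homozygous deletions in the mitf-vc7 subgroup.

The genome is deliberately small (21 chromosomes of 1-3 Mb) so interval
arithmetic, annotation and permutation testing run at desk scale; every
implanted structure is recorded in the truth manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as zio
from .types import (
    CopyNumberSegment,
    GeneInterval,
    GeneSet,
    MutationRecord,
    SampleMetadata,
    VariantClass,
    count_drivers,
)

__all__ = [
    "GenotypeRow",
    "BurdenModel",
    "SpecialSampleSpec",
    "AmpliconSpec",
    "CohortConfig",
    "CohortBundle",
    "generate_cohort",
    "generate_special_sample",
    "draw_burdens",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

AMPLICON_GENES = (
    "prkacaa_like",
    "samd1_like",
    "asf1ba_like",
    "wufj41e11_like",
    "tecra_like",
)
AMPLICON_FLANK_GENES = ("rnf222_like", "gcgr_like")


@dataclass(frozen=True)
class GenotypeRow:
    """One genotype row of the study table: a count plus the genotype."""

    count: int
    oncogene: str
    p53: str = "wt"
    mitf: str = "wt"
    mitf_rescue: bool = False
    extra_alleles: tuple[str, ...] = ()
    extra_transgenes: tuple[str, ...] = ()


#: Default genotype composition (counts sum to 53; the six rescue rows sum
#: to 25 and form the amplicon carrier subgroup).
DEFAULT_GENOTYPE_TABLE: tuple[GenotypeRow, ...] = (
    GenotypeRow(1, "BRAF"),
    GenotypeRow(2, "BRAF", p53="het"),
    GenotypeRow(1, "BRAF", p53="het", extra_alleles=("ptena_het",)),
    GenotypeRow(4, "BRAF", mitf="vc7"),
    GenotypeRow(4, "BRAF", p53="het", mitf="vc7"),
    GenotypeRow(6, "BRAF", p53="hom", mitf="null", mitf_rescue=True),
    GenotypeRow(4, "BRAF", p53="hom", mitf="null", mitf_rescue=True,
                extra_transgenes=("FOXD3",)),
    GenotypeRow(12, "BRAF", p53="hom", mitf="null", mitf_rescue=True,
                extra_transgenes=("KROX20",)),
    GenotypeRow(1, "BRAF", p53="hom", mitf="null", mitf_rescue=True,
                extra_transgenes=("KROX20", "FOXD3", "OCT6")),
    GenotypeRow(1, "BRAF", p53="hom", mitf="null", mitf_rescue=True,
                extra_transgenes=("SETDB1",)),
    GenotypeRow(1, "BRAF", p53="hom", mitf="null", mitf_rescue=True,
                extra_transgenes=("EGFP",)),
    GenotypeRow(2, "NRAS"),
    GenotypeRow(5, "NRAS", p53="hom"),
    GenotypeRow(4, "NRAS", p53="het"),
    GenotypeRow(5, "NRAS", p53="het", extra_alleles=("rps29_het",)),
)


@dataclass
class BurdenModel:
    """Negative-binomial coding-substitution burden model.

    log(mean) = intercept + driver_coefficient * drivers
              + age_coefficient * age_months.
    ``dispersion`` is the NB size parameter k (variance = mu + mu^2 / k).
    The default intercept was calibrated once, by simulation over the
    default genotype table and age range, to a cohort median burden of 4.
    """

    intercept: float = 2.45
    driver_coefficient: float = -0.45
    age_coefficient: float = 0.04
    dispersion: float = 3.0

    def mean(self, drivers: int, age: float) -> float:
        return float(np.exp(
            self.intercept
            + self.driver_coefficient * drivers
            + self.age_coefficient * age
        ))


@dataclass
class SpecialSampleSpec:
    """Archetype spec for a special sample.

    ``archetype`` is 'cg_exclusive' (n substitutions, all at C:G pairs) or
    'kataegis' (``clusters`` of (size, max_span_bp) plus ``n_background``
    dispersed substitutions; clustered variants share similar VAFs within
    ``vaf_jitter`` and are mostly C>T).
    """

    archetype: str
    n: int = 47
    clusters: tuple[tuple[int, int], ...] = ((12, 4_500), (5, 5_000))
    n_background: int = 13
    vaf_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.archetype not in ("cg_exclusive", "kataegis"):
            raise ValueError(f"unsupported archetype {self.archetype!r}")
        for size, span in self.clusters:
            if size < 2:
                raise ValueError("cluster size must be >= 2")
            if span < size - 1:
                raise ValueError(
                    f"span {span} bp cannot hold {size} distinct positions"
                )


@dataclass
class AmpliconSpec:
    """The recurrent amplicon: locus, width, carriers and copy number."""

    chrom: str = "chr3"
    start: int = 1_500_001
    width: int = 175_000
    n_carriers: int = 10
    copy_number: int = 9

    @property
    def end(self) -> int:
        return self.start + self.width - 1


@dataclass
class CohortConfig:
    """Full configuration of the synthetic study."""

    n_samples: int = 53
    genotype_table: tuple[GenotypeRow, ...] = DEFAULT_GENOTYPE_TABLE
    burden_model: BurdenModel = field(default_factory=BurdenModel)
    #: 6-class probabilities, C>T dominant at the study's 24.4%.
    spectrum_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "C>A": 0.14, "C>G": 0.11, "C>T": 0.244,
            "T>A": 0.13, "T>C": 0.236, "T>G": 0.14,
        }
    )
    hypermutant: SpecialSampleSpec = field(
        default_factory=lambda: SpecialSampleSpec("cg_exclusive", n=47)
    )
    kataegis: SpecialSampleSpec = field(
        default_factory=lambda: SpecialSampleSpec("kataegis")
    )
    amplicon: AmpliconSpec = field(default_factory=AmpliconSpec)
    deletion_excess_mitf: str = "vc7"
    indel_total: int = 13
    age_range: tuple[float, float] = (6.0, 18.0)
    n_chromosomes: int = 21
    chrom_length_range: tuple[int, int] = (1_000_000, 3_000_000)
    genes_per_chromosome: int = 25
    seed: int = 2013

    def __post_init__(self) -> None:
        if sum(r.count for r in self.genotype_table) != self.n_samples:
            raise ValueError("genotype table counts must sum to n_samples")
        total = sum(self.spectrum_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum mixture must sum to 1, got {total}")
        subgroup = sum(r.count for r in self.genotype_table if r.mitf_rescue)
        if self.amplicon.n_carriers > subgroup:
            raise ValueError(
                f"amplicon carriers ({self.amplicon.n_carriers}) exceed the "
                f"rescue subgroup size ({subgroup})"
            )


@dataclass
class CohortBundle:
    """Everything the downstream pipeline consumes, plus the truth manifest."""

    genome: dict[str, str]
    genes: list[GeneInterval]
    samples: list[SampleMetadata]
    mutations: list[MutationRecord]
    segments: list[CopyNumberSegment]
    gene_sets: list[GeneSet]
    truth: dict

    def write(self, out_dir: str | Path) -> Path:
        out = zio.ensure_dir(out_dir)
        zio.write_fasta(self.genome, out / "genome.fa")
        zio.write_gene_models(self.genes, out / "genes.gff3")
        zio.write_sample_sheet(self.samples, out / "samples.tsv")
        zio.write_mutations(self.mutations, out / "mutations.tsv")
        zio.write_segments(self.segments, out / "segments.tsv")
        zio.write_gmt(self.gene_sets, out / "gene_sets.gmt")
        with open(out / "truth_manifest.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return out


# ---------------------------------------------------------------------------
# genome and gene-model construction

_SENSE_CODONS: list[str] | None = None


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        import itertools

        from Bio.Seq import Seq

        _SENSE_CODONS = sorted(
            c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
            if str(Seq(c).translate()) != "*"
        )
    return _SENSE_CODONS


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = rng.choice(_sense_codons(), size=n_codons - 1)
    return "".join(codons) + "TAA"


def _make_gene(
    gene_id: str, chrom: str, start: int, strand: str, rng: np.random.Generator
) -> tuple[GeneInterval, list[tuple[int, int]], str]:
    """Gene layout: UTR5(100) [300 CDS] i(800) [300 CDS] i(800) [300 CDS] UTR3(150).

    Returns the model, the genomic CDS pieces, and the CDS sequence
    (transcript orientation) to be written into the genome.
    """
    utr5, cds_exon, intron, utr3 = 100, 300, 800, 150
    if strand == "+":
        e1 = (start, start + utr5 + cds_exon - 1)
        e2 = (e1[1] + intron + 1, e1[1] + intron + cds_exon)
        e3 = (e2[1] + intron + 1, e2[1] + intron + cds_exon + utr3)
        cds_start, cds_end = start + utr5, e3[1] - utr3
    else:
        e1 = (start, start + utr3 + cds_exon - 1)
        e2 = (e1[1] + intron + 1, e1[1] + intron + cds_exon)
        e3 = (e2[1] + intron + 1, e2[1] + intron + cds_exon + utr5)
        cds_start, cds_end = start + utr3, e3[1] - utr5
    gene = GeneInterval(
        gene_id=gene_id, chrom=chrom, start=e1[0], end=e3[1], strand=strand,
        exons=[e1, e2, e3], cds_start=cds_start, cds_end=cds_end,
    )
    cds_seq = _random_cds(cds_exon, rng)  # 300 codons = 900 bp across 3 pieces
    return gene, gene.coding_exon_pieces, cds_seq


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


GENE_SPAN = 100 + 300 + 800 + 300 + 800 + 300 + 150  # 2,750 bp


def _build_genome(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], list[GeneInterval]]:
    genome: dict[str, np.ndarray] = {}
    genes: list[GeneInterval] = []
    lo, hi = config.chrom_length_range
    amp = config.amplicon
    for ci in range(1, config.n_chromosomes + 1):
        chrom = f"chr{ci}"
        length = int(rng.integers(lo, hi + 1))
        if chrom == amp.chrom:
            length = max(length, amp.end + 200_000)
        arr = _BASE_BYTES[rng.integers(0, 4, size=length)].copy()
        genome[chrom] = arr
        slots = np.linspace(
            10_000, length - GENE_SPAN - 10_000, config.genes_per_chromosome
        ).astype(int)
        gi = 0
        for slot in slots:
            if chrom == amp.chrom and slot + GENE_SPAN >= amp.start - 50_000 and slot <= amp.end + 50_000:
                continue  # keep the amplicon window free of ordinary genes
            gi += 1
            strand = "+" if (gi % 2) else "-"
            gene, pieces, cds = _make_gene(f"{chrom}_g{gi:03d}", chrom, int(slot), strand, rng)
            _write_cds(arr, pieces, cds, strand)
            genes.append(gene)
        if chrom == amp.chrom:
            genes.extend(_build_amplicon_genes(arr, amp, rng))
    return genome, genes


def _write_cds(
    arr: np.ndarray, pieces: list[tuple[int, int]], cds: str, strand: str
) -> None:
    genomic = cds if strand == "+" else _revcomp(cds)
    offset = 0
    for s, e in pieces:
        piece_len = e - s + 1
        arr[s - 1 : e] = np.frombuffer(
            genomic[offset : offset + piece_len].encode("ascii"), dtype=np.uint8
        )
        offset += piece_len


def _build_amplicon_genes(
    arr: np.ndarray, amp: AmpliconSpec, rng: np.random.Generator
) -> list[GeneInterval]:
    """Five resident genes spaced through the amplicon plus two flankers."""
    genes = []
    spacing = (amp.width - GENE_SPAN) // (len(AMPLICON_GENES) - 1 or 1)
    for i, name in enumerate(AMPLICON_GENES):
        start = amp.start + 5_000 + i * (spacing - 2_000)
        strand = "+" if (i % 2 == 0) else "-"
        gene, pieces, cds = _make_gene(name, amp.chrom, start, strand, rng)
        _write_cds(arr, pieces, cds, strand)
        genes.append(gene)
    for name, start in (
        (AMPLICON_FLANK_GENES[0], amp.start - 40_000),
        (AMPLICON_FLANK_GENES[1], amp.end + 20_000),
    ):
        gene, pieces, cds = _make_gene(name, amp.chrom, start, "+", rng)
        _write_cds(arr, pieces, cds, "+")
        genes.append(gene)
    return genes


class _CodingIndex:
    """Flat arrays of coding positions and their (plus-strand) bases."""

    def __init__(self, genome: dict[str, np.ndarray], genes: Sequence[GeneInterval]):
        self.chrom_names: list[str] = []
        for g in genes:
            if g.chrom not in self.chrom_names:
                self.chrom_names.append(g.chrom)
        name_to_id = {c: i for i, c in enumerate(self.chrom_names)}
        chrom_ids, positions, bases = [], [], []
        for g in genes:
            arr = genome[g.chrom]
            for s, e in g.coding_exon_pieces:
                positions.append(np.arange(s, e + 1, dtype=np.int64))
                bases.append(arr[s - 1 : e])
                chrom_ids.append(np.full(e - s + 1, name_to_id[g.chrom], dtype=np.int32))
        self.chrom_id = np.concatenate(chrom_ids)
        self.pos = np.concatenate(positions)
        self.base = np.concatenate(bases)
        self.by_base = {
            b: np.flatnonzero(self.base == ord(b)) for b in "ACGT"
        }

    def sample_position(
        self,
        base: str,
        rng: np.random.Generator,
        used: set[tuple[str, int]],
        avoid: Sequence[tuple[str, int, int]] = (),
    ) -> tuple[str, int]:
        idx_pool = self.by_base[base]
        for _ in range(200):
            i = int(rng.integers(0, len(idx_pool)))
            j = idx_pool[i]
            key = (self.chrom_names[self.chrom_id[j]], int(self.pos[j]))
            if key in used:
                continue
            if any(c == key[0] and lo <= key[1] <= hi for c, lo, hi in avoid):
                continue
            used.add(key)
            return key
        raise RuntimeError(f"could not find an unused coding {base} position")


# ---------------------------------------------------------------------------
# mutation generation

def _depths(rng: np.random.Generator, vaf: float | None = None) -> tuple[int, int, int, int]:
    """Plausible tumor/normal depths and alt counts for a clonal somatic call."""
    t_depth = max(20, int(rng.poisson(60)))
    if vaf is None:
        vaf = float(rng.uniform(0.35, 0.60))
    t_alt = int(round(t_depth * vaf))
    t_alt = max(t_alt, max(3, int(np.ceil(0.10 * t_depth))))  # clears the VAF filter
    t_alt = min(t_alt, t_depth)
    n_depth = max(15, int(rng.poisson(60)))
    return t_depth, t_alt, n_depth, 0


def _snv_record(
    sample_id: str, chrom: str, pos: int, ref: str, klass: str,
    rng: np.random.Generator, vaf: float | None = None,
) -> MutationRecord:
    """Build an SNV record for folded class ``klass`` at a site with
    plus-strand base ``ref`` (which may be the purine complement)."""
    pyr_ref, alt = klass.split(">")
    if ref == pyr_ref:
        alt_base = alt
    elif ref == _COMPLEMENT[pyr_ref]:
        alt_base = _COMPLEMENT[alt]
    else:
        raise ValueError(f"site base {ref} incompatible with class {klass}")
    t_depth, t_alt, n_depth, n_alt = _depths(rng, vaf)
    return MutationRecord(
        sample_id=sample_id, chrom=chrom, pos=pos,
        ref_allele=ref, alt_allele=alt_base, variant_class=VariantClass.SNV,
        tumor_depth=t_depth, tumor_alt_count=t_alt,
        normal_depth=n_depth, normal_alt_count=n_alt,
    )


def _draw_class(mixture: dict[str, float], rng: np.random.Generator) -> str:
    classes = list(mixture)
    probs = np.array([mixture[c] for c in classes])
    return classes[int(rng.choice(len(classes), p=probs))]


def _generate_background_snvs(
    sample_id: str, n: int, mixture: dict[str, float],
    coding: _CodingIndex, rng: np.random.Generator, used: set[tuple[str, int]],
    avoid: Sequence[tuple[str, int, int]] = (),
) -> list[MutationRecord]:
    records = []
    for _ in range(n):
        klass = _draw_class(mixture, rng)
        pyr = klass.split(">")[0]
        base = pyr if rng.random() < 0.5 else _COMPLEMENT[pyr]
        chrom, pos = coding.sample_position(base, rng, used, avoid)
        records.append(_snv_record(sample_id, chrom, pos, base, klass, rng))
    return records


def generate_special_sample(
    spec: SpecialSampleSpec,
    sample_id: str,
    genome: dict[str, str] | dict[str, np.ndarray],
    genes: Sequence[GeneInterval],
    seed: int = 0,
) -> list[MutationRecord]:
    """Generate the mutation records of one special-archetype sample.

    'cg_exclusive': exactly ``spec.n`` coding substitutions, every
    reference base C or G.  'kataegis': the configured microclusters
    (sizes and maximum spans, members mostly C>T at similar VAFs) plus
    ``spec.n_background`` dispersed substitutions.
    """
    rng = np.random.default_rng(seed)
    arrays = {
        c: (s if isinstance(s, np.ndarray) else _seq_array(s)) for c, s in genome.items()
    }
    coding = _CodingIndex(arrays, genes)
    used: set[tuple[str, int]] = set()
    if spec.archetype == "cg_exclusive":
        records = []
        # a distinct C:G-restricted signature, deliberately not C>T-dominated
        cg_mixture = {"C>A": 0.40, "C>G": 0.30, "C>T": 0.30}
        for _ in range(spec.n):
            klass = _draw_class(cg_mixture, rng)
            base = "C" if rng.random() < 0.5 else "G"
            chrom, pos = coding.sample_position(base, rng, used)
            records.append(_snv_record(sample_id, chrom, pos, base, klass, rng))
        return records
    # kataegis archetype
    records = []
    avoid: list[tuple[str, int, int]] = []
    eligible = [g for g in genes if g.chrom != "chr3"]
    gene_pick = rng.choice(len(eligible), size=len(spec.clusters), replace=False)
    for (size, max_span), gidx in zip(spec.clusters, gene_pick):
        gene = eligible[int(gidx)]
        members = _make_cluster_records(
            sample_id, gene, size, max_span, spec.vaf_jitter,
            arrays[gene.chrom], rng, used,
        )
        records.extend(members)
        # keep dispersed background clear of the cluster so the implanted
        # run is exactly what the detector should find
        avoid.append(
            (gene.chrom, members[0].pos - 10_000, members[-1].pos + 10_000)
        )
    mixture = {"C>A": 0.14, "C>G": 0.11, "C>T": 0.244,
               "T>A": 0.13, "T>C": 0.236, "T>G": 0.14}
    records.extend(
        _generate_background_snvs(
            sample_id, spec.n_background, mixture, coding, rng, used, avoid
        )
    )
    return records


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _make_cluster_records(
    sample_id: str, gene: GeneInterval, size: int, max_span: int,
    vaf_jitter: float, chrom_arr: np.ndarray, rng: np.random.Generator,
    used: set[tuple[str, int]],
) -> list[MutationRecord]:
    """Place ``size`` mutations at C/G sites within ``max_span`` of the gene
    start, successive gaps well under the 2 kb detector threshold."""
    window_start = gene.start
    window = chrom_arr[window_start - 1 : window_start - 1 + max_span]
    cg = np.flatnonzero((window == ord("C")) | (window == ord("G")))
    if len(cg) < size:
        raise ValueError(f"not enough C/G sites in {max_span} bp window")
    # evenly spread targets across ~90% of the allowed span, snapped to C/G sites
    targets = np.linspace(0, int(0.9 * max_span), size)
    chosen = []
    for t in targets:
        i = int(np.argmin(np.abs(cg - t)))
        while cg[i] in chosen and i + 1 < len(cg):
            i += 1
        chosen.append(int(cg[i]))
    chosen = sorted(set(chosen))
    if len(chosen) < size or chosen[-1] - chosen[0] > max_span:
        raise ValueError(
            f"could not place {size} mutations within {max_span} bp"
        )
    base_vaf = float(rng.uniform(0.40, 0.50))
    records = []
    for off in chosen:
        pos = window_start + off
        ref = chr(window[off])
        klass = "C>T" if rng.random() < 0.85 else _draw_class(
            {"C>A": 0.5, "C>G": 0.5}, rng)
        vaf = base_vaf + float(rng.uniform(-vaf_jitter, vaf_jitter))
        used.add((gene.chrom, pos))
        records.append(_snv_record(sample_id, gene.chrom, pos, ref, klass, rng, vaf=vaf))
    return records


def draw_burdens(
    samples: Sequence[SampleMetadata],
    model: BurdenModel,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Negative-binomial burden draw per sample (mean from drivers and age)."""
    burdens = {}
    for m in samples:
        age = m.age if m.age is not None else 12.0
        mu = model.mean(count_drivers(m), age)
        k = model.dispersion
        burdens[m.sample_id] = int(rng.negative_binomial(k, k / (k + mu)))
    return burdens


# ---------------------------------------------------------------------------
# indels and copy number

def _implant_indels(
    config: CohortConfig,
    genome: dict[str, np.ndarray],
    genes: Sequence[GeneInterval],
    sample_ids: list[str],
    hyper_id: str,
    rng: np.random.Generator,
) -> tuple[list[MutationRecord], list[dict]]:
    """13 short indels adjacent to implanted tandem repeats, intergenic.

    Four go to the hypermutant sample, the rest to random samples.  Each
    site gets a (1-4 bp motif) x 5 repeat written into the genome; the
    indel inserts or deletes one motif unit, VCF-anchored on the base
    before the repeat.
    """
    assignments = [hyper_id] * min(4, config.indel_total)
    others = [s for s in sample_ids if s != hyper_id]
    while len(assignments) < config.indel_total:
        assignments.append(others[int(rng.integers(0, len(others)))])
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_spans.setdefault(g.chrom, []).append((g.start, g.end))
    records, truth = [], []
    chroms = list(genome)
    # eight single-base indels, five of 2-4 bp (all under 5 bp)
    motif_lengths = ([1] * 8 + [2, 2, 3, 3, 4]) * (1 + config.indel_total // 13)
    rng.shuffle(assignments)
    for sample_id, mlen in zip(assignments, motif_lengths[: config.indel_total]):
        for _ in range(500):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            arr = genome[chrom]
            pos = int(rng.integers(50_000, len(arr) - 50_000))
            if any(s - 100 <= pos <= e + 100 for s, e in gene_spans.get(chrom, [])):
                continue
            break
        else:
            raise RuntimeError("no intergenic site found for indel")
        motif = "".join(chr(c) for c in _BASE_BYTES[rng.integers(0, 4, size=mlen)])
        repeat = motif * 5
        arr[pos : pos + len(repeat)] = np.frombuffer(repeat.encode(), dtype=np.uint8)
        anchor = chr(arr[pos - 1])
        is_del = rng.random() < 0.6
        if is_del:
            ref, alt = anchor + motif, anchor
            vclass = VariantClass.DEL
        else:
            ref, alt = anchor, anchor + motif
            vclass = VariantClass.INS
        t_depth, t_alt, n_depth, n_alt = _depths(rng)
        records.append(
            MutationRecord(
                sample_id=sample_id, chrom=chrom, pos=pos,  # 1-based anchor base
                ref_allele=ref, alt_allele=alt, variant_class=vclass,
                tumor_depth=t_depth, tumor_alt_count=t_alt,
                normal_depth=n_depth, normal_alt_count=n_alt,
            )
        )
        truth.append(
            {"sample_id": sample_id, "chrom": chrom, "pos": pos,
             "motif": motif, "class": vclass.value}
        )
    return records, truth


def _generate_segments(
    config: CohortConfig,
    genome: dict[str, np.ndarray],
    samples: Sequence[SampleMetadata],
    carriers: list[str],
    rng: np.random.Generator,
) -> list[CopyNumberSegment]:
    """Amplicon segments in the carriers plus background amps/deletions.

    Background segments never touch the amplicon window, so the amplicon
    genes' amplification recurrence equals the implanted carrier count.
    """
    amp = config.amplicon
    avoid = (amp.chrom, amp.start - 60_000, amp.end + 60_000)
    chroms = list(genome)
    segments = []
    for m in samples:
        if m.sample_id in carriers:
            segments.append(
                CopyNumberSegment(m.sample_id, amp.chrom, amp.start, amp.end,
                                  amp.copy_number)
            )
        amp_cn_lo = 5 if m.ploidy < 2.7 else 8
        n_amp = int(rng.poisson(2.0))
        n_del = int(rng.poisson(3.0 if m.mitf == config.deletion_excess_mitf else 0.5))
        n_sub = int(rng.poisson(1.0))  # sub-threshold gains, never called
        for n_seg, cn_fn in (
            (n_amp, lambda: int(rng.integers(amp_cn_lo, amp_cn_lo + 6))),
            (n_del, lambda: 0),
            (n_sub, lambda: 3),
        ):
            for _ in range(n_seg):
                for _ in range(100):
                    chrom = chroms[int(rng.integers(0, len(chroms)))]
                    # segments stay small relative to the desk-scale genome,
                    # preserving the real data's segment-to-genome ratio
                    length = int(rng.integers(20_000, 300_000))
                    max_start = len(genome[chrom]) - length
                    if max_start < 1:
                        continue
                    start = int(rng.integers(1, max_start + 1))
                    end = start + length - 1
                    if chrom == avoid[0] and start <= avoid[2] and end >= avoid[1]:
                        continue
                    segments.append(
                        CopyNumberSegment(m.sample_id, chrom, start, end, cn_fn())
                    )
                    break
    return segments


def _default_gene_sets(
    genes: Sequence[GeneInterval], rng: np.random.Generator
) -> list[GeneSet]:
    pool = [g.gene_id for g in genes]
    sets = [
        GeneSet("pka_signaling", "protein kinase A signaling (amplicon resident)",
                set(AMPLICON_GENES) | set(pool[:5])),
        GeneSet("melanogenesis", "pigment synthesis", set(pool[5:25])),
        GeneSet("p53_signaling", "p53 pathway", set(pool[25:45])),
        GeneSet("mapk_signaling", "MAPK cascade", set(pool[45:75])),
        GeneSet("apoptosis", "programmed cell death", set(pool[75:95])),
        GeneSet("vegf_signaling", "VEGF / angiogenesis", set(pool[95:110])),
        GeneSet("cell_cycle", "cell cycle", set(pool[110:135])),
    ]
    for i in range(8, 16):
        members = rng.choice(pool, size=int(rng.integers(10, 40)), replace=False)
        sets.append(GeneSet(f"random_set_{i:02d}", "random background set",
                            set(members.tolist())))
    return sets


# ---------------------------------------------------------------------------
# the generator

def generate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate the full synthetic study bundle (seed-deterministic)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    genome_arrays, genes = _build_genome(config, rng)

    # --- samples -----------------------------------------------------------
    samples: list[SampleMetadata] = []
    i = 0
    for row in config.genotype_table:
        for _ in range(row.count):
            i += 1
            samples.append(
                SampleMetadata(
                    sample_id=f"ZD{i:04d}a",
                    oncogene=row.oncogene,
                    p53=row.p53,
                    mitf=row.mitf,
                    mitf_rescue=row.mitf_rescue,
                    extra_alleles=list(row.extra_alleles),
                    extra_transgenes=list(row.extra_transgenes),
                    age=round(float(rng.uniform(*config.age_range)), 1),
                    ploidy=2.0,
                )
            )
    # a minority of tumors are near-triploid or higher
    high_ploidy = rng.choice(len(samples), size=max(1, len(samples) // 5), replace=False)
    for j in range(len(samples)):
        samples[j].ploidy = round(
            float(rng.uniform(2.8, 3.6)) if j in set(high_ploidy.tolist())
            else float(rng.uniform(1.9, 2.2)), 2,
        )

    # special-sample identities: the single-driver BRAF fish is the
    # C:G-exclusive hypermutant; the first BRAF;p53het fish carries kataegis
    hyper_id = next(
        m.sample_id for m in samples
        if m.oncogene == "BRAF" and count_drivers(m) == 1
    )
    kataegis_id = next(
        m.sample_id for m in samples
        if m.oncogene == "BRAF" and m.p53 == "het" and m.mitf == "wt"
        and not m.extra_alleles
    )

    # --- indels first (they implant repeats into the genome) ---------------
    sample_ids = [m.sample_id for m in samples]
    indel_records, indel_truth = _implant_indels(
        config, genome_arrays, genes, sample_ids, hyper_id, rng
    )

    genome = {c: a.tobytes().decode("ascii") for c, a in genome_arrays.items()}
    coding = _CodingIndex(genome_arrays, genes)

    # --- substitutions ------------------------------------------------------
    burdens = draw_burdens(
        [m for m in samples if m.sample_id not in (hyper_id, kataegis_id)],
        config.burden_model, rng,
    )
    mutations: list[MutationRecord] = []
    special_seed = int(rng.integers(0, 2**31 - 1))
    hyper_records = generate_special_sample(
        config.hypermutant, hyper_id, genome_arrays, genes, seed=special_seed
    )
    kataegis_records = generate_special_sample(
        config.kataegis, kataegis_id, genome_arrays, genes, seed=special_seed + 1
    )
    mutations.extend(hyper_records)
    mutations.extend(kataegis_records)
    used: set[tuple[str, int]] = {(r.chrom, r.pos) for r in mutations}
    for m in samples:
        if m.sample_id in (hyper_id, kataegis_id):
            continue
        mutations.extend(
            _generate_background_snvs(
                m.sample_id, burdens[m.sample_id], config.spectrum_mixture,
                coding, rng, used,
            )
        )
    burdens[hyper_id] = len(hyper_records)
    burdens[kataegis_id] = len(kataegis_records)
    mutations.extend(indel_records)
    mutations.sort(key=lambda r: (r.sample_id, r.chrom, r.pos))

    # --- copy number --------------------------------------------------------
    rescue_ids = [m.sample_id for m in samples if m.mitf_rescue]
    carrier_idx = rng.choice(len(rescue_ids), size=config.amplicon.n_carriers,
                             replace=False)
    carriers = sorted(rescue_ids[int(j)] for j in carrier_idx)
    segments = _generate_segments(config, genome_arrays, samples, carriers, rng)

    gene_sets = _default_gene_sets(genes, rng)

    # kataegis_records lists cluster members first (cluster by cluster, in
    # position order), then the dispersed background
    clusters_truth = []
    offset = 0
    for size, span in config.kataegis.clusters:
        members = kataegis_records[offset : offset + size]
        offset += size
        clusters_truth.append(
            {
                "size": size,
                "max_span": span,
                "chrom": members[0].chrom,
                "positions": [r.pos for r in members],
            }
        )
    truth = {
        "seed": config.seed,
        "n_samples": config.n_samples,
        "hypermutant_sample": hyper_id,
        "hypermutant_n": config.hypermutant.n,
        "kataegis_sample": kataegis_id,
        "kataegis_clusters": clusters_truth,
        "kataegis_positions": sorted(
            [r.chrom, r.pos] for r in kataegis_records
        ),
        "amplicon": {
            "chrom": config.amplicon.chrom,
            "start": config.amplicon.start,
            "end": config.amplicon.end,
            "copy_number": config.amplicon.copy_number,
            "carriers": carriers,
            "genes": list(AMPLICON_GENES),
        },
        "burdens": burdens,
        "indels": indel_truth,
        "spectrum_mixture": config.spectrum_mixture,
        "burden_model": {
            "intercept": config.burden_model.intercept,
            "driver_coefficient": config.burden_model.driver_coefficient,
            "age_coefficient": config.burden_model.age_coefficient,
            "dispersion": config.burden_model.dispersion,
        },
    }
    return CohortBundle(
        genome=genome,
        genes=genes,
        samples=samples,
        mutations=mutations,
        segments=segments,
        gene_sets=gene_sets,
        truth=truth,
    )
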