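"""Mutation spectra, strand bias, and kataegis-style cluster detection.

Spectra use the six pyrimidine-collapsed substitution classes (C>A, C>G,
C>T, T>A, T>C, T>G): a purine-reference mutation is folded onto its
reverse complement, so G>A counts as C>T.  When a mutation lies inside a
gene, the class is attributed to the transcribed or untranscribed strand by
comparing the strand carrying the reference pyrimidine with the gene
strand; intergenic mutations stay unassigned and are excluded from the
strand-bias test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .annotate import GeneIndex
from .types import GeneInterval, MutationRecord

__all__ = [
    "SPECTRUM_CLASSES",
    "SpectrumProfile",
    "MutationCluster",
    "fold_class",
    "mutation_spectrum",
    "strand_bias_test",
    "cg_only_fraction",
    "detect_clusters",
    "intermutation_distances",
]

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
STRANDS = ("transcribed", "untranscribed", "unassigned")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def fold_class(ref: str, alt: str) -> str:
    """Collapse a substitution onto its pyrimidine-reference class."""
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class SpectrumProfile:
    """Six-class mutation spectrum, optionally split by transcription strand."""

    counts: pd.DataFrame  # index: SPECTRUM_CLASSES, columns: STRANDS
    n_non_snv_ignored: int = 0

    @property
    def class_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())

    @property
    def fractions(self) -> pd.Series | None:
        """Class fractions over all SNVs; None for an empty profile."""
        if self.total == 0:
            return None
        return self.class_totals / self.total


def mutation_spectrum(
    catalog: Iterable[MutationRecord],
    gene_models: GeneIndex | Sequence[GeneInterval] | None = None,
) -> SpectrumProfile:
    """Pyrimidine-folded 6-class spectrum with strand attribution.

    Non-SNV records are ignored (their count is reported on the profile).
    The mutated pyrimidine lies on the gene's coding (untranscribed) strand
    when the reference pyrimidine strand matches the gene strand, else on
    the template (transcribed) strand.
    """
    index = None
    if gene_models is not None:
        index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    counts = pd.DataFrame(0, index=list(SPECTRUM_CLASSES), columns=list(STRANDS))
    ignored = 0
    for r in catalog:
        if not r.is_snv:
            ignored += 1
            continue
        cls = fold_class(r.ref_allele, r.alt_allele)
        strand = "unassigned"
        if index is not None:
            genes = index.overlapping(r.chrom, r.pos, r.pos)
            if genes:
                pyrimidine_strand = "+" if r.ref_allele in "CT" else "-"
                strand = (
                    "untranscribed"
                    if pyrimidine_strand == genes[0].strand
                    else "transcribed"
                )
        counts.loc[cls, strand] += 1
    return SpectrumProfile(counts=counts, n_non_snv_ignored=ignored)


def strand_bias_test(profile: SpectrumProfile) -> dict[str, float | None]:
    """Two-sided exact binomial test of strand symmetry per class.

    For each class, the transcribed-strand count is tested against p0 = 0.5
    of the strand-assigned total.  Classes with no strand-assigned
    mutations get None.
    """
    pvals: dict[str, float | None] = {}
    for cls in SPECTRUM_CLASSES:
        t = int(profile.counts.loc[cls, "transcribed"])
        ut = int(profile.counts.loc[cls, "untranscribed"])
        n = t + ut
        pvals[cls] = None if n == 0 else stats.binomtest(t, n, 0.5).pvalue
    return pvals


def cg_only_fraction(catalog: Iterable[MutationRecord]) -> float | None:
    """Fraction of SNVs whose reference base is C or G (None when no SNVs)."""
    refs = [r.ref_allele for r in catalog if r.is_snv]
    if not refs:
        return None
    return sum(1 for b in refs if b in "CG") / len(refs)


@dataclass
class MutationCluster:
    """A run of closely spaced substitutions in one sample."""

    sample_id: str
    chrom: str
    members: list[MutationRecord] = field(repr=False, default_factory=list)
    majority_class: str = ""
    vaf_spread: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def start(self) -> int:
        return self.members[0].pos

    @property
    def end(self) -> int:
        return self.members[-1].pos

    @property
    def span(self) -> int:
        return self.end - self.start


def detect_clusters(
    catalog: Iterable[MutationRecord],
    min_size: int = 5,
    max_intermutation_distance: int = 2_000,
) -> list[MutationCluster]:
    """Kataegis-style detector: maximal runs of consecutive SNVs.

    Per sample and chromosome, mutations are sorted by position and greedily
    grouped into maximal runs whose successive gaps are all <=
    ``max_intermutation_distance``; runs of at least ``min_size`` members
    are reported, annotated with the majority folded class and the VAF
    spread (max - min tumor VAF).
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2 (a single mutation is not a cluster)")
    by_group: dict[tuple[str, str], list[MutationRecord]] = {}
    for r in catalog:
        if r.is_snv:
            by_group.setdefault((r.sample_id, r.chrom), []).append(r)
    clusters = []
    for (sample_id, chrom), records in sorted(by_group.items()):
        records.sort(key=lambda r: r.pos)
        run: list[MutationRecord] = []
        for r in records:
            if run and r.pos - run[-1].pos > max_intermutation_distance:
                if len(run) >= min_size:
                    clusters.append(_make_cluster(sample_id, chrom, run))
                run = []
            run.append(r)
        if len(run) >= min_size:
            clusters.append(_make_cluster(sample_id, chrom, run))
    return clusters


def _make_cluster(sample_id: str, chrom: str, run: list[MutationRecord]) -> MutationCluster:
    classes = pd.Series([fold_class(r.ref_allele, r.alt_allele) for r in run])
    vafs = [r.tumor_vaf for r in run if r.tumor_vaf is not None]
    return MutationCluster(
        sample_id=sample_id,
        chrom=chrom,
        members=list(run),
        majority_class=classes.mode().iloc[0],
        vaf_spread=(max(vafs) - min(vafs)) if vafs else None,
    )


def intermutation_distances(catalog: Iterable[MutationRecord]) -> pd.DataFrame:
    """Rainfall table: per-sample, per-chromosome distance to the previous SNV.

    The first mutation on each chromosome has a null (NaN) distance.
    Columns: sample_id, chrom, pos, distance, klass.
    """
    rows = []
    by_group: dict[tuple[str, str], list[MutationRecord]] = {}
    for r in catalog:
        if r.is_snv:
            by_group.setdefault((r.sample_id, r.chrom), []).append(r)
    for (sample_id, chrom), records in sorted(by_group.items()):
        records.sort(key=lambda r: r.pos)
        prev = None
        for r in records:
            rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": chrom,
                    "pos": r.pos,
                    "distance": None if prev is None else r.pos - prev,
                    "klass": fold_class(r.ref_allele, r.alt_allele),
                }
            )
            prev = r.pos
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "distance", "klass"])
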