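"""Readers and writers for the formats the pipeline touches.

Mutation catalogs travel as VCF 4.2 or as a fixed tab-delimited dialect
(columns: sample_id, chrom, pos, ref, alt, class, t_depth, t_alt, n_depth,
n_alt; '#' starts a comment).  Copy-number segments are SEG-like TSV
(sample, chrom, start, end, copy_number).  Gene models are GFF3, gene sets
GMT, the sample sheet a TSV with one row per fish.  All file coordinates
are 1-based inclusive.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import pysam

from .types import (
    CopyNumberSegment,
    GeneInterval,
    GeneSet,
    MutationRecord,
    SampleMetadata,
    VariantClass,
)

__all__ = [
    "read_mutations",
    "write_mutations",
    "read_segments",
    "write_segments",
    "read_gene_models",
    "write_gene_models",
    "read_gmt",
    "write_gmt",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_fasta",
    "write_fasta",
]

_MUTATION_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "class",
    "t_depth",
    "t_alt",
    "n_depth",
    "n_alt",
)


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path: str | os.PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _infer_class(ref: str, alt: str) -> VariantClass:
    if len(ref) == len(alt) == 1:
        return VariantClass.SNV
    return VariantClass.INS if len(alt) > len(ref) else VariantClass.DEL


def read_mutations(path: str | os.PathLike, format: str = "tsv") -> list[MutationRecord]:
    """Read a mutation catalog from ``path`` (``format`` 'tsv' or 'vcf').

    VCF input expects samples named TUMOR and NORMAL with per-sample AD
    (ref, alt allele depths); total depth is the AD sum.
    """
    if format == "tsv":
        return _read_mutations_tsv(path)
    if format == "vcf":
        return _read_mutations_vcf(path)
    raise ValueError(f"unknown mutation format {format!r}")


def _read_mutations_tsv(path: str | os.PathLike) -> list[MutationRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_MUTATION_COLUMNS):
                raise ParseError(
                    path, lineno,
                    f"expected {len(_MUTATION_COLUMNS)} fields, got {len(fields)}",
                )
            try:
                records.append(
                    MutationRecord(
                        sample_id=fields[0],
                        chrom=fields[1],
                        pos=int(fields[2]),
                        ref_allele=fields[3],
                        alt_allele=fields[4],
                        variant_class=VariantClass(fields[5]),
                        tumor_depth=int(fields[6]),
                        tumor_alt_count=int(fields[7]),
                        normal_depth=int(fields[8]),
                        normal_alt_count=int(fields[9]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return records


def write_mutations(
    records: Iterable[MutationRecord], path: str | os.PathLike, format: str = "tsv"
) -> None:
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(_MUTATION_COLUMNS) + "\n")
            for r in records:
                fh.write(
                    "\t".join(
                        str(v)
                        for v in (
                            r.sample_id, r.chrom, r.pos, r.ref_allele, r.alt_allele,
                            r.variant_class.value, r.tumor_depth, r.tumor_alt_count,
                            r.normal_depth, r.normal_alt_count,
                        )
                    )
                    + "\n"
                )
    elif format == "vcf":
        _write_mutations_vcf(records, path)
    else:
        raise ValueError(f"unknown mutation format {format!r}")


def _read_mutations_vcf(path: str | os.PathLike) -> list[MutationRecord]:
    records = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            if rec.pos < 1:
                raise ValueError(f"coordinate {rec.pos} < 1 in {path}")
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                continue
            t_ad = rec.samples["TUMOR"]["AD"]
            n_ad = rec.samples["NORMAL"]["AD"]
            sample_id = rec.info.get("SID", rec.id or "unknown")
            records.append(
                MutationRecord(
                    sample_id=str(sample_id),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    variant_class=_infer_class(rec.ref, alt),
                    tumor_depth=int(sum(t_ad)),
                    tumor_alt_count=int(t_ad[1]),
                    normal_depth=int(sum(n_ad)),
                    normal_alt_count=int(n_ad[1]),
                )
            )
    return records


def _write_mutations_vcf(records: Iterable[MutationRecord], path: str | os.PathLike) -> None:
    records = list(records)
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(r.chrom for r in records):
        header.contigs.add(chrom)
    header.info.add("SID", 1, "String", "Originating sample identifier")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total depth")
    header.add_sample("TUMOR")
    header.add_sample("NORMAL")
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos - 1 + len(r.ref_allele),
                alleles=(r.ref_allele, r.alt_allele),
            )
            rec.info["SID"] = r.sample_id
            rec.samples["TUMOR"]["AD"] = (
                r.tumor_depth - r.tumor_alt_count, r.tumor_alt_count)
            rec.samples["TUMOR"]["DP"] = r.tumor_depth
            rec.samples["NORMAL"]["AD"] = (
                r.normal_depth - r.normal_alt_count, r.normal_alt_count)
            rec.samples["NORMAL"]["DP"] = r.normal_depth
            vcf.write(rec)


def read_segments(path: str | os.PathLike) -> list[CopyNumberSegment]:
    """Read SEG-like TSV: sample, chrom, start, end, copy_number."""
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(path, lineno, f"expected 5 fields, got {len(fields)}")
            try:
                segments.append(
                    CopyNumberSegment(
                        sample_id=fields[0], chrom=fields[1],
                        start=int(fields[2]), end=int(fields[3]),
                        copy_number=int(fields[4]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return segments


def write_segments(segments: Iterable[CopyNumberSegment], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#sample_id\tchrom\tstart\tend\tcopy_number\n")
        for s in segments:
            fh.write(f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.copy_number}\n")


def read_gene_models(path: str | os.PathLike) -> list[GeneInterval]:
    """Read gene models from GFF3 (gene/exon/CDS features)."""
    import gffutils

    db = gffutils.create_db(
        os.fspath(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = [(e.start, e.end) for e in db.children(g, featuretype="exon")]
        cds = [(c.start, c.end) for c in db.children(g, featuretype="CDS")]
        cds_start = min(s for s, _ in cds) if cds else None
        cds_end = max(e for _, e in cds) if cds else None
        genes.append(
            GeneInterval(
                gene_id=g.id, chrom=g.seqid, start=g.start, end=g.end,
                strand=g.strand, exons=exons, cds_start=cds_start, cds_end=cds_end,
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tzmel\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tzmel\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            for i, (s, e) in enumerate(g.coding_exon_pieces, start=1):
                fh.write(
                    f"{g.chrom}\tzmel\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    path, lineno, "GMT line needs set_id, description, >=1 gene")
            try:
                sets.append(GeneSet(fields[0], fields[1], set(fields[2:])))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description] + sorted(s.gene_ids)) + "\n")


_SHEET_COLUMNS = (
    "sample_id", "oncogene", "p53", "mitf", "mitf_rescue",
    "extra_alleles", "extra_transgenes", "age_months", "ploidy",
)


def read_sample_sheet(path: str | os.PathLike) -> list[SampleMetadata]:
    """Read the cohort sample sheet (TSV, header row, '.' for missing age)."""
    samples = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header) != _SHEET_COLUMNS:
                    raise ParseError(
                        path, lineno,
                        f"unexpected sample sheet columns {header}")
                continue
            row = dict(zip(header, fields))
            try:
                if row["mitf_rescue"] not in ("0", "1"):
                    raise ValueError(f"mitf_rescue must be 0/1, got {row['mitf_rescue']!r}")
                samples.append(
                    SampleMetadata(
                        sample_id=row["sample_id"],
                        oncogene=row["oncogene"],
                        p53=row["p53"],
                        mitf=row["mitf"],
                        mitf_rescue=row["mitf_rescue"] == "1",
                        extra_alleles=[a for a in row["extra_alleles"].split(",") if a and a != "."],
                        extra_transgenes=[t for t in row["extra_transgenes"].split(",") if t and t != "."],
                        age=None if row["age_months"] == "." else float(row["age_months"]),
                        ploidy=float(row["ploidy"]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return samples


def write_sample_sheet(samples: Iterable[SampleMetadata], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SHEET_COLUMNS) + "\n")
        for m in samples:
            fh.write(
                "\t".join([
                    m.sample_id, m.oncogene, m.p53, m.mitf,
                    "1" if m.mitf_rescue else "0",
                    ",".join(m.extra_alleles) or ".",
                    ",".join(m.extra_transgenes) or ".",
                    "." if m.age is None else f"{m.age:g}",
                    f"{m.ploidy:g}",
                ]) + "\n"
            )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into {name: sequence} (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
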