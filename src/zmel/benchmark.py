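"""Somatic-caller benchmarking by tumor/normal genome simulation.

The harness mirrors a caller-validation design for a genome with very high
germline polymorphism: a 'normal' genome is derived from a reference by
scattering germline SNPs at a chosen density (0 to 0.5 SNPs/base), a
'tumor' genome adds a fixed number of somatic substitutions (default
2,000), error-free 75 bp reads are simulated from both, and tumor reads
are mixed with normal reads at a chosen tumor fraction to emulate normal
contamination.  A naive tumor/normal pileup caller is scored against the
implanted somatic truth with sensitivity and precision.

Reads carry their true origin coordinates in their names and no aligner is
run: with a zero sequencing-error rate, alignment adds no information at
this scale, so the harness isolates the statistical detection step (allele
counting under contamination and germline confusion).
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "SimulatedGenomePair",
    "MixSpec",
    "CallScore",
    "simulate_genome_pair",
    "simulate_reads",
    "mix_contamination",
    "write_fastq",
    "read_fastq",
    "Pileup",
    "build_pileup",
    "naive_somatic_caller",
    "score_calls",
    "run_benchmark_grid",
]

logger = logging.getLogger(__name__)

Variant = tuple[str, int, str, str]  # (chrom, 1-based pos, ref, alt)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass
class SimulatedGenomePair:
    """A matched normal/tumor genome with known germline and somatic truth."""

    normal: dict[str, str]
    tumor: dict[str, str]
    germline_truth: set[Variant]
    somatic_truth: set[Variant]
    snp_density: float
    n_somatic: int

    def __post_init__(self) -> None:
        positions_g = {(c, p) for c, p, _, _ in self.germline_truth}
        positions_s = {(c, p) for c, p, _, _ in self.somatic_truth}
        if positions_g & positions_s:
            raise ValueError("somatic and germline truth sets overlap")
        if len(self.somatic_truth) != self.n_somatic:
            raise ValueError(
                f"|somatic_truth| = {len(self.somatic_truth)} != n_somatic = {self.n_somatic}"
            )


@dataclass
class MixSpec:
    """Read-simulation and contamination-mixing parameters.

    ``total_reads`` is the number of reads in the mixed tumor sample (see
    ``reads_are_pairs`` for the pair interpretation); ``tumor_fraction``
    the fraction of them drawn from the tumor genome.  Error and indel
    rates are fixed at zero: reads reproduce their source bases exactly.
    """

    total_reads: int
    tumor_fraction: float
    read_length: int = 75
    paired: bool = True
    error_rate: float = 0.0
    indel_rate: float = 0.0
    reads_are_pairs: bool = False  # interpret total_reads as pair count

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError(f"tumor_fraction must be in [0,1], got {self.tumor_fraction}")
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")
        if self.error_rate != 0.0 or self.indel_rate != 0.0:
            raise ValueError("the harness simulates error-free reads only")

    @property
    def n_reads(self) -> int:
        return self.total_reads * 2 if self.reads_are_pairs else self.total_reads


@dataclass
class CallScore:
    """Sensitivity/precision of a call set against a truth set."""

    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def sensitivity(self) -> float | None:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else None

    @property
    def precision(self) -> float | None:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else None


def simulate_genome_pair(
    reference: Mapping[str, str],
    snp_density: float,
    n_somatic: int = 2_000,
    seed: int = 0,
) -> SimulatedGenomePair:
    """Implant germline SNPs then somatic substitutions on a reference.

    Germline SNP count per chromosome is Binomial(length, density) with
    positions drawn without replacement; the 'normal' genome carries them
    homozygously.  The tumor genome is the normal genome plus exactly
    ``n_somatic`` additional substitutions at positions free of germline
    variants, so tumor and normal differ at exactly those sites.
    """
    if snp_density < 0:
        raise ValueError("snp_density must be >= 0")
    if not reference:
        raise ValueError("reference is empty")
    rng = np.random.default_rng(seed)
    normal: dict[str, str] = {}
    tumor_arrays: dict[str, np.ndarray] = {}
    germline: set[Variant] = set()
    germline_positions: dict[str, np.ndarray] = {}

    for chrom, seq in reference.items():
        arr = _seq_to_array(seq.upper())
        n_g = rng.binomial(len(arr), min(snp_density, 1.0)) if snp_density > 0 else 0
        pos0 = rng.choice(len(arr), size=n_g, replace=False) if n_g else np.array([], dtype=int)
        for p in pos0:
            ref_base = chr(arr[p])
            alt_base = chr(rng.choice(_BASES[_BASES != arr[p]]))
            arr[p] = ord(alt_base)
            germline.add((chrom, int(p) + 1, ref_base, alt_base))
        normal[chrom] = _array_to_seq(arr)
        tumor_arrays[chrom] = arr.copy()
        germline_positions[chrom] = np.sort(pos0)

    lengths = {c: len(s) for c, s in reference.items()}
    genome_len = sum(lengths.values())
    n_free = genome_len - sum(len(p) for p in germline_positions.values())
    if n_somatic > n_free:
        raise ValueError(
            f"n_somatic = {n_somatic} exceeds {n_free} germline-free positions"
        )
    chroms = list(reference)
    offsets = np.cumsum([0] + [lengths[c] for c in chroms])
    somatic: set[Variant] = set()
    taken: set[tuple[str, int]] = {(c, p) for c, p, _, _ in germline}
    while len(somatic) < n_somatic:
        draw = rng.integers(0, genome_len, size=n_somatic - len(somatic))
        for g in draw:
            ci = int(np.searchsorted(offsets, g, side="right")) - 1
            chrom, p0 = chroms[ci], int(g - offsets[ci])
            key = (chrom, p0 + 1)
            if key in taken:
                continue
            taken.add(key)
            arr = tumor_arrays[chrom]
            ref_base = chr(arr[p0])
            alt_base = chr(rng.choice(_BASES[_BASES != arr[p0]]))
            arr[p0] = ord(alt_base)
            somatic.add((chrom, p0 + 1, ref_base, alt_base))
            if len(somatic) == n_somatic:
                break
    tumor = {c: _array_to_seq(a) for c, a in tumor_arrays.items()}
    return SimulatedGenomePair(
        normal=normal,
        tumor=tumor,
        germline_truth=germline,
        somatic_truth=somatic,
        snp_density=snp_density,
        n_somatic=n_somatic,
    )


def simulate_reads(
    sequences: Mapping[str, str],
    spec: MixSpec,
    seed: int = 0,
    origin_label: str = "hap",
) -> list[tuple[str, str]]:
    """Error-free reads with origin coordinates encoded in their names.

    Returns (name, sequence) tuples; names are
    ``<label>|<chrom>|<1-based start>|<serial>``.  Paired mode draws
    fragments (insert ~ 300 bp) and emits both mates as forward-strand
    slices at their own origins, so every read reproduces its source bases
    exactly.  Read start positions are uniform per chromosome, chromosomes
    chosen proportionally to length.
    """
    for chrom, seq in sequences.items():
        if len(seq) < spec.read_length:
            raise ValueError(
                f"chromosome {chrom} shorter ({len(seq)}) than read length"
            )
    rng = np.random.default_rng(seed)
    chroms = list(sequences)
    lengths = np.array([len(sequences[c]) for c in chroms], dtype=float)
    n_reads = spec.n_reads
    reads: list[tuple[str, str]] = []
    if n_reads == 0:
        return reads
    insert = 300
    if spec.paired:
        n_frags = (n_reads + 1) // 2
        frag_chroms = rng.choice(len(chroms), size=n_frags, p=lengths / lengths.sum())
        serial = 0
        for ci in frag_chroms:
            chrom = chroms[ci]
            seq = sequences[chrom]
            span = min(insert, len(seq))
            start0 = int(rng.integers(0, len(seq) - span + 1))
            mate2_start0 = start0 + span - spec.read_length
            for s0 in (start0, max(mate2_start0, 0)):
                if len(reads) >= n_reads:
                    break
                reads.append(
                    (
                        f"{origin_label}|{chrom}|{s0 + 1}|{serial}",
                        seq[s0 : s0 + spec.read_length],
                    )
                )
                serial += 1
    else:
        read_chroms = rng.choice(len(chroms), size=n_reads, p=lengths / lengths.sum())
        for serial, ci in enumerate(read_chroms):
            chrom = chroms[ci]
            seq = sequences[chrom]
            s0 = int(rng.integers(0, len(seq) - spec.read_length + 1))
            reads.append(
                (f"{origin_label}|{chrom}|{s0 + 1}|{serial}", seq[s0 : s0 + spec.read_length])
            )
    return reads


def mix_contamination(
    normal_reads: Sequence[tuple[str, str]],
    tumor_reads: Sequence[tuple[str, str]],
    spec: MixSpec,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Mix normal- and tumor-origin reads at the requested tumor fraction.

    Takes exactly ``round(total * (1 - f))`` normal and ``round(total * f)``
    tumor reads (first-come), shuffled deterministically by ``seed``.
    """
    n_total = spec.n_reads
    n_tumor = round(n_total * spec.tumor_fraction)
    n_normal = n_total - n_tumor
    if len(normal_reads) < n_normal:
        raise ValueError(f"need {n_normal} normal reads, have {len(normal_reads)}")
    if len(tumor_reads) < n_tumor:
        raise ValueError(f"need {n_tumor} tumor reads, have {len(tumor_reads)}")
    mixed = list(normal_reads[:n_normal]) + list(tumor_reads[:n_tumor])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(mixed))
    return [mixed[i] for i in order]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write reads as FASTQ (gzip when the path ends in .gz); quality 'I'."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    opener = gzip.open if str(path).endswith(".gz") else open
    reads = []
    with opener(path, "rt") as fh:
        while True:
            name = fh.readline().rstrip("\n")
            if not name:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()  # +
            fh.readline()  # qualities
            reads.append((name[1:], seq))
    return reads


class Pileup:
    """Alignment-free pileup of origin-encoded reads against a reference.

    Candidate sites are discovered by comparing every read with the
    reference bases at its encoded origin (reads are error-free substrings
    of their source genome, so mismatches occur exactly at variant sites
    covered by the read).  Depth at any position is computed from the read
    start index.
    """

    def __init__(self, reference: Mapping[str, str], read_length: int):
        self.read_length = read_length
        self._ref = {c: _seq_to_array(s.upper()) for c, s in reference.items()}
        self._starts: dict[str, np.ndarray] = {}
        # per chrom: {pos: {alt_base: count}}
        self.sites: dict[str, dict[int, dict[str, int]]] = {}

    def add_reads(self, reads: Sequence[tuple[str, str]], batch: int = 100_000) -> None:
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for name, seq in reads:
            _, chrom, start1, _ = name.rsplit("|", 3)
            by_chrom.setdefault(chrom, []).append((int(start1) - 1, seq))
        for chrom, items in by_chrom.items():
            ref = self._ref[chrom]
            starts0 = np.array([s for s, _ in items], dtype=np.int64)
            old = self._starts.get(chrom)
            self._starts[chrom] = np.sort(
                starts0 if old is None else np.concatenate([old, starts0])
            )
            chrom_sites = self.sites.setdefault(chrom, {})
            L = self.read_length
            for lo in range(0, len(items), batch):
                chunk = items[lo : lo + batch]
                seq_mat = np.frombuffer(
                    "".join(s for _, s in chunk).encode("ascii"), dtype=np.uint8
                ).reshape(len(chunk), L)
                chunk_starts = starts0[lo : lo + len(chunk)]
                ref_mat = ref[chunk_starts[:, None] + np.arange(L)[None, :]]
                rows, cols = np.nonzero(seq_mat != ref_mat)
                for r, c in zip(rows.tolist(), cols.tolist()):
                    pos = int(chunk_starts[r]) + c + 1
                    alt = chr(seq_mat[r, c])
                    chrom_sites.setdefault(pos, {})
                    chrom_sites[pos][alt] = chrom_sites[pos].get(alt, 0) + 1

    def depth(self, chrom: str, pos: int) -> int:
        """Number of reads covering 1-based ``pos``."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0
        p0 = pos - 1
        lo = np.searchsorted(starts, p0 - self.read_length + 1, side="left")
        hi = np.searchsorted(starts, p0, side="right")
        return int(hi - lo)

    def alt_count(self, chrom: str, pos: int, alt: str) -> int:
        return self.sites.get(chrom, {}).get(pos, {}).get(alt, 0)

    def ref_base(self, chrom: str, pos: int) -> str:
        return chr(self._ref[chrom][pos - 1])


def build_pileup(
    reads: Sequence[tuple[str, str]],
    reference: Mapping[str, str],
    read_length: int = 75,
) -> Pileup:
    pileup = Pileup(reference, read_length)
    pileup.add_reads(reads)
    return pileup


def naive_somatic_caller(
    tumor_pileup: Pileup,
    normal_pileup: Pileup,
    min_alt_reads: int = 3,
    max_normal_vaf: float = 0.05,
) -> set[Variant]:
    """Call somatic substitutions from tumor/normal pileups.

    A site is called when the tumor pileup shows >= ``min_alt_reads``
    reads supporting one alternate base and the normal pileup's VAF for
    that base is <= ``max_normal_vaf`` (zero normal coverage counts as
    VAF 0 — the caller cannot exclude germline status there).
    """
    calls: set[Variant] = set()
    for chrom, chrom_sites in tumor_pileup.sites.items():
        for pos, alt_counts in chrom_sites.items():
            alt, count = max(alt_counts.items(), key=lambda kv: kv[1])
            if count < min_alt_reads:
                continue
            n_depth = normal_pileup.depth(chrom, pos)
            n_alt = normal_pileup.alt_count(chrom, pos, alt)
            n_vaf = n_alt / n_depth if n_depth else 0.0
            if n_vaf <= max_normal_vaf:
                calls.add((chrom, pos, tumor_pileup.ref_base(chrom, pos), alt))
    return calls


def score_calls(calls: set[Variant], somatic_truth: set[Variant]) -> CallScore:
    """Exact set arithmetic on (chrom, pos, ref, alt) tuples."""
    tp = len(calls & somatic_truth)
    score = CallScore(
        true_positives=tp,
        false_positives=len(calls - somatic_truth),
        false_negatives=len(somatic_truth - calls),
    )
    if score.precision is None:
        logger.warning("no calls made: precision undefined (reported as None)")
    return score


def run_benchmark_grid(
    reference: Mapping[str, str],
    densities: Sequence[float] = (0.0, 0.001, 0.01, 0.1, 0.5),
    tumor_fractions: Sequence[float] = (0.30, 0.60, 1.00),
    target_depth: float = 80.0,
    n_somatic: int = 2_000,
    read_length: int = 75,
    min_alt_reads: int = 3,
    max_normal_vaf: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full density x tumor-fraction benchmark design.

    The read count per sample is chosen from the genome size and
    ``target_depth`` (coverage = n_reads * read_length / genome length).
    Somatic variants are implanted heterozygously: tumor-sample reads are
    drawn half from the tumor haplotype and half from the normal genome
    before contamination mixing.  Returns one row per grid cell with
    TP/FP/FN, sensitivity and precision.
    """
    genome_len = sum(len(s) for s in reference.values())
    n_reads = int(round(target_depth * genome_len / read_length))
    rows = []
    for di, density in enumerate(densities):
        pair = simulate_genome_pair(reference, density, n_somatic, seed=seed + 101 * di)
        spec = MixSpec(total_reads=n_reads, tumor_fraction=1.0, read_length=read_length)
        normal_reads = simulate_reads(pair.normal, spec, seed=seed + 7 + 101 * di, origin_label="n")
        # heterozygous somatic: tumor sample is an equal-parts haplotype mix
        half = MixSpec(total_reads=n_reads // 2, tumor_fraction=1.0, read_length=read_length)
        tum_hap = simulate_reads(pair.tumor, half, seed=seed + 11 + 101 * di, origin_label="t")
        norm_hap = simulate_reads(pair.normal, half, seed=seed + 13 + 101 * di, origin_label="t")
        tumor_reads = [x for pairr in zip(tum_hap, norm_hap) for x in pairr]
        contam_source = simulate_reads(
            pair.normal, spec, seed=seed + 17 + 101 * di, origin_label="c"
        )
        normal_pileup = build_pileup(normal_reads, reference, read_length)
        for f in tumor_fractions:
            mix_spec = MixSpec(
                total_reads=n_reads, tumor_fraction=f, read_length=read_length
            )
            mixed = mix_contamination(
                contam_source, tumor_reads, mix_spec, seed=seed + 19 + 101 * di
            )
            tumor_pileup = build_pileup(mixed, reference, read_length)
            calls = naive_somatic_caller(
                tumor_pileup, normal_pileup, min_alt_reads, max_normal_vaf
            )
            score = score_calls(calls, pair.somatic_truth)
            rows.append(
                {
                    "snp_density": density,
                    "tumor_fraction": f,
                    "tp": score.true_positives,
                    "fp": score.false_positives,
                    "fn": score.false_negatives,
                    "sensitivity": score.sensitivity,
                    "precision": score.precision,
                }
            )
    return pd.DataFrame(rows)
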