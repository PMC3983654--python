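"""Tumor/normal simulation, contamination mixing, pileup caller, scoring."""

import numpy as np
import pytest
from scipy import stats

from zmel.benchmark import (
    CallScore,
    MixSpec,
    Pileup,
    build_pileup,
    mix_contamination,
    naive_somatic_caller,
    read_fastq,
    run_benchmark_grid,
    score_calls,
    simulate_genome_pair,
    simulate_reads,
    write_fastq,
)


def _reference(length=50_000, seed=1, name="c1"):
    rng = np.random.default_rng(seed)
    return {name: "".join(rng.choice(list("ACGT"), size=length))}


class TestGenomePair:
    def test_zero_density_means_no_germline(self):
        pair = simulate_genome_pair(_reference(), 0.0, n_somatic=10, seed=2)
        assert pair.germline_truth == set()
        assert pair.normal == {c: s for c, s in _reference().items()}

    def test_tumor_differs_at_exactly_n_somatic_positions(self):
        pair = simulate_genome_pair(_reference(), 0.01, n_somatic=150, seed=3)
        diffs = sum(
            a != b for a, b in zip(pair.normal["c1"], pair.tumor["c1"])
        )
        assert diffs == 150 == len(pair.somatic_truth)

    def test_germline_count_within_three_sigma_of_binomial(self):
        """Density 0.5 on 10 kb: count ~ Binomial(10000, 0.5)."""
        pair = simulate_genome_pair(_reference(10_000), 0.5, n_somatic=5, seed=4)
        n = len(pair.germline_truth)
        mean, sd = 5_000, np.sqrt(10_000 * 0.25)
        assert abs(n - mean) < 3 * sd

    def test_somatic_and_germline_positions_disjoint(self):
        pair = simulate_genome_pair(_reference(5_000), 0.2, n_somatic=500, seed=5)
        g = {(c, p) for c, p, _, _ in pair.germline_truth}
        s = {(c, p) for c, p, _, _ in pair.somatic_truth}
        assert not (g & s)

    def test_too_many_somatic_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_genome_pair(_reference(100), 0.0, n_somatic=200, seed=6)

    def test_truth_records_use_correct_alleles(self):
        pair = simulate_genome_pair(_reference(2_000), 0.1, n_somatic=50, seed=7)
        for chrom, pos, ref, alt in pair.somatic_truth:
            assert pair.normal[chrom][pos - 1] == ref
            assert pair.tumor[chrom][pos - 1] == alt


class TestReads:
    def test_hundred_pairs_give_200_reads_of_75(self):
        seqs = _reference(10_000)
        spec = MixSpec(total_reads=100, tumor_fraction=1.0, reads_are_pairs=True)
        reads = simulate_reads(seqs, spec, seed=1)
        assert len(reads) == 200
        assert all(len(seq) == 75 for _, seq in reads)

    def test_reads_reconstruct_source_exactly(self):
        """Zero error rate: realigning by encoded origins reproduces bases."""
        seqs = _reference(5_000)
        spec = MixSpec(total_reads=500, tumor_fraction=1.0)
        for name, seq in simulate_reads(seqs, spec, seed=2):
            _, chrom, start1, _ = name.rsplit("|", 3)
            start0 = int(start1) - 1
            assert seqs[chrom][start0 : start0 + 75] == seq

    def test_mean_depth_matches_coverage_identity(self):
        length = 20_000
        seqs = _reference(length)
        n_reads = 4_000
        spec = MixSpec(total_reads=n_reads, tumor_fraction=1.0, paired=False)
        reads = simulate_reads(seqs, spec, seed=3)
        covered = np.zeros(length)
        for name, _ in reads:
            start0 = int(name.rsplit("|", 3)[2]) - 1
            covered[start0 : start0 + 75] += 1
        expected = n_reads * 75 / length
        assert covered.mean() == pytest.approx(expected, rel=0.05)

    def test_sequence_shorter_than_read_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            simulate_reads({"c": "ACGT"}, MixSpec(total_reads=2, tumor_fraction=1.0), 1)

    def test_fastq_round_trip(self, tmp_path):
        reads = simulate_reads(
            _reference(2_000), MixSpec(total_reads=50, tumor_fraction=1.0), seed=4)
        path = tmp_path / "r.fastq.gz"
        write_fastq(reads, path)
        assert read_fastq(path) == reads


class TestMixing:
    def _reads(self, n, label):
        return [(f"{label}|c1|{i + 1}|{i}", "A" * 75) for i in range(n)]

    def test_thirty_percent_tumor_split(self):
        spec = MixSpec(total_reads=1_000, tumor_fraction=0.30)
        mixed = mix_contamination(self._reads(800, "n"), self._reads(400, "t"), spec, 1)
        assert len(mixed) == 1_000
        n_tumor = sum(1 for name, _ in mixed if name.startswith("t|"))
        assert n_tumor == 300 and len(mixed) - n_tumor == 700

    def test_table_style_60_percent_split(self):
        """8M total at 60% tumor = 3.2M normal + 4.8M tumor (scaled 1:1000)."""
        spec = MixSpec(total_reads=8_000, tumor_fraction=0.60)
        mixed = mix_contamination(self._reads(6_000, "n"), self._reads(5_000, "t"), spec, 2)
        n_tumor = sum(1 for name, _ in mixed if name.startswith("t|"))
        assert (len(mixed) - n_tumor, n_tumor) == (3_200, 4_800)

    def test_full_tumor_has_no_normal_reads(self):
        spec = MixSpec(total_reads=100, tumor_fraction=1.0)
        mixed = mix_contamination(self._reads(10, "n"), self._reads(100, "t"), spec, 3)
        assert all(name.startswith("t|") for name, _ in mixed)

    def test_insufficient_reads_rejected(self):
        spec = MixSpec(total_reads=100, tumor_fraction=0.5)
        with pytest.raises(ValueError, match="need"):
            mix_contamination(self._reads(10, "n"), self._reads(100, "t"), spec, 4)

    def test_deterministic_shuffle(self):
        spec = MixSpec(total_reads=100, tumor_fraction=0.5)
        a = mix_contamination(self._reads(60, "n"), self._reads(60, "t"), spec, 5)
        b = mix_contamination(self._reads(60, "n"), self._reads(60, "t"), spec, 5)
        assert a == b


class TestScoring:
    def test_perfect_calls(self):
        truth = {("c", 1, "A", "G"), ("c", 5, "T", "C")}
        s = score_calls(truth, truth)
        assert s.sensitivity == 1.0 and s.precision == 1.0

    def test_empty_calls_have_undefined_precision(self):
        s = score_calls(set(), {("c", 1, "A", "G")})
        assert s.sensitivity == 0.0 and s.precision is None

    def test_mixed_counts(self):
        truth = {("c", i, "A", "G") for i in range(10)}
        calls = {("c", i, "A", "G") for i in range(8)} | {
            ("c", 100, "A", "G"), ("c", 101, "A", "G")}
        s = score_calls(calls, truth)
        assert (s.true_positives, s.false_positives, s.false_negatives) == (8, 2, 2)
        assert s.sensitivity == 0.8 and s.precision == 0.8

    def test_tp_plus_fn_conserves_truth_size(self):
        rng = np.random.default_rng(8)
        truth = {("c", int(p), "A", "G") for p in rng.integers(1, 10_000, 50)}
        for frac in (0.0, 0.3, 1.0):
            called = {v for v in truth if rng.random() < frac}
            s = score_calls(called, truth)
            assert s.true_positives + s.false_negatives == len(truth)


def _het_tumor_reads(pair, n_reads, seed):
    """Equal-parts tumor/normal haplotype reads: heterozygous somatic."""
    half = MixSpec(total_reads=n_reads // 2, tumor_fraction=1.0)
    tum = simulate_reads(pair.tumor, half, seed, "t")
    norm = simulate_reads(pair.normal, half, seed + 1, "t")
    return [x for pr in zip(tum, norm) for x in pr]


class TestCaller:
    def test_noise_free_full_tumor_is_perfect(self):
        """100% tumor content, no errors: sensitivity = precision = 1."""
        ref = _reference(60_000, seed=9)
        pair = simulate_genome_pair(ref, 0.01, n_somatic=60, seed=10)
        n_reads = int(50 * 60_000 / 75)  # 50x
        normal = simulate_reads(pair.normal,
                                MixSpec(total_reads=n_reads, tumor_fraction=1.0),
                                seed=11, origin_label="n")
        tumor = _het_tumor_reads(pair, n_reads, seed=12)
        calls = naive_somatic_caller(
            build_pileup(tumor, ref), build_pileup(normal, ref))
        s = score_calls(calls, pair.somatic_truth)
        assert s.sensitivity == 1.0 and s.precision == 1.0

    def test_germline_site_with_high_normal_vaf_not_called(self):
        """A site at normal VAF 0.5 is germline, never somatic."""
        ref = {"c": "A" * 200}
        tumor_reads = [(f"t|c|{1}|{i}", "A" * 49 + "G" + "A" * 25) for i in range(10)]
        normal_reads = [
            (f"n|c|{1}|{i}", ("A" * 49 + "G" + "A" * 25) if i % 2 else "A" * 75)
            for i in range(10)
        ]
        calls = naive_somatic_caller(
            build_pileup(tumor_reads, ref), build_pileup(normal_reads, ref))
        assert calls == set()

    def test_sensitivity_matches_binomial_tail_oracle_at_30_percent(self):
        """At tumor fraction f and het VAF 0.5, each covering read carries the
        alternate allele with probability f/2; the caller's sensitivity at
        min_alt_reads = 3 must match the per-site binomial tail."""
        ref = _reference(80_000, seed=13)
        pair = simulate_genome_pair(ref, 0.0, n_somatic=80, seed=14)
        n_reads = int(40 * 80_000 / 75)  # 40x
        spec = MixSpec(total_reads=n_reads, tumor_fraction=0.30)
        contam = simulate_reads(pair.normal, spec, seed=15, origin_label="c")
        tumor_component = _het_tumor_reads(pair, n_reads, seed=16)
        mixed = mix_contamination(contam, tumor_component, spec, seed=17)
        normal = simulate_reads(pair.normal,
                                MixSpec(total_reads=n_reads, tumor_fraction=1.0),
                                seed=18, origin_label="n")
        tumor_pileup = build_pileup(mixed, ref)
        normal_pileup = build_pileup(normal, ref)
        calls = naive_somatic_caller(tumor_pileup, normal_pileup, min_alt_reads=3)
        s = score_calls(calls, pair.somatic_truth)
        # oracle: per-site P(detect) from the realised tumor-sample depths
        p_alt = 0.30 * 0.5
        probs = [
            stats.binom.sf(2, tumor_pileup.depth(c, p), p_alt)
            for c, p, _, _ in pair.somatic_truth
        ]
        expected = float(np.mean(probs))
        sigma = np.sqrt(sum(q * (1 - q) for q in probs)) / len(probs)
        assert abs(s.sensitivity - expected) < 3 * sigma + 1e-9


class TestGrid:
    def test_grid_shape_and_monotonicity(self):
        """Scaled-down full design: densities x fractions table; sensitivity
        never falls as tumor fraction rises; TP + FN = n_somatic always."""
        ref = _reference(100_000, seed=19)
        grid = run_benchmark_grid(
            ref, densities=(0.0, 0.01), tumor_fractions=(0.30, 0.60, 1.00),
            target_depth=30.0, n_somatic=50, seed=20,
        )
        assert len(grid) == 6
        assert (grid["tp"] + grid["fn"] == 50).all()
        for _, sub in grid.groupby("snp_density"):
            sens = sub.sort_values("tumor_fraction")["sensitivity"].to_numpy()
            assert (np.diff(sens) >= -1e-12).all()

    def test_grid_is_seed_deterministic(self):
        ref = _reference(30_000, seed=21)
        a = run_benchmark_grid(ref, densities=(0.001,), tumor_fractions=(0.6,),
                               target_depth=20.0, n_somatic=20, seed=22)
        b = run_benchmark_grid(ref, densities=(0.001,), tumor_fractions=(0.6,),
                               target_depth=20.0, n_somatic=20, seed=22)
        assert a.equals(b)


class TestSpecValidation:
    def test_tumor_fraction_bounds(self):
        with pytest.raises(ValueError):
            MixSpec(total_reads=10, tumor_fraction=1.5)

    def test_error_rate_must_be_zero(self):
        with pytest.raises(ValueError):
            MixSpec(total_reads=10, tumor_fraction=0.5, error_rate=0.01)

    def test_pair_interpretation_doubles_reads(self):
        spec = MixSpec(total_reads=10, tumor_fraction=0.5, reads_are_pairs=True)
        assert spec.n_reads == 20
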