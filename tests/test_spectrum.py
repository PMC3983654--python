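"""Spectrum folding, strand bias, and the kataegis detector vs brute force."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zmel.spectrum import (
    SPECTRUM_CLASSES,
    cg_only_fraction,
    detect_clusters,
    fold_class,
    intermutation_distances,
    mutation_spectrum,
    strand_bias_test,
)
from zmel.types import GeneInterval, MutationRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _snv(pos, ref, alt, sample="s", chrom="chr1", t_depth=40, t_alt=20):
    return MutationRecord(sample, chrom, pos, ref, alt, "SNV",
                          t_depth, t_alt, 40, 0)


class TestFolding:
    @pytest.mark.parametrize("ref, alt, expected", [
        ("C", "T", "C>T"), ("G", "A", "C>T"), ("A", "C", "T>G"),
        ("T", "A", "T>A"), ("G", "C", "C>G"), ("A", "G", "T>C"),
    ])
    def test_purines_fold_to_pyrimidine_classes(self, ref, alt, expected):
        assert fold_class(ref, alt) == expected

    def test_ct_and_ga_collapse_to_one_class(self):
        catalog = [_snv(100, "C", "T"), _snv(200, "G", "A"), _snv(300, "G", "A")]
        profile = mutation_spectrum(catalog)
        assert profile.fractions["C>T"] == 1.0

    def test_empty_catalog_has_undefined_fractions(self):
        profile = mutation_spectrum([])
        assert profile.fractions is None and profile.total == 0

    def test_non_snvs_ignored_and_counted(self):
        catalog = [_snv(100, "C", "T"),
                   MutationRecord("s", "chr1", 5, "AT", "A", "DEL", 40, 20, 40, 0)]
        profile = mutation_spectrum(catalog)
        assert profile.total == 1 and profile.n_non_snv_ignored == 1

    @given(st.lists(
        st.tuples(
            st.integers(1, 10_000),
            st.sampled_from("ACGT"),
            st.sampled_from("ACGT"),
        ).filter(lambda t: t[1] != t[2]),
        max_size=30,
    ))
    @settings(derandomize=True, max_examples=50)
    def test_complement_invariance(self, triples):
        """Complementing every record's alleles leaves the profile unchanged."""
        catalog = [_snv(p, r, a) for p, r, a in triples]
        mirrored = [_snv(p, _COMP[r], _COMP[a]) for p, r, a in triples]
        a = mutation_spectrum(catalog).class_totals
        b = mutation_spectrum(mirrored).class_totals
        assert a.equals(b)


class TestStrandAttribution:
    _GENE_PLUS = GeneInterval("gp", "chr1", 50, 150, "+", exons=[(50, 150)])
    _GENE_MINUS = GeneInterval("gm", "chr2", 50, 150, "-", exons=[(50, 150)])

    def test_pyrimidine_on_coding_strand_is_untranscribed(self):
        profile = mutation_spectrum([_snv(100, "C", "T")], [self._GENE_PLUS])
        assert profile.counts.loc["C>T", "untranscribed"] == 1

    def test_purine_on_coding_strand_is_transcribed(self):
        profile = mutation_spectrum([_snv(100, "G", "A")], [self._GENE_PLUS])
        assert profile.counts.loc["C>T", "transcribed"] == 1

    def test_minus_strand_gene_flips_attribution(self):
        profile = mutation_spectrum(
            [_snv(100, "C", "T", chrom="chr2")], [self._GENE_MINUS])
        assert profile.counts.loc["C>T", "transcribed"] == 1

    def test_intergenic_is_unassigned(self):
        profile = mutation_spectrum([_snv(500, "C", "T")], [self._GENE_PLUS])
        assert profile.counts.loc["C>T", "unassigned"] == 1


class TestStrandBias:
    def test_balanced_counts_give_p_one(self):
        catalog = [_snv(p, "C", "T") for p in range(60, 70)] + \
                  [_snv(p, "G", "A") for p in range(80, 90)]
        gene = GeneInterval("g", "chr1", 1, 1000, "+", exons=[(1, 1000)])
        profile = mutation_spectrum(catalog, [gene])
        assert strand_bias_test(profile)["C>T"] == 1.0

    def test_fully_one_sided_counts(self):
        catalog = [_snv(p, "C", "T") for p in range(60, 70)]
        gene = GeneInterval("g", "chr1", 1, 1000, "+", exons=[(1, 1000)])
        profile = mutation_spectrum(catalog, [gene])
        p = strand_bias_test(profile)["C>T"]
        assert math.isclose(p, 2 * 0.5**10, rel_tol=1e-12)

    def test_unassigned_only_class_gives_null(self):
        profile = mutation_spectrum([_snv(100, "C", "T")])  # no gene models
        assert strand_bias_test(profile)["C>T"] is None


class TestCgFraction:
    def test_all_tc_catalog_scores_zero(self):
        assert cg_only_fraction([_snv(1, "T", "C"), _snv(2, "T", "C")]) == 0.0

    def test_half_and_half(self):
        assert cg_only_fraction([_snv(1, "C", "T"), _snv(2, "T", "C")]) == 0.5

    def test_empty_is_null(self):
        assert cg_only_fraction([]) is None


def _brute_force_clusters(positions, min_size, max_gap):
    """All maximal runs of consecutive sorted positions with gaps <= max_gap."""
    positions = sorted(positions)
    runs, run = [], []
    for p in positions:
        if run and p - run[-1] > max_gap:
            runs.append(run)
            run = []
        run.append(p)
    if run:
        runs.append(run)
    return [r for r in runs if len(r) >= min_size]


class TestClusterDetector:
    def test_dispersed_mutations_yield_no_clusters(self):
        catalog = [_snv(100_000 * i, "C", "T") for i in range(1, 10)]
        assert detect_clusters(catalog) == []

    def test_min_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            detect_clusters([], min_size=1)

    @given(st.lists(st.integers(1, 12_000), min_size=0, max_size=12, unique=True),
           st.integers(2, 4), st.integers(1, 3_000))
    @settings(derandomize=True, max_examples=200)
    def test_detector_matches_brute_force(self, positions, min_size, max_gap):
        catalog = [_snv(p, "C", "T") for p in positions]
        found = detect_clusters(catalog, min_size=min_size,
                                max_intermutation_distance=max_gap)
        expected = _brute_force_clusters(positions, min_size, max_gap)
        assert [[m.pos for m in c.members] for c in found] == expected

    @given(st.lists(st.integers(1, 50_000), min_size=0, max_size=20, unique=True))
    @settings(derandomize=True, max_examples=100)
    def test_widening_gap_never_shrinks_clusters(self, positions):
        catalog = [_snv(p, "C", "T") for p in positions]
        narrow = detect_clusters(catalog, min_size=2, max_intermutation_distance=500)
        wide = detect_clusters(catalog, min_size=2, max_intermutation_distance=2_000)
        # every narrow cluster is contained in some wide cluster
        for c in narrow:
            assert any(
                set(m.pos for m in c.members) <= set(m.pos for m in w.members)
                for w in wide
            )

    def test_cluster_conservation(self, default_bundle):
        """Clustered + unclustered mutation counts equal the per-sample total."""
        kat_id = default_bundle.truth["kataegis_sample"]
        catalog = [r for r in default_bundle.mutations
                   if r.sample_id == kat_id and r.is_snv]
        clusters = detect_clusters(catalog)
        clustered = sum(c.size for c in clusters)
        member_keys = {(m.chrom, m.pos) for c in clusters for m in c.members}
        unclustered = sum(1 for r in catalog if (r.chrom, r.pos) not in member_keys)
        assert clustered + unclustered == len(catalog)

    def test_cluster_annotations(self):
        catalog = [_snv(p, "C", "T", t_alt=20) for p in (100, 300, 500, 700, 900)]
        (cluster,) = detect_clusters(catalog, min_size=5)
        assert cluster.majority_class == "C>T"
        assert cluster.span == 800
        assert cluster.vaf_spread == 0.0


class TestRainfall:
    def test_distances_within_chromosome(self):
        catalog = [_snv(100, "C", "T"), _snv(200, "C", "T"), _snv(500, "C", "T")]
        table = intermutation_distances(catalog)
        assert table["distance"].tolist()[0] is None or \
            np.isnan(table["distance"].tolist()[0])
        assert table["distance"].tolist()[1:] == [100, 300]

    def test_single_mutation(self):
        table = intermutation_distances([_snv(100, "C", "T")])
        assert len(table) == 1 and table["distance"].isna().all()

    def test_distances_reset_per_chromosome(self):
        catalog = [_snv(100, "C", "T", chrom="chr1"),
                   _snv(900, "C", "T", chrom="chr1"),
                   _snv(50, "C", "T", chrom="chr2"),
                   _snv(60, "C", "T", chrom="chr2")]
        table = intermutation_distances(catalog)
        by_chrom = {c: g["distance"].tolist() for c, g in table.groupby("chrom")}
        assert by_chrom["chr1"][1] == 800
        assert np.isnan(by_chrom["chr2"][0]) and by_chrom["chr2"][1] == 10

    def test_strand_splits_sum_to_class_totals(self, default_bundle,
                                               default_gene_index):
        profile = mutation_spectrum(default_bundle.mutations, default_gene_index)
        assert (profile.counts.sum(axis=1) == profile.class_totals).all()
        assert set(profile.counts.index) == set(SPECTRUM_CLASSES)
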