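"""Synthetic-cohort generator: composition, special samples, determinism."""

import collections

import numpy as np
import pytest

from zmel.cohort import (
    AmpliconSpec,
    BurdenModel,
    CohortConfig,
    SpecialSampleSpec,
    draw_burdens,
    generate_cohort,
    generate_special_sample,
)
from zmel.spectrum import cg_only_fraction, detect_clusters, mutation_spectrum
from zmel.types import count_drivers


def _snv_counts(bundle):
    counts = collections.Counter(
        r.sample_id for r in bundle.mutations if r.is_snv
    )
    return {m.sample_id: counts.get(m.sample_id, 0) for m in bundle.samples}


class TestComposition:
    def test_genotype_composition_matches_table(self, default_bundle):
        rows = collections.Counter(
            (m.oncogene, m.p53, m.mitf, m.mitf_rescue, tuple(m.extra_alleles),
             tuple(m.extra_transgenes))
            for m in default_bundle.samples
        )
        cfg = CohortConfig()
        expected = {
            (r.oncogene, r.p53, r.mitf, r.mitf_rescue, r.extra_alleles,
             r.extra_transgenes): r.count
            for r in cfg.genotype_table
        }
        assert dict(rows) == expected
        assert len(default_bundle.samples) == 53

    def test_rescue_subgroup_has_25_samples(self, default_bundle):
        assert sum(1 for m in default_bundle.samples if m.mitf_rescue) == 25

    def test_driver_counts_span_one_to_four(self, default_bundle):
        counts = collections.Counter(count_drivers(m) for m in default_bundle.samples)
        assert counts == {1: 3, 2: 15, 3: 10, 4: 25}


class TestBurden:
    def test_median_coding_burden_is_four(self, default_bundle):
        burdens = list(_snv_counts(default_bundle).values())
        assert np.median(burdens) == 4

    def test_manifest_burdens_match_catalog(self, default_bundle):
        assert _snv_counts(default_bundle) == default_bundle.truth["burdens"]

    def test_burden_falls_with_drivers_across_cohorts(self, default_bundle):
        """Negative driver-burden correlation in >= 95% of 200 redraws."""
        rng = np.random.default_rng(99)
        model = BurdenModel()
        samples = default_bundle.samples
        drivers = np.array([count_drivers(m) for m in samples])
        n_negative = 0
        for _ in range(200):
            burdens = draw_burdens(samples, model, rng)
            vals = np.array([burdens[m.sample_id] for m in samples])
            n_negative += np.corrcoef(drivers, vals)[0, 1] < 0
        assert n_negative >= 190

    def test_background_spectrum_matches_mixture(self, default_bundle):
        """Mixture-drawn samples reproduce the configured C>T weight
        within binomial sampling error (3 sigma)."""
        special = {
            default_bundle.truth["hypermutant_sample"],
            default_bundle.truth["kataegis_sample"],
        }
        records = [r for r in default_bundle.mutations
                   if r.sample_id not in special and r.is_snv]
        profile = mutation_spectrum(records)
        f = profile.fractions["C>T"]
        p0 = CohortConfig().spectrum_mixture["C>T"]
        sigma = np.sqrt(p0 * (1 - p0) / profile.total)
        assert abs(f - p0) < 3 * sigma


class TestSpecialSamples:
    def test_hypermutant_has_47_cg_exclusive_substitutions(self, default_bundle):
        hyper = [
            r for r in default_bundle.mutations
            if r.sample_id == default_bundle.truth["hypermutant_sample"] and r.is_snv
        ]
        assert len(hyper) == 47
        assert cg_only_fraction(hyper) == 1.0

    def test_kataegis_clusters_detected_with_described_geometry(self, default_bundle):
        kat = [
            r for r in default_bundle.mutations
            if r.sample_id == default_bundle.truth["kataegis_sample"]
        ]
        clusters = sorted(detect_clusters(kat), key=lambda c: -c.size)
        assert [c.size for c in clusters] == [12, 5]
        assert clusters[0].span <= 4_500
        assert clusters[1].span <= 5_000
        assert all(c.majority_class == "C>T" for c in clusters)
        assert all(c.vaf_spread <= 0.13 for c in clusters)

    def test_archetype_generation_standalone(self, default_bundle):
        spec = SpecialSampleSpec("cg_exclusive", n=21)
        records = generate_special_sample(
            spec, "X", default_bundle.genome, default_bundle.genes, seed=5
        )
        assert len(records) == 21
        assert cg_only_fraction(records) == 1.0

    def test_cluster_of_size_one_rejected(self):
        with pytest.raises(ValueError, match="size"):
            SpecialSampleSpec("kataegis", clusters=((1, 4500),))

    def test_infeasible_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            SpecialSampleSpec("kataegis", clusters=((10, 5),))

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError, match="archetype"):
            SpecialSampleSpec("uv_signature")


class TestAmpliconAndSegments:
    def test_amplicon_implanted_in_exactly_ten_rescue_samples(self, default_bundle):
        amp = default_bundle.truth["amplicon"]
        carriers = set(amp["carriers"])
        assert len(carriers) == 10
        rescue = {m.sample_id for m in default_bundle.samples if m.mitf_rescue}
        assert carriers <= rescue
        implanted = {
            s.sample_id for s in default_bundle.segments
            if s.chrom == amp["chrom"] and s.start == amp["start"]
            and s.end == amp["end"]
        }
        assert implanted == carriers

    def test_no_carriers_config_gives_flat_locus(self):
        cfg = CohortConfig(amplicon=AmpliconSpec(n_carriers=0), seed=7)
        bundle = generate_cohort(cfg)
        amp = bundle.truth["amplicon"]
        overlapping = [
            s for s in bundle.segments
            if s.chrom == amp["chrom"] and s.start <= amp["end"]
            and s.end >= amp["start"]
        ]
        assert overlapping == []

    def test_deletions_enriched_in_vc7_subgroup(self, default_bundle):
        dels = collections.Counter(
            s.sample_id for s in default_bundle.segments if s.copy_number == 0
        )
        vc7 = [m.sample_id for m in default_bundle.samples if m.mitf == "vc7"]
        other = [m.sample_id for m in default_bundle.samples if m.mitf != "vc7"]
        mean_vc7 = np.mean([dels.get(s, 0) for s in vc7])
        mean_other = np.mean([dels.get(s, 0) for s in other])
        assert mean_vc7 > mean_other

    def test_carriers_exceeding_subgroup_rejected(self):
        with pytest.raises(ValueError, match="subgroup"):
            CohortConfig(amplicon=AmpliconSpec(n_carriers=26))


class TestIndels:
    def test_thirteen_short_indels_flanking_tandem_repeats(self, default_bundle):
        indels = [r for r in default_bundle.mutations if not r.is_snv]
        assert len(indels) == 13
        for r in indels:
            indel_len = abs(len(r.ref_allele) - len(r.alt_allele))
            assert 1 <= indel_len < 5
            # the implanted repeat: the motif recurs right of the anchor
            motif = (r.ref_allele if len(r.ref_allele) > 1 else r.alt_allele)[1:]
            seq = default_bundle.genome[r.chrom]
            assert seq[r.pos : r.pos + 3 * len(motif)] == motif * 3

    def test_four_indels_in_hypermutant(self, default_bundle):
        hyper = default_bundle.truth["hypermutant_sample"]
        n = sum(1 for r in default_bundle.mutations
                if not r.is_snv and r.sample_id == hyper)
        assert n == 4


class TestDeterminismAndManifest:
    def test_same_seed_reproduces_bundle(self, default_bundle):
        again = generate_cohort(CohortConfig())
        assert again.mutations == default_bundle.mutations
        assert again.segments == default_bundle.segments
        assert again.truth == default_bundle.truth
        assert again.genome.keys() == default_bundle.genome.keys()
        assert all(again.genome[c] == default_bundle.genome[c]
                   for c in again.genome)

    def test_written_bundle_is_byte_deterministic(self, tmp_path):
        cfg = CohortConfig(seed=11)
        a = generate_cohort(cfg).write(tmp_path / "a")
        b = generate_cohort(cfg).write(tmp_path / "b")
        for name in ("samples.tsv", "mutations.tsv", "segments.tsv",
                     "gene_sets.gmt", "truth_manifest.json", "genes.gff3",
                     "genome.fa"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_manifest_cluster_positions_match_catalog(self, default_bundle):
        kat_id = default_bundle.truth["kataegis_sample"]
        catalog_pos = {
            (r.chrom, r.pos) for r in default_bundle.mutations
            if r.sample_id == kat_id
        }
        for cluster in default_bundle.truth["kataegis_clusters"]:
            members = {(cluster["chrom"], p) for p in cluster["positions"]}
            assert members <= catalog_pos
            span = max(cluster["positions"]) - min(cluster["positions"])
            assert span <= cluster["max_span"]

    def test_manifest_indels_match_catalog(self, default_bundle):
        manifest = {
            (d["sample_id"], d["chrom"], d["pos"])
            for d in default_bundle.truth["indels"]
        }
        catalog = {
            (r.sample_id, r.chrom, r.pos)
            for r in default_bundle.mutations if not r.is_snv
        }
        assert manifest == catalog


class TestConfigValidation:
    def test_genotype_counts_must_sum(self):
        with pytest.raises(ValueError, match="sum"):
            CohortConfig(n_samples=52)

    def test_spectrum_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            CohortConfig(spectrum_mixture={"C>T": 0.5, "T>C": 0.4})
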