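# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `zmel`.

## Mutation–selection model

The selection module models coding substitution counts, cross-classified by
the 12 strand-specific substitution types and three consequence classes, as
independent Poisson variables with mean `r_s · L[s][c] · ω_c` (ω_syn ≡ 1).
The opportunity matrix L is computed by enumerating all three alternative
bases at every coding position of the supplied CDS sequences under the
standard genetic code, so the selection parameters are free of sequence
composition and per-type rate confounding. Assumptions: substitutions are
independent across sites, the CDS supplied is the relevant mutational
target, and selection acts multiplicatively per consequence class (no
per-gene or per-site variation in ω).

**Fitting.** The likelihood is bilinear in (r, ω), so coordinate ascent has
closed-form updates: for fixed ω, `r̂_s = Σ_c n[s][c] / Σ_c L[s][c]·ω_c`,
and symmetrically for each free ω. Iteration stops when the log-likelihood
improves by less than 1e-10 (cap 10,000 iterations; in practice tens).
The constrained fits (ω_mis = 1, ω_non = 1) reuse the same ascent with the
parameter frozen; `2·Δloglik` is referred to χ²(1). Substitution types with
zero total opportunity are excluded with a warning; observed counts at
zero-opportunity cells are an error (data inconsistency). A single trailing
stop codon on a CDS is skipped; internal stops are errors.

**Verification.** The coordinate-ascent MLE is checked in the test suite
against a dense profile-likelihood grid search on two-type problems, a
closed-form two-cell case (ω̂ = n_mis/n_syn when L_syn = L_mis), neutral
saturation (counts ∝ L ⟹ ω̂ = 1, LRT = 0), CDS-scaling invariance, and a
2,000-replicate null simulation whose rejection rate at α = 0.05 must lie
in [0.035, 0.065]. Parameter recovery is demonstrated at 10,000 mutations
on a 30 kb CDS with generating values ω_mis = 5.5, ω_non = 9.8 (the
hypermutant sample's estimates), recovered within ±15%.

The optional CpG context extension mentioned in the module interface is not
implemented as a separate rate class; the 12-type parameterisation is the
supported model.

## Combined gene significance

Each modality's background rate q_i is the average probability that a fixed
gene is hit at least once when sample k throws m_k events uniformly over N
genes: `q_i = (1/n_i) Σ_k [1 − (1 − 1/N)^{m_k}]`. m_k counts *events* (not
distinct mutated genes) per sample; N defaults to the number of genes in
the supplied models. The per-gene statistic multiplies the per-modality
binomial upper tails; a modality with zero hits contributes 1. Tails are
verified against explicit pmf summation for every n ≤ 12. The combined
product is not calibrated as a p-value under dependence between modalities;
it is used, as in the original analysis, as a ranking statistic with a fixed
0.05 selection cutoff (strict inequality). Pathway enrichment is a
one-sided hypergeometric tail over the gene universe, swept over minimum
per-gene mutation counts N_min = 1..10.

## Copy-number recurrence permutation test

Amplification calls are gated on tumor ploidy (CN ≥ 5 below ploidy 2.7,
CN ≥ 8 at or above; homozygous deletions at CN = 0); segments ≥ 10 Mb are
dropped. The null model re-places each called segment, per sample,
uniformly at random in a concatenated target space — positions are
randomized, lengths and per-sample segment counts preserved exactly.
Placement is unrestricted by chromosome (a per-chromosome mode is a
possible extension; the concatenated space is the default because the
segments being randomized are small relative to the space). The empirical
p is the add-one estimator `(#{count ≥ observed} + 1)/(n_perm + 1)`, so it
is never zero, with Bonferroni adjustment over the genes tested (default:
all genes overlapping the target space). Note the estimator's floor:
Bonferroni significance at 0.05 requires `n_perm > 20 × n_genes` —
desk-scale runs use 25,000 permutations for ~530 genes. The permutation
machinery is verified against exhaustive placement enumeration on a
100-position toy space.

## Spectra, strand bias and kataegis

Spectra use the six pyrimidine-folded classes; strand attribution compares
the strand carrying the reference pyrimidine with the strand of the
overlapping gene (pyrimidine on the coding strand ⇒ "untranscribed");
intergenic mutations are unassigned and excluded from bias testing. The
strand-bias test is a two-sided exact binomial test of the transcribed
count against 0.5; being discrete it is mildly conservative (achievable
size ≈ 0.044 at 500 assigned mutations), which the type-I simulation in
the test suite accounts for.

The kataegis detector reports maximal runs of ≥ `min_size` (default 5)
consecutive same-sample SNVs with successive gaps ≤
`max_intermutation_distance` (default 2,000 bp). These defaults are a
design choice — the original clusters were found by inspection — set so
that both described microclusters (12 mutations within 4,500 bp; 5 within
5 kb) are detected while same-gene background pairs are not. The detector
is verified against brute-force run enumeration on all small inputs.

## Caller benchmark harness

Genome pairs implant germline SNPs homozygously at a configurable density
(binomial placement) and exactly `n_somatic` (default 2,000) somatic
substitutions at germline-free positions. Reads are 75 bp, error-free, and
carry their true origin in the read name; no aligner is run — with zero
error rate, alignment at this scale is informationless, so the harness
isolates the statistical detection step. Somatic variants are
heterozygous: tumor samples draw reads half from the tumor haplotype and
half from the normal genome before contamination mixing. The naive caller
calls sites with ≥ `min_alt_reads` (default 3) alternate reads in tumor and
normal VAF ≤ `max_normal_vaf` (default 0.05; zero normal coverage counts as
VAF 0). Pileup candidate discovery compares each read with the reference at
its origin, batched in numpy. Coverage targets are expressed as mean depth
and converted to read counts from the genome size, so the study's full design
(five SNP densities × three tumor contents at 80×) runs at any genome
scale; the test suite exercises a reduced grid (2 densities × 3 fractions,
100 kb, 30×) and checks sensitivity monotonicity in tumor fraction and
TP + FN conservation.

## Synthetic cohort generator

The generator emulates the *structure* of the study, not its sequences:

* **Genome**: 21 chromosomes of 1–3 Mb, uniform random bases; 25 gene slots
  per chromosome, each gene 2,750 bp with three exons, 900 bp of stop-free
  CDS (random sense codons + terminal stop) written into the genome, UTRs
  of 100/150 bp, alternating strands. The chr3 analog carries a 175 kb
  amplicon window with five resident genes (prkacaa/samd1/asf1ba/
  wu:fj41e11/tecra analogs) and two flankers outside it.
* **Samples**: the 15-row genotype table (53 fish: 38 BRAF, 15 NRAS; the
  six MITF-rescue rows total 25) with driver counts 1–4 by the convention:
  oncogene + any mutant p53 + any non-wt mitf + rescue + each extra
  germline allele; co-expressed transcription-factor transgenes are not
  counted. Ages are uniform on 6–18 months (rounded to 0.1); ploidies are
  ~2.0 with a fifth of samples at 2.8–3.6.
* **Burden**: negative binomial with
  `log μ = 2.45 − 0.45·drivers + 0.04·age`, dispersion k = 3. The negative
  driver and positive age coefficients encode the reported directions; the
  intercept was calibrated once by simulation to a cohort median of 4
  coding substitutions and then frozen. The dispersion is a free choice
  (the source reports no distributional detail beyond median and maximum).
* **Spectrum**: class probabilities {C>A .14, C>G .11, C>T .244, T>A .13,
  T>C .236, T>G .14} — C>T fixed at the reported 24.4%, the rest spread
  roughly evenly as a design choice. Sites are drawn from coding positions
  whose reference base matches the class (either strand orientation).
* **Special samples**: the single-driver BRAF fish is the hypermutant —
  47 substitutions, every reference base C or G, class mix {C>A .40,
  C>G .30, C>T .30} (a deliberately distinct, non-C>T-dominated
  signature). The first BRAF;p53+/- fish carries two kataegis clusters
  (12 members within ≤ 4,500 bp and 5 within ≤ 5,000 bp, ≈85% C>T, VAFs
  within ±0.05 of a common value) plus 13 dispersed background mutations
  kept ≥ 10 kb away from the clusters.
* **Indels**: 13 cohort-wide (8 of 1 bp, 5 of 2–4 bp), four assigned to the
  hypermutant, each adjacent to a tandem repeat (motif × 5) implanted at an
  intergenic site; the indel inserts or deletes one motif unit.
* **Copy number**: the amplicon (CN 9, called at any ploidy) implanted in
  exactly 10 randomly chosen rescue-subgroup samples; background
  amplifications (Poisson mean 2/sample), homozygous deletions (mean 0.5,
  raised to 3 in mitf-vc7 samples) and sub-threshold gains, with lengths
  20–300 kb so segments stay small relative to the desk-scale genome (the
  same segment-to-genome ratio as < 10 Mb segments on a real genome).
  Background segments never overlap the amplicon window, keeping the
  implanted recurrence exact.
* **Truth manifest**: JSON recording seed, burdens, special-sample
  identities, cluster member positions, amplicon carriers, indel sites and
  the generating model parameters. Identical config + seed reproduces the
  bundle byte for byte.

**What passing tests do not show.** The generator has no sequencing noise,
no subclonality or purity variation, no mapping artifacts, no fragile
sites, and mutation placement is uniform within coding regions; results on
it validate the statistical machinery, not robustness to real-data
artifacts. Depth/VAF columns are drawn to pass the somatic filters by
construction.

## Burden covariates

Pearson correlation with two-sided t-test p (listwise deletion; null when
fewer than 3 complete pairs or zero variance). The burden GLM is Poisson
with log link via statsmodels IRLS; when the Pearson dispersion exceeds 2
the model is refitted with the dispersion-scaled (quasi-Poisson) covariance
for Wald tests. Driver count enters numerically. On the default synthetic
cohort the marginal age–burden correlation is weak (the driver effect
dominates); the positive age direction is recovered conditionally in the
GLM.

## Problem sizes and determinism

Simulation-based checks use desk-scale sizes chosen to make their
statistical bands meaningful: 2,000 replicates for the LRT null, 1,000 for
strand-bias and GLM type-I error, 10,000–25,000 permutations for
enrichment, 30–50× coverage over 50–100 kb genomes for the caller
benchmark, and a 5 Mb reference for the exact-somatic-count check. Every
stochastic component takes an explicit seed (numpy `default_rng`);
cohort generation, read simulation, mixing and permutation are reproducible
bit for bit given the seed.

## Known limitations

* The consequence annotator is single-transcript, assumes frame-0 CDS
  models, and classifies deep-intronic positions as non-coding rather than
  as a dedicated intron class.
* The selection model has no CpG context classes and no per-gene ω.
* The combined significance product ignores inter-modality dependence.
* The permutation test randomizes amplifications as placed intervals in
  concatenated space; it does not model chromosome-specific mechanisms.
* VCF output stores the originating sample in an INFO tag (one catalog per
  file across samples) rather than multi-sample genotype columns.
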