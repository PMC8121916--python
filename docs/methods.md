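# Methods

`assortscan` detects positive assortative mating between a female
pheromone-signal locus and a male preference locus from population-genomic
samples, and ships the forward simulator used to validate every scan.  This
note records the models, the defaults and why they were chosen, and what
the synthetic data can and cannot say about real samples.

## The biological model

Two moth strains (E and Z) share a range.  Females advertise with a blend
controlled by an autosomal biallelic *signal* locus (hom-E females produce
an E-biased blend, hom-Z a Z-biased blend, heterozygotes intermediate).
Males respond according to a biallelic *preference* locus on the Z
chromosome.  Because moths are female-heterogametic (males ZZ, females ZW)
and female meiosis is achiasmatic, the preference locus is diploid in males,
hemizygous in females, and recombines only through males.

Assortative mating leaves two signatures in a sample pooled across the two
mating pools:

1. **Signal-preference linkage disequilibrium.**  Non-random mating builds
   a genetic correlation between the unlinked signal and preference loci;
   r² between them rises above the genome-wide admixture background.
2. **Heterozygote deficit.**  Sampling across partially isolated pools
   depresses heterozygosity at every differentiated locus (Wahlund), most
   strongly at the loci that determine the assortment.

## Scan statistics

### Pairwise r² by two-locus EM

For each pair of biallelic sites the multinomial likelihood of the nine
genotype combinations is maximized over the haplotype frequency `p_AB`
(only double heterozygotes have ambiguous phase).  The EM runs from three
starts — linkage equilibrium and both Lewontin bounds — and keeps the
highest-likelihood solution, which handles the occasional second mode of
the two-locus likelihood; convergence tolerance 1e-12 on `p_AB`, at most
1000 iterations, flagged if unconverged.  `r² = D²/(p_A q_A p_B q_B)` is
undefined (NaN, never an exception) at monomorphic margins.  Pairs with
fewer than `min_n = 10` complete cases are skipped, not zero-filled.
Hemizygous (female Z) calls are excluded pairwise: the genotype table
assumes diploids.  This replaces external statistical phasing; for pairwise
r² the EM maximum likelihood is exact, so nothing is lost.

### Empirical null for the LD scan

The focal-locus scan reports, per Z-linked site, the maximum r² against the
focal set (ties broken toward the lowest (chrom, pos)).  The null
distribution is built from variant pairs on different chromosomes or at
least 1 Mb apart (admixture affects these pairs identically, so the null
carries the genome-wide background), subsampled to a seeded cap of 10⁴
pairs; the threshold is the 99.99th percentile with linear interpolation
between order statistics (stated explicitly because extreme percentiles are
estimator-sensitive).  A 1-kb / 100-bp-step sliding mean of max-r² smooths
the track; a distance-stratified profile from 15-kb regions sampled
uniformly (seeded) along the chromosome puts the focal LD on the physical
distance scale.

### Exact heterozygote-deficit test

Conditional on `n` diploids and `n_A` copies of an allele, the number of
heterozygotes `h` follows

    Pr(h) ∝ n! 2^h / (n_AA! h! n_aa!),

over `h` of matching parity.  The one-sided deficit P sums the tail
`h' ≤ h_obs`; computation is in log space (gammaln + logsumexp), safe to
n ~ 1e5.  The one-sided tail is the default because the assortative-mating
prediction is directional; excess and two-sided variants are available for
comparison with generic HWE tools.  FDR control is Benjamini-Hochberg
(named only generically in the scan's provenance; it is the canonical
choice and monotone in p).  Genes collect every site their interval covers
(introns included; no nearest-gene fallback) and rank by count of q < 0.01
sites, ties by min P.

### Pool-seq differentiation

Per site and pool pair, F_ST is the classic pool-seq estimator
`(π_total − π_within)/π_total` with `π = 2p(1−p)` corrected by
`n/(n−1)`, `n = min(coverage, haploid pool size)`; site values average over
non-overlapping 1-kb windows per pair and across pairs.  Consistent
allele-frequency differences across replicate collection sites are tested
by the Cochran-Mantel-Haenszel statistic with continuity correction
(clamped at zero for deviations inside the correction, the `mantelhaen.test`
convention), applied only to sites that pass a Woolf log-odds-ratio
homogeneity test (Haldane-Anscombe +0.5; pass at p > 0.05, configurable).

**Effective pool coverage.**  Raw read-count CMH is anticonservative
whenever depth approaches the haploid pool size: read counts then
pseudo-replicate the few underlying chromosomes.  Counts entering the
Woolf/CMH tests are therefore rescaled to the variance-matched effective
coverage `1/(1/coverage + 1/haploids)` (standard pool-seq practice).  With
the rescaling, random-mating pools yield ≤1% of sites at q < 0.01; without
it (toggle `effective_size=False`) the same null shows ~20% false
discoveries at depth 50 over ~15-haploid pools.

Site filters mirror the conventional pool-seq pipeline: every pool's
coverage within [10, 200], the site-wide minor allele seen at least twice
in each collection site's pooled reads, and no indel within 5 bp (the
near-indel distance is the conventional default; the source pipelines state
the filter but not the distance).

## The simulator

Discrete non-overlapping generations, two demes.  Each generation:
symmetric migration of `round(m·N)` individuals per sex; then each female
draws candidate males uniformly with replacement until one accepts
(acceptance 1 on a blend/preference match, `assort_alpha` on a mismatch;
heterozygous males are "indifferent" by default and intermediate-blend
females are courted at the mean of the two pure-blend probabilities,
`(1+alpha)/2`; after 100 failed draws the female mates randomly — sampled
in closed form, the accepted father is distributed proportionally to his
acceptance probability).  Offspring draw a mother uniformly; gametes follow
ZW rules with Poisson crossovers (rate `rec_rate_male` per bp) in males
only.  Background SNPs start at per-deme frequencies differing by 0.5
(0.25/0.75) and drift neutrally; the focal loci start as fixed differences.
All randomness flows from one seed through spawned substreams; identical
config + seed gives byte-identical outputs.

### Calibration of the defaults

The defaults are the study conditions: they were chosen, once, so that
pheromone-trapped males are trap-concordant double homozygotes ~80% of the
time (the two-locus genotype structure of the 62-male field panel) *and*
that structure is a quasi-equilibrium rather than a transient.  Two
observations fixed the operating point:

- Concordance is governed by the migration/assortment balance, but weak
  assortment with appreciable migration decays toward fusion of the demes,
  so the ~80% state must be held by strong-ish assortment at low migration
  (`assort_alpha = 0.1`, `migration = 0.005`).
- The LD scan's discriminating power is limited by background admixture
  LD: background SNPs that drift to large between-deme frequency
  differences mimic the signal-preference correlation.  Deme size 2000
  (1000 females + 1000 males) keeps migration-drift equilibrium F_ST low
  enough that the preference locus tops the Z-chromosome scan reliably,
  while 50 generations let the initial background differentiation decay.

At these defaults (2000 background SNPs, trap error 0.05, 31 males per
trap per sample): panel concordance ~0.82 ± 0.07; preference-locus max r²
~0.6-0.7 against an empirical 99.99th-percentile threshold of ~0.6 — the
same regime as the field data (0.71 vs 0.66).  Trap error and migration have no
field estimates; their values are calibration outputs of this procedure,
not measurements.

### What the synthetic data does not emulate

Single pair of chromosomes plus the Z; no mutation, no selection at
background loci, no overlapping generations, no spatial structure beyond
two demes, equal deme sizes, one variant class (SNPs).  Real data add
reference/mapping artifacts, coverage heterogeneity, indel/SV genotyping
error and uneven recombination — so passing scans here demonstrate the
statistics and their calibration under the model's assumptions, not
robustness to those artifacts.

## Problem sizes used in the shipped checks

Oracle-equivalence checks run on 1000 random tables (EM vs likelihood
grid; exact test vs rational enumeration) and several hundred random
stratified tables (CMH/Woolf vs from-scratch formulas).  Null calibration
pools 8-12 random-mating replicates (panmictic, 300 individuals, 800
SNPs); signal recovery uses 10-12 replicates at the full calibrated
defaults.  These replicate counts are the package's chosen operating sizes
for routine verification; the underlying rates were also spot-checked on
larger replicate sets during calibration.

## Known limitations

- The EM r² assumes random mating *within the genotype table* it sees;
  under extreme inbreeding the two-locus genotype frequencies are no
  longer products of haplotype frequencies.  In this pipeline that is
  acceptable: the quantity scanned for is precisely the departure, and the
  estimator matches the grid-search ML of the stated multinomial model.
- The exact HWE test conditions on allele counts; with fewer than ~10
  diploid calls it has essentially no power, hence the `min_n` floor.
- Woolf's test with the +0.5 correction is conservative at very low
  counts; sites failing it are reported with their heterogeneity P but no
  CMH P, never silently dropped.
- The F_ST estimator is a method-of-moments ratio and is clipped to
  [0, 1]; per-site values at low coverage are noisy by construction and
  only window means are interpreted.
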