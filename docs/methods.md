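# Methods

## The question the simulation answers

For a complex trait with heritability 0.14 recorded only on females,
most phenotypes belong to animals without genotypes.  Single-step GBLUP
can use those records through the pedigree; marker-only methods cannot.
The experiment simulates populations whose LD level is controlled by
bottleneck length, maps QTLs with both method families, and measures
whether — and under which LD regime — the extra phenotypes improve QTL
detection.

## Population model

**Historical phase.** Generation 0 starts with every gene copy drawn
uniformly from its locus's allele set (frequency 1/k per allele).  Each
generation is produced by random union of gametes (each offspring draws
a random sire and a random dam), constant size 1,000 for 1,000
generations, then a linear decline to 200 over 2,020 generations
(high-LD population, HLD) or 1,020 generations (low-LD, LLD).  The two
populations differ *only* in bottleneck length; the longer bottleneck
accumulates roughly twice the drift (Σ 1/2N ≈ 2.0 vs 1.0 over the
decline), hence stronger LD.

**Meiosis.** Crossover counts per chromosome are Poisson with mean
equal to map length in Morgans, positions uniform, no interference
(Haldane's model); chromosomes assort independently.  Implementation:
a genome-wide Poisson process on the concatenated map plus a random
phase per chromosome, walked per gamete in a numba kernel.  The
recombination fraction between loci d Morgans apart is
½(1 − e^(−2d)), verified against that closed form in the tests.

**Mutation.** Recurrent, rate μ = 1e-4 per gene copy per locus per
generation (each newborn carries Poisson(2Lμ) mutations assigned to
random loci and gametes).  A mutated marker flips its allele; a mutated
QTL draws a different allele uniformly.  Mutation operates in the
historical phase only.  The per-copy reading matters: it maintains
roughly 40–55% of markers at MAF ≥ 0.02 through the bottleneck, which
is what makes the full-scale 335,000-marker panel selectable; a
population-level Poisson(2Lμ) reading would retain only ~12% and
cannot supply the design's panel.

**Panel selection.** From the last historical generation: markers with
MAF ≥ 0.02 and QTLs still segregating, sampled uniformly without
replacement (full scale: 335,000 of 735,293 markers, 1,000 of 7,000
QTLs).  Eligibility shortfalls raise errors naming the deficit.

**Genome.** 29 autosomes with lengths proportional to the bovine
physical autosomes, normalized to 2,333 cM; locus counts per chromosome
proportional to length, positions uniform.  Window analyses use the
1 cM = 1 Mb equivalence throughout.

**Trait.** QTL allele effects |e| ~ Gamma(0.4, 1) with independent
random signs, rescaled once so the variance of the summed QTL values in
the panel-founder cohort equals h²·σ²_p = 0.14 exactly.  Phenotype =
TBV + N(0, 0.86), females only (the trait is sex-limited).

**Expansion.** All 100 founder dams are mated to random founder males;
dams double each generation (100 → 3,200 over six generations), five
offspring per dam, 100% replacement, no selection; 16,000 animals in
the last cohort.

**Selection.** 240 sires and 6,000 dams sampled from the last expansion
cohort; each dam produces one offspring per generation from a randomly
assigned sire; 20% of sires and dams are replaced each generation by
the top-EBV candidates of the newest cohort (lowest-EBV parents culled).
EBVs are pedigree-BLUP predictions using all female records to date and
the true variance ratio — the design is silent on the EBV machinery, and
BLUP is the natural reading of "expected breeding value"; parent
averages reach unphenotyped candidates through the BLUP itself.
15 generations × 6,000 dams = 90,000 animals; 2,000 females of the last
three generations are genotyped.

## Analyses

**WssGBLUP.** Henderson's MME with `H⁻¹ = A⁻¹ + scatter(Gb⁻¹ − A22⁻¹)`.
`A⁻¹` comes from Henderson's rules with inbreeding (Meuwissen–Luo
coefficients; Mendelian-sampling variance uses F = −1 for unknown
parents).  `G` is VanRaden method 1 with observed allele frequencies in
the genotyped set, `Gb = 0.95 G + 0.05 A22` for invertibility (no τ/ω
scaling).  `A22` is obtained by solving `A⁻¹X = E` on the genotyped
unit vectors rather than building dense A.  Back-solving uses
`û = D P′ (c·Gb)⁻¹ â_g` with `c = Σ 2pq`, i.e. the same blended matrix
as the solve, so `P D P′ ∝ G` consistently.  Weights
`dᵢ ∝ ûᵢ²·2pᵢ(1−pᵢ)` are normalized to `Σd = m` each iteration — the
"constant total genetic variance" rule; the printed weight formula of
the source design omits the factor 2, which normalization absorbs.
Scenario SI fits all records, SII only the genotyped animals' records;
with fixed effects beyond a mean, SII records are pre-adjusted using
estimates from a regular pedigree BLUP on everything (for the simulated
trait only a mean is fitted, so pre-adjustment is a no-op).

**Bayes C.** Single-site Gibbs in fixed SNP order; δᵢ sampled from its
full conditional with bᵢ marginalized, then bᵢ | δᵢ=1 from its normal
conditional; μ, σ²_g, σ²_e from scaled-inverse-χ² conditionals
(ν = 4.2; scales matched in expectation to σ²ₐ/((1−π)·m·2p̄q̄) and
σ²ₑ).  π carries beta pseudo-counts of total weight 1e8 oriented so the
prior mean equals the configured exclusion fraction (0.99 or 0.999),
pinning it in practice — the published hyper-parameters (α = 1e8,
β = 1e10) describe a beta with mean ≈ 0.01, i.e. they parameterize the
*inclusion* fraction; the stated behaviour ("almost fixed" exclusion)
is what is implemented.  Full-scale chain: 550,000 / 50,000 / 50
(10,000 kept samples); reduced chains at the smaller scales.

**Scoring.** True shares are Var(per-QTL genotypic value)/Var(TBV) over
the phenotyped cohort (shares may not total 100% under LD; a config
switch can use Σ-variance instead).  topQTL = shares ≥ 1%; the equally
many best 1-Mb windows (ties broken by genomic order) are matched
one-to-one to topQTL positions within 1 Mb; the count of matched QTLs is
NtrueQTL, computed as the maximum bipartite matching of the
within-tolerance adjacency.  A greedy nearest-first rule was considered
and rejected: it can undercount (two windows at 0 and 1.2 Mb with QTLs
at 0.5 and −0.6 Mb admit two matches but greedy finds one), whereas the
maximum matching is deterministic and agrees with exhaustive
enumeration on every tested instance.

## The marginal-drift shortcut for truth statistics

The distribution of the *true* QTL variance shares depends on allele
frequencies and effects, not on the marker panel or the analyses.
`simulate_locus_drift` therefore drifts each locus independently
(multinomial resampling of 2N gene copies per generation, per-copy
mutation as above) through the same demographic schedule, after which
shares follow from Hardy–Weinberg/linkage-equilibrium algebra.  That is
how `scripts/acceptance.py` computes the headline topQTL counts at the
full design scale in minutes.

Caveats of the shortcut: marginal drift reproduces per-locus frequency
distributions exactly but ignores linked drift and the 21
post-historical generations (measuring after those generations was
tested and shifts the topQTL count by less than one QTL).  The counts
are sensitive to the mutation model and to any MAF floor on QTL
eligibility: requiring QTL MAF ≥ 0.05 instead of bare segregation would
lower the 10-replicate mean count by roughly 3–4 QTLs, because a
segregating-only panel carries many near-fixed loci that concentrate
the variance shares.  The design states bare segregation, which is what
is implemented.

## Problem scales

| scale | genome | panel | historical gens (HLD/LLD) | selection | genotyped |
|-------|--------|-------|---------------------------|-----------|-----------|
| full  | 29 chr, 2,333 cM, 735k+7k loci | 335,000 / 1,000 | 3,020 / 2,020 (N 1,000→200) | 15 gen, 240×6,000 | 2,000 |
| desk  | 29 chr, 600 cM, 15k+900 | 6,000 / 300 | 1,204 / 804 (N 400→100) | 5 gen, 96×2,400 | 800 |
| mini  | 10 chr, 200 cM, 9k+300 | 2,000 / 100 | 600 / 400 (N 200→80) | 5 gen, 24×600 | 300 |

The mini scale is the test-suite workhorse: its drift budget per
generation (1/2N) and the 2:1 HLD:LLD bottleneck ratio mirror the full
design, so LD ordering, weight-iteration behaviour and the SI/SII
contrast are preserved while one replicate simulates and analyzes in
about 15 s.  The full preset is the documented nominal configuration;
its memory footprint (90,000 animals × 742,293 loci) is beyond a
workstation and it is retained as configuration, not as a test target.

## Numerical choices

* Sparse MME systems are factorized with SuperLU using the
  `MMD_AT_PLUS_A` ordering (the systems are symmetric; default COLAMD
  ordering fills in badly on pedigree graphs with heavily-used sires).
  Above 150,000 equations the solver switches to Jacobi-preconditioned
  conjugate gradients with relative tolerance 1e-10; direct solves are
  verified to residuals below 1e-10.
* Monomorphic SNPs in the genotyped set are excluded from G with a
  warning; their back-solved effects are exactly zero by centering, so
  window statistics remain aligned with the full marker map.
* The gamete sampler guarantees both sexes exist in every cohort of
  size ≥ 2 (the historical random-mating phase would otherwise die with
  small probability at small N).
* Weight degeneracy (all û = 0), zero genetic variance before effect
  scaling, singular blended G, rank-deficient fixed effects and
  non-finite sampler states all raise explicit errors; rank-deficient
  fixed-effect columns are dropped with a warning and constrained to 0.
* Seeding: every stochastic stage draws from a named
  `SeedSequence([base_seed, replicate, stream])`, so SI and SII consume
  byte-identical simulated data within a replicate and reruns reproduce
  summary tables byte-for-byte.

## Limitations

* No sex chromosomes, dominance/epistasis, genotyping error, or
  missing-marker handling; no REML — variance components are the true
  simulation values (the design's own convention).
* The synthetic populations have a single overall mean as fixed effect;
  real datasets with contemporary groups exercise the pre-adjustment
  path, which is implemented but only lightly used by the bundled
  experiment.
* Bayes C is run on genotyped animals only (the marker-model likelihood
  has no pedigree term), matching the design's scenario assignment.
* The drift shortcut's topQTL counts run a few QTLs above values
  obtained with gene-level simulators of the same nominal design; the
  sensitivity analysis above (mutation reading, MAF floor, measurement
  cohort) brackets the plausible causes.
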