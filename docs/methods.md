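# Methods

`rumherit` screens a rumen microbiome for heritable bacterial OTUs using
host SNP genotypes, then characterizes the called set phylogenetically and
by its association with rumen metabolites and host traits. This note
documents the statistical models, the defaults and why they were chosen,
what the synthetic generators do and do not emulate, and the numerical
choices that matter.

## The mixed model and heritability

For each phenotype (an OTU's relative abundance on one sampling day, or a
host trait) over the n genotyped animals:

    y = Xβ + u + ε,   u ~ N(0, σu² A),   ε ~ N(0, σε² I)

where A is the SNP-derived genetic relationship matrix,

    A_jk = (1/n_jk) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

x the reference-allele counts, p_i the reference-allele frequency, and
n_jk the number of SNPs non-missing in both animals of the pair
(pairwise-complete; equal to the global SNP count on complete data, where
A = WWᵀ/n with W the column-standardized genotype matrix). Narrow-sense
heritability is h² = σu²/(σu² + σε²).

Variance components are estimated by REML. The likelihood is profiled to
one dimension: with V = σ²·(h²A + (1−h²)I), both β and the total variance
σ² have closed-form optima given h², leaving a bounded scalar maximization
over h² ∈ [0, 1]. A single eigendecomposition A = QΛQᵀ turns every
likelihood evaluation into O(n) work after rotating y and X by Qᵀ, which
is what makes per-day fits across thousands of OTUs and the 100-iteration
permutation null tractable on one CPU. The maximizer is a 41-point coarse
grid followed by 48 fixed golden-section iterations inside the bracketing
cell, with the boundary points h² = 0 and h² = 1 always compared exactly —
deterministic, no random restarts, boundary solutions returned exactly.
Batched fits across phenotype columns use the identical algorithm
vectorized; they agree with independent single fits to ~1e-6 in h² (the
residual difference is BLAS reduction-order noise on a flat likelihood,
not an algorithmic difference).

Significance of σu² > 0 uses the boundary likelihood-ratio test: the null
distribution of LR = 2(ℓ_full − ℓ_{h²=0}) is the equal mixture of a point
mass at zero and χ²₁, so p = 0.5·Pr(χ²₁ ≥ LR). This is conservative to
exact asymptotically; the calibration check (500 null simulations at
n ≈ 200) observes a rejection rate of ~0.03 at α = 0.05.

### Numerical choices

* **PSD repair.** Pairwise-complete GRMs from genotypes with missing calls
  are routinely slightly indefinite (each pair's estimate uses its own SNP
  subset). Eigenvalues down to −0.05·(trace/n) are clipped to zero;
  anything lower raises, since that indicates a broken kernel rather than
  estimation noise.
* **Degenerate phenotypes.** Constant phenotypes raise (screen callers
  mark the fit failed); quadratic forms are floored at 1e-300 before logs.
* **Grid + golden section.** Grid spacing 1/40 with ±1-cell refinement is
  robust to the mild multimodality small-n REML surfaces can show; 48
  golden iterations shrink the bracket below 1e-9.
* **GRM diagonal.** The default diagonal applies the same formula as the
  off-diagonal with j = k (`diagonal_mode="plain"`); the GCTA-style
  alternative `1 + (1/n)Σ(x² − (1+2p)x + 2p²)/(2p(1−p))` is available as
  `diagonal_mode="gcta"`. The two coincide in expectation under
  Hardy–Weinberg; which one a given study used is rarely documented, so
  both are first-class and the mode is recorded in run metadata.

## Genotype QC

PED/MAP text in the `--recode12` dialect (alleles coded 1/2, 0 missing; a
genotype is the count of "1" alleles, any 0 in the pair is missing).
Filters run in the order individual call rate (`mind`, default 0.05) →
SNP missingness (`geno`, 0.05) → minor allele frequency (`maf`, 0.05),
each recomputed on the individuals retained so far. MAF exactly equal to
the threshold is kept (strictly-below removal), the usual convention of
chip-QC tools. A reference-panel hook lets stage-2/3 statistics be pooled
with a larger PED when one is available; by default statistics come from
the analysis cohort alone. No Hardy–Weinberg filter and no LD pruning are
applied.

## The consensus screen and its permutation null

OTUs are first presence-filtered: kept if nonzero in ≥ `min_present`
(default 12) genotyped animals, where an animal counts as present when any
of its day samples is nonzero. Presence is defined at the animal level
because the animal is the unit of genotyping; a day-level alternative is a
config switch away.

Each surviving OTU is then fit once per sampling day, with the phenotype
being that day's raw relative abundance (an optional rank-based
inverse-normal transform exists but is off by default — raw abundance
first, robustness as an option). The consensus heritable set contains the
OTUs with h² > 0.7 and p < 0.05 on **every** day; requiring day-consistent
significance is the multiplicity control here, and no per-OTU q-values are
computed.

The false-discovery calibration reruns the entire consensus screen under
permutations of the genotyped animals' genetic identities: each of
`n_perm` (default 100) iterations draws one permutation and applies it to
the GRM's rows and columns — implemented equivalently by permuting every
phenotype's animal order, identically across all OTUs and all days, so
cross-OTU dependence is preserved under the null. The report is the
observed heritable count and the fraction of permutations with a strictly
smaller count.

## 16S clade relatedness

Pairwise percent identity uses global (end-to-end) affine-gap alignment:
match +2, mismatch −1, gap open −5, gap extend −2 (a gap of length L costs
−5 −2(L−1); end gaps are penalized like internal ones). Identity is
100·matches/columns with gap columns in the denominator, and `N` never
counts as a match. Because several alignments can share the optimal score,
identity is defined path-independently as the maximum match count among
all optimal-score alignments (ties toward fewer columns), computed by a
second dynamic program over score-tight transitions. This makes the value
deterministic and invariant under jointly reverse-complementing both
sequences, and it is checked exactly against an independent aligner.
The scoring is configurable and echoed into output metadata, since
percent-identity values are only comparable under a stated scoring.

The clade test compares the mean pairwise identity of the heritable set
against `n_draws` (default 100) uniform same-size subsets of the eligible
(presence-filtered) pool; the empirical p-value uses the add-one rule
(1 + #{null ≥ observed})/(1 + draws), so it is never zero. Taxon
enrichment at a chosen rank (default order) uses two-sided Fisher exact
tests on the (heritable vs not) × (taxon vs not) table; lineages
unparseable at the rank count as "unclassified".

## Trait association

Correlation analyses use the per-animal **mean abundance across days**
over the full cohort (heritability fits, in contrast, stay per-day over
genotyped animals — the two conventions serve different questions).
Spearman correlations use average ranks and the large-sample t
approximation for nominal p-values, pairwise-complete per (OTU, index).
The permutation null for an index's mean correlation over the heritable
set shuffles each OTU's abundance profile independently in each of
`n_perm` (default 1000) iterations; both the signed mean r (tested on
|mean|) and the mean |r| are reported. Heritable-vs-all comparisons use
Welch's t on |r|. The per-index correlation odds ratio is
(hc/hn)/(nc/nn) with "correlated" meaning nominal Spearman p < 0.05;
infinite when hn·nc = 0 with hc·nn > 0, undefined when a margin is empty.
The Bonferroni flag divides 0.05 by the number of indices actually tested.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analyses assume,
at desk scale. Defaults describe the kind of dairy-herd design this
pipeline targets: a 78-animal cohort with 47 genotyped, 11 half-sib sire
families (one of four, one of three, nine of two), ~40k post-QC SNPs with
MAF ≥ 0.05, three sampling days, and 22 planted heritable OTUs.

* **Genotypes.** Per SNP, a reference-allele frequency uniform on the MAF
  range; each sire carries two haplotype alleles, each offspring inherits
  one (chosen independently per SNP — SNPs are unlinked) plus a fresh
  population dam allele. Expected half-sib relatedness is 0.25 without
  pedigree machinery; the realized GRM entry of an embedded half-sib pair
  averages ~0.23–0.25 (cohort-estimated allele frequencies bias it
  slightly low, as they do in real data).
* **Abundances.** Each planted OTU's per-animal latent is g + e_shared +
  e_day with g ~ N(0, h²A), variances scaled so the per-day latent has
  unit variance and genetic fraction h²; day noise sd defaults to 20% of
  the latent sd (capped by the available non-genetic variance), so day
  replicates share the genetic component and the three-day consensus is
  attainable. Latents map to abundances through exp(0.25·latent) — a
  strictly monotone log-normal shape giving the right skew — the
  lowest-latent animals are zeroed to meet the presence fraction, and
  each sample is renormalized to sum to one. The distribution of real OTU
  abundances is unknown; the log-normal is a stand-in, and Spearman-based
  downstream stages are invariant to the monotone choice. Two consequences
  worth knowing: (i) the exponential map plus compositional
  renormalization attenuates abundance-scale h² below the latent target
  by roughly 0.05–0.1 at h² = 0.7, so parameter-recovery checks against
  the generating mixed model are the clean estimator test, while
  abundance-scale recovery is asserted with a ±0.1 band; (ii) animals
  without genotypes receive independent latents of equal total variance —
  they exist so the full cohort can be traited, and carry no genetic
  signal.
* **Sequences.** Star trees: background OTUs (and the clade ancestor)
  diverge independently from a global ~250 nt ancestor at the background
  substitution rate, planted OTUs from the clade ancestor at the
  within-clade rate. The per-branch rate q solves
  (1−q)² + q²/3 = target identity. Default targets: 0.90 within clade,
  0.75 background. Taxonomy strings draw from a fixed rumen-like lineage
  pool with the planted clade 80% Bacteroidales. No indels are simulated,
  no rate variation across sites, no real phylogeny — the generator
  controls exactly one observable, pairwise identity.
* **Traits.** Each index is a weighted sum of standardized mean-across-day
  abundances of its linked OTUs plus N(0, sd²) noise; the default panel
  mimics a fermentation/production metabolite layout (VFA ratios, methane,
  amino acids, milk protein, feed efficiency) with one pure-noise control.

What passing tests on these generators show: the estimators recover
planted effects under the model they assume, the permutation and
subset nulls are calibrated, and the pipeline is deterministic. What they
do not show: robustness to real-data features the generators omit —
linkage disequilibrium, library-size and sparsity structure of real OTU
tables beyond presence-zeroing, sequencing noise, diet/batch covariates,
or pedigree errors.

## Problem sizes used in the shipped checks

The property checks run at 297 genotyped animals (11 families of 27),
5,000 SNPs, 500 OTUs × 3 days for the screen, 100 permutations for the
false-discovery null, 100 subset draws for the clade test, and 500 null
fits for LRT calibration — sizes at which the planted signals are
comfortably identifiable and a full run completes in a few minutes on one
CPU.

## Known limitations

* Single-kernel model only: no dominance/epistatic kernels, no
  multi-variance-component or bivariate fits, no GWAS/BLUP.
* The LRT's boundary mixture is asymptotic; at n ≈ 47 (the real study's
  genotyped count) it is noticeably conservative, which is the safe side
  for a screen.
* Heritability estimates on raw relative abundances inherit the
  compositional coupling of the simplex; the screen's conclusions are
  about detection (which OTUs carry a genetic signal), not about unbiased
  h² magnitudes — small-cohort h² magnitudes are wide in any case.
* The aligner is pairwise-only by design: no multiple sequence alignment,
  no tree inference, no UniFrac.
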