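# rumherit

Heritability screening of rumen microbiome OTUs from host SNP genotypes —
for microbiome researchers and animal geneticists who want to ask, on a
modest dairy-cow cohort, *which bacterial taxa does the host genome
influence, and what do those taxa do?*

## The problem and the method

A cohort of Holstein-Friesian cows is 16S-profiled (one OTU table per
animal per sampling day) and a genotyped subset is typed on a dense SNP
chip. After standard chip QC (individual call rate, SNP missingness,
minor allele frequency), pairwise genomic relatedness is estimated as

    A_jk = (1/n) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

the allele-sharing GRM weighted by allele rareness. Each OTU's relative
abundance on each day is treated as a phenotype in the mixed model
y = Xβ + u + ε with u ~ N(0, σu²A), fitted by REML (GREML), giving
h² = σu²/(σu² + σε²) and a boundary likelihood-ratio p-value
(p = ½·Pr(χ²₁ ≥ LR)). An OTU is called **heritable** only when h² > 0.7
and p < 0.05 on *all* sampling days, after a presence filter (detected in
at least 12 genotyped animals). The call count is calibrated by a
permutation null that shuffles the animals' genetic identities and reruns
the whole screen.

Called OTUs are then characterized two ways: their 16S sequences are
tested for phylogenetic clustering (mean pairwise global-alignment
identity versus 100 random same-size OTU subsets, plus Fisher-exact taxon
enrichment), and their abundance profiles are correlated (Spearman)
with rumen metabolites and host traits, with permutation nulls for mean
correlations and a per-index correlation odds ratio
(hc/hn)/(nc/nn) over heritable versus non-heritable OTUs.

A first-class synthetic-data module simulates the whole study — half-sib
sire families and SNPs, planted heritable OTUs with day-replicate
structure, a planted 16S clade, and OTU-linked trait indices — so every
stage is testable at desk scale. See `docs/methods.md` for models,
defaults, and limitations.

## Worked example

Simulate a study-scale herd (300 animals in 11 half-sib families, 5,000
SNPs, 400 OTUs of which 22 are planted heritable at h² = 0.85, three
sampling days) and run the full pipeline:

```yaml
# study.yaml
out_dir: study_run
seed: 11
simulate:
  n_animals: 300
  n_genotyped: 297
  families: [[F01, 27], [F02, 27], [F03, 27], [F04, 27], [F05, 27], [F06, 27],
             [F07, 27], [F08, 27], [F09, 27], [F10, 27], [F11, 27]]
  n_snps: 5000
  n_otus: 400
  n_heritable: 22
  true_h2: 0.85
n_perm_fdr: 100
n_perm_corr: 1000
n_draws_phylo: 100
```

```text
$ rumherit run --config study.yaml
stage=screen otus_after_presence_filter=400
stage=screen consensus_count=16 fdr_fraction_below=1.000
stage=phylo metrics={'observed_mean_similarity': 88.61, 'phylo_p': 0.0099, ...}
stage=associate metrics={'indices_tested': 9}
pipeline complete; manifest at study_run/manifest.json
```

Reading those numbers: the consensus screen called 16 OTUs heritable —
all 16 are planted ones (cross-check `study_run/sim_truth.tsv` against
`study_run/heritable_otus.tsv`: 16 true positives, 0 false positives; the
remaining 6 planted OTUs fell under the h² > 0.7 cut on at least one
day). All 100 genetics-shuffled reruns produced fewer calls than 16
(`fdr_fraction_below=1.000`), so the count is far above its null. The
called OTUs' mean pairwise 16S identity is 88.6%, higher than every one
of 100 random same-size subsets (empirical p = 0.0099 — the add-one
lower bound at 100 draws). The association stage
(`study_run/index_summary.tsv`) finds the planted metabolite linkages:

```text
                   index  mean_abs_r  p_mean_abs_r  odds_ratio  fisher_p
propionate_acetate_ratio       0.143         0.001      11.182     0.001
                 methane       0.149         0.001      20.333     0.000
            milk_protein       0.131         0.001      15.857     0.000
           noise_control       0.051         0.261       1.097     1.000
```

Indices constructed from heritable OTUs show significant permutation
p-values and elevated correlation odds ratios; the pure-noise control
index shows neither.

Each stage is also a standalone command (`rumherit simulate / qc / grm /
h2 / screen / phylo / associate`) over plain-text formats: PED/MAP
(recode12), GCTA-style `.grm.id`/`.grm.gz`, OTU-table TSV, FASTA, trait
TSV — and a Python API mirrors it (`GREML`, `HeritabilityScreen`
estimator classes plus per-module functions).

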