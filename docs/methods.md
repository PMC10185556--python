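# Methods

`admeth` re-implements, as a tested library, the statistical core of an
integrative case/control adipocyte methylome analysis: a two-cohort,
two-depot epigenome-wide association study (EWAS) with meta-analysis and
replication gating, sentinel and differentially-methylated-region (DMR)
calling, matched-permutation enrichment, hierarchical target-gene
assignment with a random-intercept methylation–expression model,
two-sample Mendelian randomisation (MR) with Steiger directionality, and
TF–methylation mediation contrasts. Every stage can be exercised
end-to-end against a synthetic cohort generator that plants known truth.

## Coordinates and containers

All genomic intervals are 0-based half-open internally. CG sites are
width-1 intervals at the cytosine; 1-based positions in TSV matrices are
converted on read and restored on write, while BED is consumed natively.
Strand is ignored for overlap computations (array methylation is
strand-collapsed); gene strand is used only to orient promoter windows
and UTRs. Missing betas are permitted and handled by per-site listwise
deletion; sites with more than 10% missingness in a cohort are dropped
(configurable — upstream detection-p filtering leaves this choice open,
and 10% is conservative).

## EWAS model

Within each cohort, the methylation beta at each site is regressed by
OLS on case status plus age, sex and technical covariates; the case
coefficient is the adjusted case-minus-control difference in methylation
fraction (rendered ×100 as %-methylation in reports). Technical
covariates are the leading principal components of positive-control
probe intensities, keeping the smallest number of PCs explaining ≥95% of
control-probe variance. Quantile normalisation replaces each sample's
sorted values with cross-sample means of order statistics (ties receive
the mean of the reference values their ranks span; samples with missing
values are mapped by quantile interpolation).

Cohorts are combined by fixed-effect inverse-variance weighting:
β̄ = Σwᵢβᵢ/Σwᵢ with wᵢ = 1/seᵢ², se = 1/√Σwᵢ, with Cochran's Q and
I² = max(0, (Q − df)/Q) reported but not used as a gate (no
heterogeneity cutoff is part of the design). Significance requires all
of: discovery FDR < 0.01, replication FDR < 0.01 with a consistent
direction of effect, and combined fixed-effect p < 1e-7 (epigenome-wide
significance). FDR is Benjamini–Hochberg throughout — a deliberate,
parameter-free substitution for q-value estimation; at these thresholds
the two rarely disagree. The combined-p gate uses the fixed-effect IVW
p-value.

## Sentinels, DMRs and sign tests

Epigenome-wide-significant sites ≤5 kb apart on a chromosome are chained
into loci by single-linkage closure (so a chain's ends may be farther
apart than 5 kb); a fixed-window alternative is available behind a flag,
but chaining is the default reading of "within ±5 kb of each other".
The locus sentinel is the minimum-p member, ties broken to the lower
position for determinism. A sentinel is DMR-flagged when ≥5 sites within
±5 kb share its direction at Bonferroni-adjusted p < 0.05; the
Bonferroni denominator defaults to the pooled count of array sites in
all tested windows and is exposed as a parameter, since the adjustment
family is otherwise underdetermined.

Sign tests use an exact binomial with log-space tail summation
(log-gamma pmf terms combined by log-sum-exp), so tails far below the
double-precision underflow limit (~1e-308) remain exact in the log
domain; the two-sided test doubles the smaller tail and caps at 1, which
at p0 = 0.5 coincides with the minimum-likelihood rule by symmetry.

## Matched-permutation enrichment

For each sentinel, 1000 background sites with equivalent methylation
level and variability are drawn from the array: the tolerance ladder
starts at (|Δmean| ≤ 0.025, |Δsd| ≤ 0.0025) and widens by the same
increments until more than 1000 candidates at >5 kb distance qualify,
then exactly 1000 are sampled without replacement from a per-sentinel
stream seeded by (global seed, sentinel index) so sets regenerate
exactly. Matched sites may repeat across different sentinels' sets;
uniqueness holds within a set. Background replicate j is the set of
every sentinel's j-th matched site, so replicates share the sentinel
list's size; empirical p = (1 + #{replicates ≥ observed})/(N + 1) on the
enrichment side (mirrored for depletion, both sides always reported),
alongside a Fisher exact test on pooled counts. GWAS–chromatin-state
overlap uses interval-level semantics (the state interval containing the
sentinel must itself contain a genome-wide-significant SNP); label-level
semantics are available behind a flag. Nearest-gene assignment ranks
promoter > 5′/3′UTR > exon > intron > intergenic, ties to the nearest
then lower-coordinate TSS; pathway counting deduplicates to one sentinel
per gene and one permutation per gene.

## Target genes and expression

TAD input is flattened by deleting intervals strictly nested inside a
larger domain (partial overlaps are kept). Target assignment is
hierarchical and exclusive: genic (exon/UTR/promoter-window overlap,
promoter = TSS ±5 kb), else functional (distal interaction intervals),
else TAD co-membership of gene TSSs.

Methylation–expression pairs are tested on the combined two-depot sample
with a per-participant random intercept absorbing the correlation
between a participant's two depots. The fitter profiles the restricted
likelihood over the single variance ratio λ = σ²ᵤ/σ²ₑ with closed-form
GLS at each λ (for a group of size m the covariance I + λJ has an
analytic inverse and determinant), scanning a log-grid then refining
with bounded scalar minimisation; a cluster-robust OLS fallback is
flagged on numerical failure. At λ = 0 the fit is exactly OLS. Because λ
is estimated with sampling noise, σᵤ = 0 data land on the boundary in
only about half of replicates; the degenerate-limit guarantee is that
boundary solutions equal OLS, which is what the tests assert. Expression
is log2-CPM with a 0.5 prior count; precision weighting (voom-style) is
deliberately out of scope, and the differential-expression table used by
the target-enrichment binomial test comes from a naive per-gene OLS on
logCPM — plumbing standing in for a negative-binomial model, adequate
for rate comparisons at the simulated depths.

## Mendelian randomisation

Instruments are cis-SNPs within ±500 kb of a sentinel regressed on
covariate-adjusted methylation; strand-ambiguous palindromic SNPs with
MAF > 0.42 are removed before testing. Greedy LD clumping walks records
by ascending p and keeps a SNP iff its dosage r² with every kept SNP is
below the threshold (0.01 primary, 0.8 for the correlated-instrument
sensitivity set). Instruments must pass Bonferroni-corrected p < 0.05,
with the denominator the number of in-window SNPs tested for that
sentinel. Estimators: Wald ratio (β_out/β_exp, first-order se) for one
instrument; IVW regression through the origin with 1/se² weights for
several (random-effects variant inflates se by √(Q/df) floored at 1, the
multiplicative convention); MR-Egger (weighted with intercept, exposure
effects oriented non-negative) for three or more, its intercept the
pleiotropy test. Steiger directionality compares Fisher-transformed
instrument–exposure and instrument–outcome correlations for independent
samples: z = (atanh√r²_exp − atanh√r²_out)/√(1/(n_exp−3) + 1/(n_out−3));
r² values come from the t-statistic identity r² = t²/(t² + df) on both
sides. A locus is flagged causal when the MR q-value and the Steiger
q-value both clear FDR < 0.01 with an exposure→outcome direction; MR and
Steiger q-values form separate BH families (a joint-family option is
exposed). Proxy lookup returns the in-window SNP with maximal dosage r²
(≥0.8), flipping the aligned allele when the correlation is negative.

## Synthetic cohort generator

The generator defines the study conditions; downstream tests recover
what it plants.

* **Design.** Two cohorts (discovery, replication); 24 participants per
  case/control arm per cohort, each contributing one subcutaneous and
  one visceral sample — 48 + 48 samples per cohort, matching the scale
  of the emulated study, with participant pairing exercising the
  random-intercept model. Expression counts are generated for the
  replication cohort, mirroring where RNA-seq was available.
* **Methylation.** Baselines are logistic transforms of a three-part
  latent normal mixture (bimodal, array-like marginals). Group, mQTL
  dosage, batch and noise effects add on the beta scale, then clamp to
  [0, 1]. Noise sd is 0.05 at intermediate methylation and shrinks
  toward the boundaries (×(0.25 + 0.75·4β(1−β))), as beta-value
  variability does on real arrays; a warning reports clamping above 1%
  of draws. Per-site variance of real array betas is not part of the
  published record, so these defaults are documented assumptions.
* **Planted effects.** 4% of sites are differential with |shift| ~
  U(0.01, 0.18) and 75% hypomethylated in cases — matching the reported
  median/range and hypomethylation bias — planted at
  intermediate-methylation (0.2–0.8) sites, where most real sentinels
  sit and where the largest shifts survive clamping. Half the effects
  are shared across depots, the rest depot-specific.
* **Genetics.** mQTLs shift methylation 0.05 per allele at MAF ~
  U(0.1, 0.4); each gets a high-LD partner SNP (5% allele flips,
  r² ≈ 0.9) to exercise clumping and proxy lookup. Forward causal chains
  carry SNP→CpG effects jittered ±40% around 0.10 (so multi-instrument
  estimators see a spread of strengths) and a CpG→phenotype effect of
  2.0 phenotype-sd per beta unit; reverse chains give the SNP a direct
  phenotype effect (1.2) with only a weak induced SNP→CpG effect (0.05),
  putting the Steiger comparison firmly on the outcome side. Outcome
  GWAS betas are drawn at se = 1/√(2·maf·(1−maf)·n) on a unit-variance
  phenotype, n = 100,000 by default; null SNPs are pure noise, and a
  constant pleiotropy offset can be added for Egger testing.
* **Expression and mediation.** Counts are gamma-Poisson (negative
  binomial, dispersion 0.05) with log-mean linear in planted methylation
  (−2 log2 units per beta unit), a per-participant intercept (sd 0.5 on
  the log scale), and TF→CpG→target triples with path coefficients
  (a = 0.04 beta per TF-sd, b = −2 log2 per beta, direct c = 0.3).
* **Annotations.** Sites sit 10 kb apart on four chromosomes (so loci do
  not chain accidentally); an "enhancer" track covers planted sites at a
  configurable fold (default 3×) over a 10% background; chromatin states
  tile the genome; TADs tile each chromosome with configurable nesting;
  interactions connect half of the planted, linked sites to their true
  target genes.

What the generator does not emulate: realistic LD beyond the block-wise
partner SNPs, probe chemistry and batch×probe interactions, cell-type
heterogeneity, sex chromosomes, and correlated phenotype GWAS across
traits. Passing recovery tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to every
artefact of real array data.

## Problem sizes used in the shipped checks

The statistical acceptance suite runs: the seven exact binomial
statistics at their published counts; 100 all-null EWAS seeds (5,000
sites, two cohorts of 48+48); five planted-effect EWAS seeds pooled for
2-SE coverage of gate-passing estimates; five enrichment seeds with 100
sentinels × 1000 matched permutations; 100 MR seeds for chain
recovery/direction plus 100 null-trait seeds at 50 instrumented
sentinels; exhaustive binomial-oracle agreement for all n ≤ 60; and 200
random-intercept recovery seeds. These sizes make the whole suite run in
a few minutes while leaving each assertion's sampling error far from its
threshold.

## Known limitations

Voom-style precision weights, negative-binomial differential expression,
colocalisation, weighted-median/mode MR estimators, bump-hunting-style
region tests and cell-composition deconvolution are out of scope. The
mediation contrast reports effect-size attenuation without a formal
indirect-effect test. The mixed-model comparison against a second
independent fitter is covered in the test suite (statsmodels MixedLM as
oracle) rather than shipped as a user-facing sensitivity option.
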