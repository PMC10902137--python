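# Methods

## Scope and model

`germscan` analyses germination-stage drought screens of germplasm panels:
seeds germinated under an osmoticum (15% PEG-6000) and a water control, with
newly germinated seeds counted daily. The analysis chain is

1. germination indices per unit (GR, GE, GI),
2. relative drought indices per genotype×environment (RGR, RGE, RGI),
3. membership-function scoring (DTC → SFV → ASFV), equal-interval
   five-grade classification and screening of highly tolerant genotypes,
4. descriptive statistics, balanced two-way ANOVA, variance components and
   broad-sense heritability,
5. a kinship-controlled mixed-linear-model association scan with a fixed
   −log10(P) ≥ 5 threshold, per-SNP variance explained and haplotype
   contrasts.

## Index definitions and conventions

GR and GE are cumulative germination percentages through the final day and
the energy day (default day 4 of 7). GI = Σ_t G_t/t is unitless. Relative
indices are **ratios of replicate means** (drought mean ÷ control mean per
genotype×environment), not means of per-replicate ratios; this matches the
DTC definition, which divides trait average values. Ratios above 1 are
legitimate (a genotype can germinate better under mild osmotic stress) and
are never clamped.

**Zero control means.** 0/0 and x/0 are undefined; the affected
genotype×environment row is set to missing with a warning and excluded from
all downstream min–max scans and grading. Dropping rather than clamping
keeps the membership scaling honest.

**Replicate-level relative indices.** The genotype×environment ANOVA needs
within-cell replication, but a ratio of means has none. Each drought
replicate is therefore divided by its genotype×environment control mean.
Because the denominator is constant within a cell, the cell means of these
replicate values equal the screening-level relative index, so the two
definitions are mutually consistent; only the within-cell spread (driven by
the drought arm) differs from alternatives such as replicate-wise pairing,
which would impose an arbitrary pairing of drought and control squares.

## Membership-function scoring and grading

DTC_ij = ȳ_ij(drought)/ȳ_ij(control)×100; F_ij is the min–max normalisation
of DTC across genotypes within one environment; ASFV is the mean of the
three trait memberships. Min–max scaling is invariant to positive affine
transforms, so the ×100 in DTC is cosmetic — scoring raw relative indices
gives identical ASFV, which the tests assert.

Degenerate cases: a trait column whose non-missing values are all equal
carries no ranking information and is set to 0.5 everywhere (warned); a
single non-missing value is an error. A genotype missing any trait
membership gets a missing ASFV and is excluded from grading (warned).

Grading cuts the observed ASFV range [min, max] into five equal intervals
labelled HDS, DS, MDT, DT, HDT from low to high. Intervals are
[min+(k−1)w, min+kw) with the **top interval closed** and interior
boundaries belonging to the upper grade — the tie direction is a
convention; it guarantees the maximum is HDT and grade is a monotone step
function of ASFV. Boundaries are carried at full precision; 2-decimal
rounding is display only. Scoring and grading run per environment
independently (environments get distinct schemes), then HDT lists are
combined by union and intersection. Applying a scheme to ASFV values
outside its range clamps to the extreme grades with a warning, supporting
re-use of a scheme on new material.

## Variance analysis and heritability

The balanced genotype×environment model with replication is computed in
closed form (sums of squares over marginal and cell means); the
decomposition is exact and is checked against both a brute-force summation
oracle and statsmodels' `anova_lm`. Unbalanced layouts are rejected rather
than approximated. Variance components invert the expected mean squares:
σ² = MS_res, σge² = (MS_GxE − MS_res)/r, σg² = (MS_G − MS_GxE)/(nr);
negative estimates are clipped to zero with a warning, as usual for
method-of-moments components. Broad-sense heritability is
h² = σg²/(σg² + σge²/n + σ²/(nr)). REML would be preferable for unbalanced
data but the balanced closed form is reproducible and matches the
formula's structure. Skewness and kurtosis use the bias-adjusted sample
formulas (SPSS/spreadsheet convention, excess kurtosis); SD is the n−1
sample standard deviation; CV = SD/mean × 100, undefined for zero mean.

## Mixed-model association scan

Kinship is the VanRaden centred cross-product K = WWᵀ/(2Σp(1−p)) on
MAF-filtered dosages (default MAF ≥ 0.05; the filter level is a design
choice, not a published value). The scan fits
y = Xβ + g·b + u + ε, cov(u) = σg²K, cov(ε) = σe²I, in two steps:

1. **Null fit.** δ = σe²/σg² by REML, profiled on the spectrum of SKS
   (S the covariate-projection complement), optimised on a log grid with a
   bounded refinement — the EMMA construction.
2. **Per-SNP tests.** With δ fixed (population parameters previously
   determined), rotate by the eigenvectors of K; GLS becomes weighted least
   squares with weights 1/(s_i+δ), solved for all SNPs at once by block
   elimination. Wald t tests use n − p − 1 degrees of freedom. With K = I
   the procedure reduces exactly to ordinary least squares, and on small
   instances it matches a dense GLS refit to machine precision (tested at
   1e-6). `per_snp_reml=True` re-estimates δ per SNP model — slower, used
   as a cross-check.

PVE is the likelihood-ratio R² of the SNP term on the decorrelated scale,
which for a Gaussian model equals 1 − RSS_full/RSS_null of the whitened
regressions, reported in percent. Published scans rarely state their PVE
formula; this one is documented here and versioned with the package.

Significance keeps −log10(P) ≥ 5.0 inclusively, with no further
multiple-testing correction by default (an FDR/Bonferroni report can be
derived from the scan table). Haplotype contrasts compare the two
homozygote classes of a significant SNP by one-way ANOVA, excluding
heterozygotes so the contrast is between allele classes; annotation uses
`**` for p<0.01 and `***` for p<0.001.

## Synthetic-data generator

The generator emulates the screening design: 264 genotypes, 2 environments,
control vs drought, 3 replicates of 50 seeds, 7 daily counts, energy day 4.
Genetic signal is a latent drought-response liability

    L_ier = g_i^poly + Σ_c (dosage_ic − 2p_c)·β_c + (gē)_ie + ε_ier

with g^poly ~ N(0, var_genotype), G×E ~ N(0, var_gxe), unit noise
~ N(0, var_residual), and centred causal-SNP dosages entering additively
(matching the additive scan model). Under drought the per-seed germination
probability is expit(logit(p₀) + L) — a logistic link chosen for
boundedness — with p₀ = 0.5; each germinating seed draws its day from
1 + Poisson(max(μ_d − 0.6·L, 0.05)) truncated at day 7, so low-liability
genotypes germinate less *and* later, which propagates into GE and GI.
Control units use probability 0.885 and day mean 1.0 independent of
liability. The defaults p₀ and the control probability mirror the observed
drought/control germination means of such screens (≈50% vs ≈89%); the
liability variances (0.4, 0.3, 2.0) were set so that realized
relative-index heritability falls in the 0.45–0.50 band typical of
germination-stage drought traits (with the five default causal SNPs of
effect 0.4 the genotypic variance rises and h² lands nearer 0.55–0.60).
SNPs are independent biallelic sites with allele frequencies uniform on
[0.05, 0.5]; linkage disequilibrium, population structure and admixture are
deliberately not simulated, and panels are thousands of SNPs, not the
millions of a resequencing map.

What passing tests therefore show: the analysis chain is algebraically
correct, statistically calibrated (uniform null p-values, nominal type-I
error), and able to recover planted signal (variance components within 15%
over 50 runs; a 15%-PVE SNP detected in ≥80% of runs; the HDT screen
enriched for truly tolerant genotypes). What they do not show: robustness
to LD structure, relatedness/stratification, seed-lot quality differences,
dormancy, or counting error in real trials.

## Numerical choices and degenerate inputs

- Germination probabilities are clamped to (1e-9, 1−1e-9); saturation
  warns, or raises under `strict=True`.
- Eigenvalues of K are clipped at zero before weighting; δ is searched in
  [1e-5, 1e5].
- SNPs monomorphic or collinear with covariates after filtering yield
  missing statistics with a warning rather than a crash.
- p-values are floored at the smallest positive float before −log10.
- All simulation randomness flows from one integer seed through named
  `SeedSequence` streams; identical config + seed is bit-reproducible, and
  pipeline outputs are byte-identical across reruns.

## Problem sizes

Default test and demonstration runs use panels of tens to hundreds of
genotypes and 150–2000 SNPs, with the acceptance computation at the full
264×2×3 design, 2000 SNPs, 10,000 null SNP tests and 20 power replicates —
sizes chosen so a complete validation runs in seconds on a single core
while keeping every statistical check at its stated sample size.

## Known limitations

- The equal-interval grading depends on the observed ASFV extremes, so a
  single outlier genotype shifts all boundaries; quantile-based grading
  would be more robust but is a different method.
- Method-of-moments components can be noisy for small panels; no REML
  fallback for unbalanced germination data is currently wired into the
  pipeline stage (the ANOVA rejects unbalance instead).
- P3D holds the variance ratio fixed across SNPs; for very large single-SNP
  effects the Wald p-value is slightly conservative relative to a full
  refit (the `per_snp_reml` flag quantifies this).
- PVE from likelihood-ratio R² is one of several defensible definitions;
  values are comparable within this package, not across tools.
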