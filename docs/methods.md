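# Methods

This note documents the models, conventions and numerical choices behind
`stratgwas`, and what the simulation studies do and do not establish.

## The analysis model

Each variant *j* is tested within each age stratum *s* by ordinary least
squares:

    y_i = α + β_js · g_ij + γ' c_i + ε_i

with `g` the additive dosage (0/1/2 copies of the effect allele) and `c`
the covariates — by default age, sex, genotyping-array indicator and ten
principal components. Age stays in the within-stratum design because age
varies inside each quartile. Complete cases are taken per variant
(individuals missing that variant's call, the phenotype, or any covariate
are dropped for that fit only), so the effective `NMISS` varies across
variants exactly as in PLINK's `.assoc.linear` output. Two-sided p-values
use the t distribution with the residual degrees of freedom; above
df = 10⁴ the standard normal is used (numerically identical there).

Two code paths produce the same numbers: a per-variant least-squares fit,
and a vectorised batch path for fully observed variants that residualises
the phenotype and all dosage columns against the covariates once
(Frisch–Waugh–Lovell) and recovers each β, SE and residual df from dot
products. Their equivalence is property-tested; the per-variant path is
itself checked against statsmodels OLS and textbook normal equations.

### The differential test

Effect sizes estimated in two strata of the same cohort are not
independent: shared environment and shared true signal correlate them,
and ignoring that inflates the null variance of their difference. The
test statistic is

    t = (b1 − b2) / √(SE1² + SE2² − 2 r SE1 SE2)

with a single scalar *r* — the signed Spearman rank correlation of the
two strata's β vectors over all shared QC-passing variants (raw signed
betas, not magnitudes, not a pruned subset) — applied to every variant.
The reference distribution for P_diff is the standard normal: at the
stratum sizes the design targets (tens of thousands) the t and normal
references are indistinguishable, and no degrees-of-freedom convention
for this statistic is standard. P_diff is computed through the normal
survival function and keeps precision down to ~1e-300.

The stratum pair compared is the one with the lowest Spearman
correlation, i.e. the pair carrying the most differential information;
with ties, the widest age gap wins, then lexicographic order. A fixed
pair (e.g. always Q1 vs Q4) can be configured instead — the calibration
and power studies use the fixed youngest/oldest pair so that the quantity
being measured does not depend on which pair noise happens to select.

Before differencing, the two summary-statistic tables are harmonized on
the effect allele: an exact a1/a2 match keeps β, a swapped pair flips its
sign, anything else excludes the variant with a logged count.
Strand-ambiguous (A/T, C/G) variants are not specially removed because
both tables come from one genotype dataset. Significance tiers:
genome-wide at P_diff < 5×10⁻⁸, suggestive at < 10⁻⁶. For replication
exercises against a fixed list of m candidate loci the package provides
the Bonferroni threshold α/m.

Two degenerate conventions: if the corrected variance is zero (possible
only as r → 1 with SE1 = SE2, e.g. comparing a table with itself) and the
betas are equal, t is 0 by continuity; a nonzero difference with zero
variance is an error.

### Variant QC and stratification

A variant is removed iff missing rate > 0.05, or MAF < 0.01, or HWE
exact-test p < 10⁻⁶ — strict inequalities on the removal side, computed
on the full cohort before stratification (a per-stratum mode is not
provided; QC precedes stratification in the design this implements). The
HWE test is the exact conditional test (not mid-p): with the allele
counts fixed, the heterozygote count's conditional distribution is
evaluated in log space (gammaln, normalised by logsumexp) and the p-value
sums all outcomes whose probability does not exceed the observed one,
with a 1e-12 relative tie tolerance. The implementation agrees with an
exact rational-arithmetic enumeration to ~1e-10 relative for every
genotype table with n ≤ 200.

Age strata are nearest-rank (type-1) quantiles of the age vector, with
assignment by age value so equal ages always share a stratum; with
integer ages this makes stratum sizes only approximately equal, mirroring
real biobank quartiles. Fewer than k distinct ages is an error.

### Clumping

LD (r²) is the squared Pearson correlation of dosages over
pairwise-complete individuals, computed from the analysis genotypes (any
genotype matrix, e.g. an external reference panel read from VCF, can be
passed instead). Clumping is two-stage: (1) among genome-wide-significant
variants, iterate in ascending P_diff (ties by variant id, making the
result independent of input row order); the best remaining variant leads
and absorbs all remaining significant variants with r² ≥ 0.1 to it;
(2) leads on one chromosome closer than 250 kb merge transitively into
one locus represented by the smallest-P_diff lead. Surviving loci are
therefore pairwise below the LD threshold and beyond the distance window.
This two-stage rule is this package's definition of "distance between LD
blocks"; an intermediate looser-r² tier used by some annotation platforms
is intentionally omitted because it does not change lead/locus identity
under a 0.1 lead threshold. Note the direction of the parameter effects:
*lowering* the r² absorption threshold or *widening* the merge window can
only reduce the locus count; raising the r² threshold can split loci.

### Report tables

Manhattan tables concatenate chromosomes (numeric labels first, in
numeric order) on a strictly increasing cumulative coordinate and carry
the −log10 threshold lines as metadata. QQ tables plot sorted observed
−log10 p against expected quantiles i/(n+1). The genomic-inflation
λ is median(χ²₁-quantile of p) divided by the exact χ²₁ median
(≈ 0.45494, via `scipy.stats.chi2.ppf(0.5, 1)` rather than the common
0.456 rounding).

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes,
at configurable scale:

* **Genotypes** — biallelic hard calls at HWE: per-variant allele
  frequency uniform on `maf_range` (default 0.01–0.5), dosage
  binomial(2, maf); one synthetic chromosome with fixed 5 kb spacing, so
  a 250 kb clump window spans 50 variants. Optional LD blocks copy a
  source variant's two allele copies into neighbours with a per-allele
  flip probability, giving tunable r²; this is not coalescent-realistic
  LD. Missingness is masked uniformly at `missing_rate` (default 0:
  imputed biobank hard calls are essentially complete after QC; tests
  switch it on explicitly).
* **Covariates** — integer ages uniform on 40–69 by default (an optional
  per-age weight vector reproduces skewed cohort pyramids; the equal-width
  alternative is deliberately simple), sex Bernoulli(0.46 male), array
  Bernoulli(0.5), PCs standard normal.
* **Phenotype** — linear model with per-allele effects that vary linearly
  in age: each causal variant contributes
  `g · (a_j + c_j · (age − age_ref))`, default reference age 55 (the
  cohort midpoint). Linearity is the minimal interaction model consistent
  with monotone quartile-wise effect trends; no sex interaction is
  exposed. Default covariate effects sketch a standardized anthropometric
  trait: age 0.02/yr, sex 0.1, PCs 0.05 each, array 0, noise SD 1.
  Missing dosages contribute the variant's mean dosage to the generative
  model (a documented choice that keeps the model defined under
  missingness; the *analysis* never imputes).

The generator also derives BMI (= weight/height², kg/m²) and WHR
(= waist/hip circumference) from raw measurements, and emits a truth
table of exactly the effects applied, for recovery tests.

What passing tests on this cohort do **not** show about real data:
no realistic LD structure or allele-frequency spectrum, no population
stratification beyond Gaussian PCs, no relatedness, no non-linear or
sex-specific interactions, and phenotype noise is homoscedastic Gaussian.
Calibration and power results transfer to real cohorts only to the
extent these assumptions hold.

## Simulation studies and problem sizes

* **Type-I error** (`calibration.null_calibration`): 4,000 individuals ×
  20,000 null variants (covariate effects on), quartile strata, Q1 vs Q4.
  Checks that the P_diff rejection rate at 0.05 is within ±0.005, that a
  KS test against Uniform(0,1) does not reject at α = 0.01, and that
  λ ≈ 1. These sizes give a null Monte-Carlo SD of ~0.0015 on the
  rejection rate while keeping the study around half a minute on one CPU.
* **Power** (`calibration.power_study`): one planted variant with zero
  effect at the reference age and an age slope sized analytically for a
  target power — noncentrality z_{α/2} + z_{power} ≈ 6.73 for 90% power
  at 5×10⁻⁸, which at n = 4,000, k = 4, MAF 0.3, noise SD 1 works out to
  ≈ 0.02 trait units per allele per year, a plausible interaction
  magnitude. Across 20 seeded replicates the study reports the
  genome-wide recovery rate and whether the planted variant leads its
  clump whenever significant. By default the planted variant has no LD
  buddies: a near-copy carrying essentially the same signal can
  legitimately out-rank the causal variant by sampling noise, which would
  conflate "locus recovered" with "exact variant leads".

## Reproducibility

One master seed lives in the pipeline config. Every stochastic stage
derives a sub-seed by folding the SHA-256 hash of its stage name with the
master seed (kept below 2³¹), so any stage reruns identically in
isolation and two runs with the same config are byte-identical on disk.

## Other conventions and limitations

* Coordinates are 1-based (VCF); chromosome labels are never normalised.
  The effect allele is ALT throughout; dosage coding is never flipped
  internally (minor/major relabelling is a reporting concern).
* Summary statistics are tab-separated (CHR SNP BP A1 A2 NMISS BETA SE
  STAT P) with reals in 6-significant-digit scientific notation, so
  round trips are loss-free to printed precision; the space-aligned
  print format of other tools is not emitted.
* Multi-allelic VCF records are rejected, not split; dosage (non-hard-
  call) genotypes, BGEN/PLINK binary inputs, phased data, mixed models,
  logistic traits and X-chromosome handling are out of scope.
* Variants monomorphic within a stratum are emitted flagged (NaN
  statistics) rather than dropped, keeping stratum files row-aligned.
* No genomic-control correction is applied to per-stratum results; λ is
  reported as a diagnostic only.
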