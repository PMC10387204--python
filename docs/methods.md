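# Methods

## The model

`gwsub` derives GWAS summary statistics for a *paternal* phenotype from two
GWASs that were both run on the index person's (the "child's") genotype: a
GWAS of the child's own phenotype and a GWAS of the maternal phenotype as
reported for the child. Writing `b_CG_CP`, `b_CG_MP`, `b_CG_FP` for the
per-SNP associations of the child genotype with the child, maternal and
paternal phenotypes, two facts of autosomal inheritance drive the model:

1. a child's per-allele genetic effect is the average of the parental
   effects, `b_CG_CP = (b_FG_FP + b_MG_MP) / 2`;
2. a child's genotype correlates 0.5 with each parent's genotype, so the
   child-genotype/parent-phenotype association is half the within-parent
   association: `b_CG_FP = 0.5 * b_FG_FP` and `b_CG_MP = 0.5 * b_MG_MP`.

Combining these gives the weighted linear model (WLM)

```
b_CG_FP = b_CG_CP - b_CG_MP
se(b_CG_FP) = sqrt(se(b_CG_CP)^2 + se(b_CG_MP)^2)
```

applied per SNP after allele harmonization. The SE formula is error
propagation for a difference of *independent* estimates; see "Known
limitations" for what happens when the two input GWASs share samples.

Assumptions worth stating explicitly: the same per-allele trait
architecture in parents and offspring (fact 1); random mating (fact 2 — the
0.5 child-parent genotype correlation); and no dynastic/indirect effects
contaminating the child GWAS. None of these is testable from summary
statistics alone; the model is implemented as stated.

## Units

Subtraction requires both inputs on one scale. The package tracks an
effect-scale label (`linear`, `log-odds`, `SMD`) on every table and
converts:

* continuous traits: divide beta and SE by the phenotype SD → SMD;
* 0/1 traits analysed with a linear model: divide by `p(1-p)` (`p` =
  prevalence from case counts) → log odds, then by `pi/sqrt(3)` (the SD of
  the standard logistic distribution) → SMD.

All conversions divide beta and SE by the same constant, so z-scores and
p-values are invariant; conversions refuse mismatched scale labels unless
forced. The `pi/sqrt(3)` constant is computed at full floating precision.

## Monte-Carlo validation (`gwsub.simulation`)

One replicate simulates `n` trios at a single locus: transmitted alleles
`F_i, M_i ~ Bernoulli(maf)` (default maf 0.5), child genotype
`C_g = F_i + M_i`, a weight `W ~ N(1, 0.006^2)` (the second parameter is
treated as an SD, matching the R `rnorm` convention; a
`variance_parameterization` switch covers the other reading), and
phenotypes `C_p = C_g W + e`, `M_p = (M_i + M_nt) W + e`,
`F_p = (F_i + F_nt) W + e` with `e ~ N(0,1)` and independent Bernoulli(maf)
non-transmitted alleles. The estimand is `0.5 W`. Two estimators are
compared per replicate: the direct OLS of `F_p` on `C_g` (what a real
paternal GWAS would do) and the WLM difference of the `C_p` and `M_p`
slopes. Reported performance measures are the mean bias, its Monte-Carlo
standard error `sd(bias)/sqrt(reps)`, and the normal 95% CI.

Defaults are `n = 10,000`, `reps = 1,000`: with these, both estimators'
mean biases are zero to ~0.001 with a CI half-width of ~0.001-0.002, the
precision at which the study's conclusions (both estimators unbiased; WLM
comparable to a direct GWAS) are stated. Regressions include an intercept
(phenotypes are not centred). One master seed spawns independent
per-replicate substreams, so results are reproducible and order-independent.

`run_grid` repeats the study over fixed (W, maf) grids, holding W fixed
within a cell and letting maf drive all four allele draws. The natural
grid would be the per-SNP betas and frequencies of a real smoking GWAS's
genome-wide significant hits; since the package ships no external data,
the default 6x6 grid instead uses six-point summaries of a plausible
effect/frequency range (W in {0, 0.01, 0.02, 0.05, 0.5, 1}; maf in
{0.05, ..., 0.5}). Unbiasedness of the WLM is parameter-free, so the grid
checks the property across the design space rather than specific values.

## Quality control

`genomic_inflation` is the classic median-based factor
`lambda_GC = median(z^2) / 0.4549...` (the chi-square(1) median). On a
table of `m` null SNPs the sampling SD of lambda is roughly `2.35/sqrt(m)`,
which is why the synthetic null benchmark uses 20,000 SNPs (SD ~0.017).
`qq_manhattan` writes the standard observed-vs-expected `-log10 p` QQ plot
and a Manhattan plot with the 5e-8 genome-wide line.

## MR validation (`gwsub.mr`)

Instrument selection at p < {5e-6, 5e-7, 5e-8} (primary 5e-6), winner's-
curse correction by FDR inverse quantile transformation (FIQT: replace each
z by the normal quantile of its Benjamini-Hochberg-adjusted two-sided p;
applied genome-wide *before* selection so the multiplicity is the full
scan; selection itself uses unadjusted p, estimation uses adjusted betas —
both switchable), greedy clumping (r² > 0.001 within 10,000 kb of a
lower-p index SNP removes a variant; ties on p broken by chromosome,
position, SNP id), harmonization with the outcome GWAS (palindromic SNPs
resolved by allele frequency with a configurable ambiguity band, default
(0.30, 0.70), the common two-sample-MR convention), and IVW with
multiplicative random effects:

```
beta = sum(w bx by) / sum(w bx^2),  w = 1/se_y^2
Q    = sum(w (by - beta bx)^2)
se   = max(1, sqrt(Q/(k-1))) * sqrt(1/sum(w bx^2))
```

The residual scale is floored at 1 (no credit for underdispersion); with
k = 1 the estimate is exactly the Wald ratio. Instrument strength is
`mean F = mean((beta/se)^2)`, computed on the FIQT-adjusted instruments
actually used. LD comes either from a reference genotype panel (squared
Pearson correlation of allele counts) or a precomputed long-format r²
table; SNPs absent from the LD source are treated as independent with a
warning (`strict` mode errors instead).

## The synthetic benchmark (`gwsub.synth`)

The generator emulates the study's data situation end to end: trios under
Mendelian transmission at many loci, three GWASs on the child genotype
(child phenotype, maternal phenotype, binary paternal outcome), an LD
table, and known truth. Design choices:

* **Disjoint subcohorts.** The three GWASs are scanned on disjoint sets of
  `n = 6,000` trios each. If they shared individuals, the polygenic
  background would correlate the child- and maternal-GWAS errors and the
  propagated SE would overstate the derived GWAS's noise (lambda_GC well
  below 1); disjoint scans match the independence assumed by both the SE
  formula and the two-sample MR design.
* **LD blocks.** SNPs come in 5-SNP blocks: each haplotype's member allele
  copies the block head with probability 0.9, giving head-member genotype
  correlation 0.9 and member-member 0.81, with constant allele frequency
  within a block. This makes the marginal (GWAS-visible) effect of a null
  neighbour of a causal head analytically `0.9 * W`, which the truth file
  records (`eff_w`), and gives clumping real correlations to prune.
  Positions sit every 10 kb on up to 22 synthetic chromosomes.
* **Effect sizes.** 20,000 SNPs, 6 causal block heads with |W| uniform in
  [1.1, 1.6] and random sign, frequencies in [0.2, 0.5]. These weights are
  deliberately large: they place the causal SNPs' derived-GWAS z-scores
  near 10, comfortably past the 5e-6..5e-8 selection thresholds, in the
  regime where the FIQT correction is mild and MR parameter recovery is
  identifiable at desk-scale n. A real polygenic trait has hundreds of
  far smaller effects; what the benchmark preserves is the *pipeline
  geometry* (selection, curse correction, clumping, harmonization,
  ratio estimation), not a realistic per-SNP heritability.
* **Outcome.** Binary, `Bernoulli(expit(alpha + gamma * F_p))` with
  gamma = 0.15 per phenotype unit in the causal scenario (0 in the null)
  and the intercept solved numerically so prevalence is exactly 0.30. The
  outcome GWAS is emitted on the linear scale with case counts in the
  metadata, exercising the linear → log-odds → SMD chain. The metadata
  also records the generator-implied causal slope on the scale the MR
  stage estimates (log odds per exposure SD), computed from the simulated
  outcome cohort itself.
* **Truth.** Per SNP, the derived-GWAS estimand `0.5 * eff_w` in raw and
  SMD units; the SMD divisor is the population phenotype SD
  `sqrt(sum(W^2 2 maf (1-maf)) + 1)`, stored in the metadata and playing
  the role of the externally supplied trait SD.
* **Bernoulli draws** threshold 16-bit uniforms, so realised frequencies
  are exact to 2^-16 — invisible next to sampling noise, and fast enough
  to draw ~1.5e9 alleles per bundle in seconds.

What passing tests on this generator do *not* show: robustness to
assortative mating, dynastic effects, population stratification, sample
overlap between exposure and outcome GWASs, realistic LD/MAF spectra, or
imputation artifacts. None of these are simulated.

## Numerical choices and degenerate inputs

* p-values for derived tables are always recomputed as `2(1-Phi(|z|))`
  and clipped into `(0, 1]` at the smallest positive double, keeping beta,
  se, z and p mutually consistent.
* A perfectly fitting SNP in `gwas_scan` (zero residual) gets its SE
  floored at the smallest positive double rather than zero, so the record
  stays valid.
* Records violating invariants (non-positive SE, identical or multi-base
  alleles, out-of-range frequencies or p-values, duplicate ids, unparseable
  numerics) are dropped with a categorized logged count; missing mandatory
  columns are hard errors.
* Palindromic SNPs with a missing allele frequency cannot be inferred and
  are dropped under `infer`.
* The derived GWAS reports `n = min(n_child, n_maternal)` as its headline
  sample size (no effective-n is defined for a WLM difference) and keeps
  both inputs as `n_child`/`n_maternal`.
* `sigma` in the IVW fit is floored at 1; `Q` uses k-1 degrees of freedom;
  single-instrument analyses fix sigma = 1.
* With one simulation replicate the Monte-Carlo SE is undefined and
  reported as missing rather than zero.

## Problem sizes

Shipped defaults are sized for an ordinary workstation: the bias study
(1,000 x 10,000) runs in a few seconds; the 6x6 grid in about a minute; a
full benchmark bundle (18,000 trios x 20,000 SNPs) in about half a minute;
the 20-seed null-calibration loop uses 4,000-SNP bundles. All sizes are
arguments, so any of them can be scaled up.

## Known limitations

* The SE propagation assumes independent input GWASs. With overlapping
  samples the derived SEs are conservative or anticonservative depending on
  the sign of the error correlation; the package neither detects nor
  corrects this.
* lambda_GC is reported as a point estimate only; no standard error is
  attached.
* FIQT over-shrinks borderline instruments (z near the selection
  threshold); the benchmark sidesteps this by design, real analyses cannot.
* The MR stage implements IVW with multiplicative random effects only — no
  MR-Egger, weighted-median or multivariable extensions, and no
  correlated-instrument corrections beyond clumping.
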