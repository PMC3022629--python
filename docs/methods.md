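# Methods

## Model

For one transcript probe and one SNP, expression `y` (an already-normalized
array intensity, unitless) is regressed on a numeric genotype coding `x` by
ordinary least squares, `y = α + βx + ε`. The coding depends on the genetic
model, always relative to the minor allele of the *analyzed* sample set
(post merging and filtering, not the whole file):

| model | regressors | test |
|---|---|---|
| additive | minor-allele count 0/1/2 | Wald t = β̂/se, t(n−2) |
| dominant | 1{≥1 minor allele} | same |
| recessive | 1{2 minor alleles} | same |
| genotypic | additive count + 1{heterozygote} | joint F(2, n−3) of both terms |

The genotypic parameterization is the additive-plus-dominance-deviation
(ADD + DOMDEV) convention used by standard quantitative-trait association
tools; the reported β/se under that model belong to the additive term while
the p-value comes from the 2-df joint test. p-values use the exact t / F
reference distributions rather than the asymptotic normal; at the sample
sizes involved (tens to hundreds) the difference is negligible but the t
form is the convention of the tooling this workflow mirrors.

Assumptions: independent individuals, homoskedastic Gaussian residuals, no
covariates and no population-stratification adjustment — even for pooled
multi-population analyses. The last point is a deliberate mirror of the
workflow this package reimplements and is the main caveat for pooled runs:
population differences in both allele frequency and mean expression can
confound pooled associations.

## Workflow and data handling

A run proceeds: read PED/MAP → extract the region (inclusive endpoints) or
SNP list → optional population filter → founder filter (on by default) →
per-probe merge with the expression table → per-SNP regression → p-value
adjustment → tables, bedGraph tracks and a log. The founder filter keeps
exactly the individuals whose parental IDs are both "0"; in the emulated
HapMap phase II design (CEU 30 trios, CHB 45 unrelated, JPT 45 unrelated,
YRI 30 trios) it reduces 270 individuals to 210, removing the statistical
dependence between trio parents and children. Founders-only is the default
even when a single trio population is selected; `--all-samples` overrides
it, with the caveat that related individuals violate the independence
assumption.

Merging intersects genotyped and expression-profiled individuals, keeping
genotype order and logging drop counts on each side; individuals missing
from either source are silently excluded (with a logged count) rather than
imputed. Missing genotypes are excluded per SNP (complete cases per SNP,
not listwise), so n varies across SNPs within one table.

Gene symbols match case-insensitively and exactly; no alias or identifier
resolution is attempted. Each probe of a multi-probe gene is a separate
analysis with its own output files and its own adjustment family.

## Multiple testing

Five procedures: Bonferroni, Holm (step-down), Šidák (single-step,
1−(1−p)^m), Benjamini–Hochberg and Benjamini–Yekutieli. The family size m
counts the non-degenerate SNPs of one probe's scan; degenerate SNPs stay NA
through adjustment. The arithmetic is statsmodels'
`multipletests`, wrapped with validation and NA masking; the test suite
verifies every method to 1e-12 against step-procedure formulas coded
independently from their published definitions, plus the dominance
orderings (Bonferroni ≥ Šidák ≥ raw, Bonferroni ≥ Holm ≥ raw,
BY ≥ BH ≥ raw). Šidák is single-step because the step-down variant is a
different procedure and the single-step form is the common default.

## Numerical and degenerate-case choices

* Minor-allele ties (frequency exactly 0.5) break toward the alphabetically
  first allele symbol, making codings deterministic.
* Monomorphic SNPs, all-missing SNPs, constant codings, and genotypic
  designs with fewer than three observed genotype classes are *degenerate*:
  they yield NA rows, are excluded from m, and are omitted from tracks
  (plotting them at score 0 would fake a null result).
* A perfect fit (residual sum of squares ≤ 1e−24 of the total sum of
  squares, i.e. only floating-point rounding left) reports se = 0, an
  infinite statistic and the p floor 1e−300 instead of dividing by zero.
  All finite p-values are also floored at 1e−300.
* Track scores are −log₁₀ p capped at 50 by default (`--cap`); positions
  convert from 1-based MAP coordinates to UCSC's 0-based half-open
  single-base intervals. bedGraph was chosen over wiggle because per-SNP
  scores are sparse and irregularly spaced.
* Tables print 6 significant digits (p in scientific notation, "NA" for
  missing), so files parse back losslessly to printed precision.
* Half-missing calls ("A 0") are a parse error, not coerced to missing:
  silent coercion would shift allele frequencies. The missing code is "0"
  for both alleles. Sex chromosomes are treated as diploid autosomes and
  flagged with a warning; MAP rows with negative positions are dropped
  with a warning (the conventional exclusion flag).

## Synthetic data generator

`simdata` emulates the sampling design the workflow targets: four
populations, two collected as parent–parent–child trios, 270 individuals
with 210 founders by default. Founder genotypes are independent draws under
Hardy–Weinberg equilibrium at each SNP's configured MAF; children receive
one uniformly chosen allele from each parent. Expression is
`β·coding(causal SNP) + N(0, σ)` per individual; probes of one gene share
the genetic effect and draw independent noise. Defaults used by the
calibration experiments: MAF 0.3, noise sd 1 (recovery) or 0.5 (detection),
effect sizes β = 0.5–1 — magnitudes typical of strong cis-eQTLs on
normalized intensity scales.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent; an optional block-copy helper `add_ld_proxies` duplicates a
SNP with flip noise as a visualization aid, not a coalescent model),
population divergence in allele frequency or expression, probe
cross-hybridization, and non-Gaussian expression distributions. Passing
tests therefore demonstrate correctness of the statistics and plumbing on
idealized data, not robustness to real-data artifacts such as
stratification or batch effects.

## Calibration experiments and problem sizes

`eqtlscan.experiments` measures, through the package's own code path:
type-I error per model (5,000 null SNPs, n = 100, MAF 0.3, α = 0.05 —
binomial standard error ≈ 0.003); additive-β recovery (500 replicates at
n = 500, true β = 0.5); and end-to-end detection of one causal SNP among
20 nulls across 50 seeded pipeline runs that go through the on-disk
formats. These sizes give tight Monte-Carlo error while keeping the whole
experiment battery under a minute; the same functions accept larger sizes
for finer calibration.

## Known limitations

* No covariates, kinship/mixed models, permutation p-values or interaction
  terms; pooled analyses are unadjusted for stratification.
* Text PED/MAP only (no binary BED/BIM/FAM, no VCF), no genome-build
  liftover, no LD computation.
* Expression values are used as provided; normalization is upstream. The
  per-population vs pooled normalization distinction is handled by pointing
  the run at different input tables, not recomputed.
* Haploid male X is not modeled; X/Y SNPs are analyzed as diploid with a
  warning.
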