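# Methods

This note documents the models behind `cytogen`, the defaults that matter,
what the synthetic-data generator does and does not emulate, and the
numerical and design choices that were genuinely open.

## Generative model for summary statistics

Individual-level genotypes are never simulated. Each trait × cohort GWAS is
drawn directly at the summary level under the RSS (regression with summary
statistics) model: with R the signed LD matrix of a region and b the joint
causal effects on the standardized-genotype scale,

    z ~ MVN( √n · R b ,  R ).

The marginal expectation of z at variant j is √n·(Rb)ⱼ — LD applied once to
the joint effects. Per-allele betas and SEs follow deterministically,
β = z/√(2f(1−f)(n+z²)) and SE = 1/√(2f(1−f)(n+z²)), so the simulator
produces exactly the quantities the downstream code consumes, and a
cohort's z and its reconstructed β/SE are consistent by construction.

One MVN draw is taken per LD block per trait per cohort, using a single
Cholesky factor of R (ridge 10⁻⁸ on the diagonal only if factorization
fails). Blocks are disjoint with zero cross-block LD, one block per
simulated gene region (default 200 variants at 2 kb spacing).

**Heterogeneous LD.** Blocks are AR(1) with ρ varying linearly from
`ar1_rho_min` (0.3) to `ar1_rho` (0.9) across gene regions. Two reasons:
real genomes have region-to-region LD variation, and a single AR(1) profile
makes interior LD scores essentially constant, leaving the LD-score
regression slope unidentified (pre-build simulation: sd(ĥ²) ≈ 0.2 under
constant ρ vs ≈ 0.055 under the heterogeneous design at M = 5000,
n = 20 000).

**Alleles and frequencies.** Variants are biallelic A/G with a 5%
palindromic A/T fraction (to exercise harmonization); alleles and
effect-allele frequencies (uniform on [0.05, 0.5], minor-allele
orientation) are drawn once per panel and shared by every trait and cohort
— alleles are properties of the variant, not the trait.

**Cohorts.** Default sample sizes 11 000 / 21 000 / 35 000 mirror the
order-of-magnitude imbalance of an immunoassay cohort, an Olink cohort and
a SomaScan cohort. Cohorts share no samples (the LDSC cross-trait intercept
then has expectation ≈ 0) and share the same LD and frequencies
(single-ancestry assumption). Assay heterogeneity is planted through
per-cohort multiplicative effect rescalings (`assay_shift`) and
cohort-restricted effects (`cohort_specific`); with neither, Cochran's Q is
exactly χ²ₖ₋₁-calibrated (verified).

**Causal links.** A cytokine→cytokine effect θ is realized by planting an
effect θ·b_cis on the *donor's* cis causal variant in the recipient's
architecture: a mediated effect makes the recipient's marginal betas
proportional to the donor's across the donor's whole LD block, which is
precisely the relationship MR assumes. Disease GWAS are emitted on the
per-allele log-odds scale, β_Y ~ N(θ·β_X,allele, SE²) with
SE = 1/√(2f(1−f)·n_eff), n_eff = 4/(1/n_cases + 1/n_controls), and
LD-correlated noise; the per-allele ratio β_Y/β_X equals θ at every
instrument.

**What the generator does not emulate.** Covariate structure (absorbed into
the standardized-trait model), imputation quality, allele-frequency
differences between cohorts, sample overlap, strand errors beyond clean
complements, population stratification, winner's-curse-inducing
two-stage designs. A green recovery test therefore establishes correctness
of the estimators *under the stated model*, not robustness to those
real-data pathologies.

## Meta-analysis

Weights √nᵢ (sample-size scheme); the cohorts' assay scales are
incompatible, so no effect-size meta-analysis is offered. Direction strings
use METAL conventions ('+', '-', '0', '?' per cohort in fixed order).
Variants present in one cohort are retained with k = 1 and undefined Q.
Heterogeneity is computed on per-cohort *reconstructed* standardized betas
(each cohort's own z, EAF, N), putting all assays on one scale first; under
the null this makes Q exactly χ²ₖ₋₁. λ uses the true χ²₁ median
(scipy's `chi2.ppf(0.5, 1)` ≈ 0.454936), so λ = 1 exactly when every
p = 0.5. Two-sided p-values throughout; quantiles via `norm.isf`, which is
accurate to the smallest positive double (the documented floor for
`z_from_p`).

## Loci

Clumping is greedy (provably equal to exhaustive greedy selection; tested
against a brute-force oracle on all instances ≤ 12 variants): ties on p
break by (chrom, pos). The clumping window is ±1 Mb — published pipelines
typically name only r² thresholds, and 1 Mb matches the locus rule. Locus merging is
transitive/chained (nearest-neighbour reading of "separated by more than
1 Mb"). Cis windows are closed intervals, gene ± 300 kb. Replication
denominators exclude variants absent from the target cohort's panel by
default (`drop_missing=False` counts them as failures instead).

## Fine-mapping

Deliberately a single-causal-variant model — not a multi-effect (SuSiE-type)
procedure. Wakefield's ABF per variant, flat causal prior across the locus,
PIPs normalized in log space, minimal-prefix credible set with ties broken
by position. Prior effect SD W^½ = 0.15 for quantitative traits, 0.2 for
binary (coloc conventions). Loci with several independent signals get sets
concentrated on the strongest signal; set sizes are emitted so the pipeline
can tabulate ranges. Coverage of the 95% set under the stated model,
b = 0.08 at n = 30 000 in a ρ = 0.9 block, measured ≈ 100% over 500 seeds.

## LD-score regression

Weighted least squares of χ² on nℓ/M (free intercept), with a two-pass
weighting: an initial 1/ℓ fit gives a slope guess, then exactly one refit
with model-implied variance weights 1/[2ℓ(1 + nĥ²ℓ/M)²] (cross-trait
analogue for z₁z₂). No iteration to convergence — that is the full extent of
the deliberate divergence from the reference tool. SEs by delete-a-block
jackknife over 20 position-contiguous blocks; rg's jackknife re-derives the
h² denominators per leave-out for a consistent ratio. rg is emitted only
when both ĥ² > 0; otherwise status `undefined_h2` (never a crash), and
|rg| > 1.25 is flagged. Sparse (single-causal) architectures genuinely
carry little LD-score information and typically return `undefined_h2`;
the demo pipeline shows this honestly.

## Mendelian randomization

Instrument minima: Wald 1, IVW 2 (single-instrument input falls back to
Wald with a log note), Egger 3, weighted median 3 — the conventional
minima. Egger orients rows to β_X ≥ 0 before the weighted fit
and uses t inference on n−2 df. The weighted median interpolates the
0.5-quantile of ratio estimates under normalized β²_X/SE²_Y weights; its SE
is a seeded parametric bootstrap (200 replicates, seed recorded via the
run configuration). The network analysis excludes any variant appearing in
both the exposure's and the outcome's own cis instrument lists (so no
variant instruments two cytokines at once); Steiger filtering drops strict
|β_Y| > |β_X|. FDR families: all ordered pairs of one network run; all
cytokine × disease tests of one screen (per-disease available by grouping).
A heterogeneity-sensitivity re-run (`het_exclude`) drops instruments with
meta HetPval < 0.05. Sensitivity estimates carry a
directional-concordance flag against the pair's primary estimate.

## Colocalization

Enumeration under one causal variant per trait. All sums in log space;
L3 = L1·L2 − L4 is evaluated as a guarded log-difference and falls back to
the exact pairwise double loop when the two terms agree within 0.1 nats
(regions ≤ 2000 SNPs; larger cancellation-prone regions raise). Priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵; the colocalization call is strict PP4 > 0.8,
with sub-threshold PP4 still reported. Agreement with exhaustive
configuration enumeration is exact to 10⁻¹⁰ in relative log posterior on
small regions (tested).

## Pipeline

Stages run in fixed order, each reading only prior-stage TSVs; every
filtered record increments a logged counter. The manifest stores the
package version, seed, a SHA-256 of the serialized configuration and
per-stage row counts — nothing time-dependent, so equal seeds give
byte-identical output trees. The report's cis-vs-trans effect-size
comparison uses a two-sided Mann–Whitney test; MAF-vs-|β| association is a
Spearman
rank correlation over locus leads; the pleiotropy histogram merges lead
positions across traits with the same 1 Mb chaining rule and can exclude a
configured HLA-like interval. The upstream-regulator integration is two
TWAS-MR runs (eQTL→cytokine, eQTL→disease) joined on gene id — no new
statistics.

## Known limitations

- Single-causal fine-mapping understates credible-set sizes at
  multi-signal loci.
- The weighted-median bootstrap ignores instrument selection, slightly
  understating its SE under winner's curse.
- LDSC at desk scale (thousands of variants) has wide jackknife SEs; the
  recovery guarantees hold for polygenic architectures at M ≈ 5000.
- Replication rates in the default demo are near 1.0 because no assay
  noise is planted there; plant `assay_shift`/`cohort_specific` entries to
  generate realistic replication failure.
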