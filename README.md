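# cytogen

Statistical-genetics toolkit for circulating-cytokine protein QTLs: it takes
multi-cohort GWAS summary statistics for a panel of cytokines and carries
them through the full inference chain used in pQTL atlas studies —
cross-assay replication, sample-size-weighted z-score meta-analysis with
standardized-beta reconstruction, LD clumping and independent-locus calling
with cis/trans labels, credible-set fine-mapping, LD-score regression
genetic correlation, cis-instrument two-sample Mendelian randomization
(cytokine→cytokine network, cytokine→disease screen, eQTL-exposure TWAS-MR),
and Bayesian colocalization.

Real cohort downloads are not required: a seeded generator simulates the
whole world — three cohorts with very different sample sizes and partially
overlapping panels, LD-structured summary statistics with planted cis and
trans effects, binary-disease GWAS with configurable causal cytokine
effects, and cis-eQTL exposure sets — so every estimate can be checked
against a known truth. It is aimed at methodologists and students who want
a compact, fully inspectable implementation of this pipeline.

## The statistics

**Meta-analysis.** Per-cohort signed statistics combine as
z_meta = Σᵢ √nᵢ zᵢ / √(Σᵢ nᵢ) (METAL's SAMPLESIZE scheme; the cohorts' assay
scales are incompatible, so effect-size meta-analysis is not used).
Standardized effects are reconstructed from z, effect-allele frequency f and
total N:

    β̂ = z / √(2f(1−f)(N + z²)),  SE = 1 / √(2f(1−f)(N + z²))

Heterogeneity is Cochran's Q on per-cohort reconstructed betas; inflation is
λ = median(χ²)/median(χ²₁).

**Loci.** Greedy clumping (smallest p first, absorb r² ≥ threshold within a
window), chained merging of leads within 1 Mb, cis iff the lead is within
±300 kb of the trait's encoding gene.

**Fine-mapping.** Single-causal-variant model with Wakefield's approximate
Bayes factor, log ABF = ½[log(V/(V+W)) + z²·W/(V+W)]; PIPs are normalized
ABFs and the 95% credible set is the minimal descending-PIP prefix.

**LDSC.** E[χ²ⱼ] = 1 + n·h²·ℓⱼ/M with ℓⱼ = Σₖ r²ⱼₖ; cross-trait
E[z₁ⱼz₂ⱼ] = √(n₁n₂)·ρ_g·ℓⱼ/M + intercept; rg = ρ_g/√(h²₁h²₂), withheld with
an explicit `undefined_h2` status when either ĥ² ≤ 0. Block-jackknife SEs.

**MR.** Cis instruments (gene ± 300 kb, p < 5×10⁻⁵, clumped at r² < 0.1;
r² < 0.01 for eQTL exposures), harmonized to a shared effect allele;
fixed-effects IVW as primary, MR-Egger and the weighted median as
sensitivity analyses, Steiger filtering (drop |β_outcome| > |β_exposure|),
Benjamini–Hochberg FDR per analysis family.

**Colocalization.** Per-SNP ABFs for both traits, enumeration posteriors
PP0–PP4 over the five causal configurations with priors
(p1, p2, p12) = (10⁻⁴, 10⁻⁴, 10⁻⁵); colocalized iff PP4 > 0.8.

## Worked example

```bash
cytogen run --seed 5 --out demo_out
```

runs the demonstration world (3 cohorts of 11 000 / 21 000 / 35 000
samples, 8 cytokines on 200-variant gene blocks, 2 diseases; planted truths:
every cytokine has a cis effect of 0.15, CYT1 raises CYT2 with effect 0.4
per SD, CYT3 raises disease DIS1 with log-OR 0.3 per SD) and prints

```
pipeline complete; report at demo_out/report/summary.json
MAF-vs-|beta| Spearman rho = -0.795
```

`demo_out/report/summary.json` then contains (seed 5):

- `locus_counts` — one cis locus per cytokine plus one trans locus for CYT2
  (the planted CYT1→CYT2 link surfacing at CYT1's gene), e.g.
  `"CYT2": {"cis": 1, "trans": 1, "total": 2}`;
- `maf_beta_spearman` — `{"rho": -0.795, "p": 0.010, "n": 9}`: rarer lead
  variants carry larger effects, the usual selection-driven pQTL pattern;
- `network_edges` — `{"tested": 56, "significant": 1, "positive": 1}`: of
  the 8×7 ordered cytokine pairs only the planted CYT1→CYT2 edge survives
  FDR (its reverse is removed by Steiger filtering and lack of signal);
- `screen_hits` — `{"tested": 16, "significant": 1, "positive": 1}`: the
  planted CYT3→DIS1 effect, reported as an odds ratio per SD with 95% CI in
  `mr/screen.tsv`;
- `coloc` — `{"tested": 1, "colocalized": 1}`: the CYT3~DIS1 signal shares
  one causal variant, PP4 ≈ 1;
- `replication_medians` — cross-assay replication of genome-wide significant
  variants between cohort pairs (median 1.0 here: no assay noise is planted
  in the demo configuration).

Every number in the report is re-derivable from the stage TSVs
(`meta/`, `loci/`, `finemap/`, `ldsc/`, `mr/`, `coloc/`), and a rerun with
the same seed is byte-identical. The LDSC stage reports `undefined_h2` for
the demo cytokines — a single-causal-variant architecture carries almost no
LD-score signal, the same failure mode real LDSC shows on non-polygenic
traits; polygenic recovery (h² and rg) is exercised in the test suite.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full demonstration pipeline from scratch under the given seed
(synthetic panel → meta-analysis → loci → fine-mapping → LDSC → MR network →
disease screen → colocalization → report), leaving all intermediates under
`scratch/acceptance_run/` and writing the results JSON to `--out`.

## Layout

```
src/cytogen/
  synth_gwas.py    seeded simulators: LD blocks, cohort/disease/eQTL sumstats
  sumstats_io.py   containers, TSV dialect, validation, allele harmonization
  meta.py          z-score meta-analysis, reconstruction, Q, lambda, r²
  loci.py          clumping, locus merging, cis/trans, replication
  finemap.py       Wakefield ABFs, PIPs, credible sets
  ldsc.py          LD scores, h² regression, genetic correlation
  mr.py            instruments, IVW/Egger/weighted-median, Steiger, FDR,
                   network / disease screen / TWAS-MR assemblies
  coloc.py         enumeration colocalization (PP0-PP4)
  pipeline.py      orchestration, config, manifest, summary report
  cli.py           `cytogen` command-line entry point
```
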