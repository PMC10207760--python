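# mrpipe

Two-sample and drug-target **Mendelian randomization (MR)** from GWAS
summary statistics, with a fully seeded synthetic-data generator for
validating every stage of the analysis.

## The scientific problem

Does an exposure (e.g. systolic blood pressure, SBP) causally affect an
outcome (e.g. the residual age at motor onset of a disease, in years)?
Observational associations are confounded; MR sidesteps this by using
genetic variants as instrumental variables. Because alleles are randomized
at conception, a variant that raises SBP by a known amount acts like a tiny
lifelong randomized intervention, provided three assumptions hold:

1. **Relevance** — the variant is robustly associated with the exposure;
2. **Independence** — it is not associated with confounders;
3. **Exclusion restriction** — it affects the outcome only through the exposure.

In *two-sample* MR the SNP-exposure effects (`beta_exp`, `se_exp`) and
SNP-outcome effects (`beta_out`, `se_out`) come from different GWAS cohorts
and are combined per SNP. Writing `gamma_i` for the true effect of SNP *i*
on the exposure and `beta` for the causal effect of the exposure on the
outcome, the generative model is

```
beta_exp,i ~ Normal(gamma_i,              se_exp,i)
beta_out,i ~ Normal(beta * gamma_i + alpha_i, se_out,i)
```

where `alpha_i` is horizontal pleiotropy (zero for a valid instrument).
Each SNP yields a Wald ratio `beta_out,i / beta_exp,i`; the estimators
differ in how they pool the ratios and how much invalidity they tolerate.

*Drug-target* MR restricts instruments to variants inside the gene (and
regulatory regions) encoding a drug's pharmacologic target — here the
targets of three antihypertensive classes (ACE inhibitors, beta-blockers,
calcium-channel blockers) — and orients every variant to the SBP-*lowering*
allele, so the estimate proxies the drug's on-target effect.

## What the package provides

| Stage | Module | Contents |
|---|---|---|
| I/O | `mrpipe.io` | summary-stats TSV (+dialects, gzip), LD reference, gene regions (BED), confounder lookup; strict row validation with per-line audit |
| Instrument selection | `mrpipe.selection` | p < 5×10⁻⁸ filter, greedy LD clumping (10 000 kb, r² < 0.001), confounder screen, F ≥ 10 strength filter, R² = 2β²·EAF(1−EAF)/SD² |
| Drug-target proxies | `mrpipe.drug_targets` | region containment, orientation to the SBP-lowering allele, windowless clumping at r² < 0.4 and r² < 0.2, per-10-mmHg-decrease scaling |
| Harmonization | `mrpipe.harmonize` | allele-order swaps, strand complements, palindromic SNPs resolved by allele frequency or dropped when intermediate (±0.08 of 0.5) |
| Estimators | `mrpipe.estimators` | Wald ratio, fixed/random-effects IVW, MR-Egger (slope + intercept), weighted median, simple and weighted mode; Bonferroni thresholds |
| Sensitivity | `mrpipe.sensitivity` | Cochran's Q (IVW and Egger), Egger intercept test, MR-PRESSO global/outlier/distortion tests |
| Multivariable MR | `mrpipe.mvmr` | joint WLS across correlated exposures (e.g. SBP + DBP), conditional instrument-strength diagnostic |
| Simulation | `mrpipe.simulate` | seeded two-sample generator with known truth: pleiotropy (balanced/directional), invalid-weight fraction, outliers, palindromic/strand/swap allele coding, LD blocks, drug regions, correlated second exposure |
| Pipeline | `mrpipe.pipeline`, `mrpipe.cli` | YAML-configured end-to-end run; `report.json` is byte-identical across reruns of the same config + seed |

## Worked example

Generate a synthetic study (150 SNPs, true effect 0.004 outcome units per
mmHg SBP, one CCB target region), then run the full analysis:

```sh
cat > scenario.yaml <<'YAML'
config:
  n_snps: 150
  drug_regions: [[CCB, CACNA1C, 6]]
truth:
  beta_causal: 0.004
YAML
mrpipe simulate --scenario scenario.yaml --seed 7 --out data/
```

```text
wrote synthetic study (150 SNPs) to data
```

Stage by stage:

```sh
mrpipe select-instruments --stats data/exposure.tsv \
    --ld-pairs data/ld_pairs.tsv --ld-variants data/ld_variants.tsv \
    --confounder-table data/confounders.tsv --trait-sd 21.5 --out instruments.tsv
mrpipe harmonize --exposure instruments.tsv --outcome data/outcome.tsv --out harmonized.tsv
mrpipe estimate --instruments harmonized.tsv --scale-mmhg 10 --seed 7 --out estimates.json
```

```text
73 instruments selected -> instruments.tsv
retained 72/73 (palindromic dropped 1, irreconcilable 0) -> harmonized.tsv
ivw: beta=-0.01839 (95% CI -0.4172 to 0.3804), p=0.928
mr_egger: beta=0.03034 (95% CI -1.003 to 1.064), p=0.954
weighted_median: beta=-0.3384 (95% CI -0.9474 to 0.2707), p=0.276
simple_mode: beta=-0.4149 (95% CI -1.735 to 0.9056), p=0.538
weighted_mode: beta=-0.5486 (95% CI -1.573 to 0.476), p=0.294
```

(The true scaled effect here is +0.04 per 10 mmHg; with a 9 064-sample
outcome GWAS the CI is wide, and the point estimates scatter around a value
this small — exactly the situation the sensitivity analyses are for.)

Or everything at once from one config:

```sh
cat > analysis.yaml <<'YAML'
seed: 7
exposures:
  SBP: {stats: data/exposure.tsv, trait_sd: 21.5, scale_mmhg: 10}
outcome: {stats: data/outcome.tsv, trait_sd: 5.0, label: residual_AAO}
ld: {pairs: data/ld_pairs.tsv, variants: data/ld_variants.tsv}
regions: data/regions.bed
confounder_table: data/confounders.tsv
YAML
mrpipe run --config analysis.yaml --out results/
```

```text
report -> results/report.json
```

`results/report.json` contains, among other things:

```text
stage_counts: {'input': 150, 'genome_wide_significant': 75, 'post_clump': 73,
               'post_confounder_screen': 73, 'post_f_filter': 73}
harmonization: {'n_intersection': 73, 'n_retained': 72,
                'n_palindromic_dropped': 1, 'n_irreconcilable': 0}
variance_explained: 0.0144
q_ivw: {'q': 50.275, 'df': 71, 'pval': 0.97}
drug CCB r2<0.4: {'n_proxies': 3, 'max_pairwise_r2': 0.05,
                  'single_proxy_wald_fallback': False}
```

`results/report.tsv` is the same content flattened to one estimate per row
(the text form of a forest plot).

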