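# Methods

Statistical conventions, parameter defaults, and the scope of the synthetic
generator. Notation: per SNP *i*, `beta_exp,i ± se_exp,i` is the
SNP-exposure association, `beta_out,i ± se_out,i` the SNP-outcome
association (different GWAS cohorts), `w_i = 1/se_out,i²` the outcome
inverse-variance weight, and `n` the number of instruments.

## Model

The instrumental-variable model behind both the estimators and the
generator:

```
beta_exp,i ~ Normal(gamma_i, se_exp,i)
beta_out,i ~ Normal(beta * gamma_i + alpha_i, se_out,i)
```

`gamma_i` is SNP *i*'s true effect on the exposure, `beta` the causal
effect of the exposure on the outcome (the estimand), and `alpha_i`
horizontal pleiotropy — zero for a valid instrument. All estimators assume
the two samples are independent and the per-SNP errors are uncorrelated
across SNPs (instruments are LD-clumped for this reason).

## Instrument selection

Defaults (all overridable per run):

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `p_gws` | 5×10⁻⁸ | — | conventional genome-wide significance; strict `<` |
| `clump_kb` | 10 000 | kb | clumping window, center-to-center distance |
| `clump_r2` | 0.001 | r² | near-independence for genome-wide instruments |
| `f_min` | 10 | — | conventional weak-instrument bound; F = β²/se², F = 10 is kept |
| variance explained | — | — | R² = 2β²·EAF(1−EAF)/SD², summed over instruments |

Clumping is greedy: variants sorted by ascending p (ties broken by
chromosome, position, then SNP id); each index variant removes every
not-yet-kept variant on the same chromosome within the window whose r² with
it is at or above the threshold. A pair *inside* the window but missing
from the LD reference is treated conservatively as r² = 1 (the variant is
removed); a pair *outside* the window is never compared, and missing
distant pairs default to r² = 0. The confounder screen removes any
instrument with a recorded confounder association at p < 5×10⁻⁸ (strict),
using a local lookup table rather than a live service so runs are
reproducible offline. Every exclusion carries a machine-readable reason
code (`NOT_GWS`, `CLUMPED`, `CONFOUNDER`, `WEAK_F`).

## Drug-target proxies

Variants inside a drug class's target gene region(s) — 1-based inclusive
intervals, optionally extended by regulatory intervals — significant at
`p_gws`, oriented so the effect allele *lowers* SBP (beta < 0 after
orientation; a variant with beta exactly 0 cannot be oriented and is
excluded). Within-region clumping is windowless (every pair is compared) at
the two conventional cis thresholds r² < 0.4 (primary) and r² < 0.2
(strict); the strict set is reported alongside the primary one. Estimates
are scaled by −10, i.e. per 10 mmHg *decrease* in SBP, matching how
antihypertensive effects are reported. A class whose regions contain a
single surviving proxy falls back to the Wald ratio and is flagged
(`single_proxy_wald_fallback`).

## Harmonization

Per SNP shared by both studies, aligned to the exposure's effect allele:

- same allele pair, same order → kept as is;
- same pair, swapped order → `beta_out` negated, `eaf_out` complemented;
- strand complement (non-palindromic only) → relabelled, then as above;
- palindromic (A/T or C/G): if either study's EAF is within `af_window`
  (default **0.08**) of 0.5, the strand is unresolvable and the SNP is
  dropped and counted; otherwise the orientation matching minor to minor
  allele frequency is chosen;
- anything else → dropped as irreconcilable.

The audit satisfies exact count conservation: intersection = retained +
palindromic-dropped + irreconcilable. Harmonization is idempotent and
invariant under a complement-and-swap re-encoding of either study (tested).

## Estimators

- **Wald ratio** (n = 1): `beta_out/beta_exp`, first-order SE
  `se_out/|beta_exp|`.
- **IVW**: zero-intercept WLS of `beta_out` on `beta_exp` with weights
  `w_i`; algebraically identical to the `w_i·beta_exp,i²`-weighted mean of
  the Wald ratios. Random-effects (the default) inflates the SE by
  `max(1, sqrt(Q/(n−1)))` — multiplicative, never deflating. p-values from
  the normal distribution.
- **MR-Egger**: the same regression with a free intercept, after orienting
  all instruments to positive `beta_exp`. The slope SE uses the same
  truncated inflation with `Q/(n−2)`; the intercept SE uses the *free*
  residual-variance estimate `sqrt(Q/(n−2))` so the directional-pleiotropy
  test is exactly t(n−2)-calibrated (verified empirically: type-I ≈ 4.8 %
  at α = 0.05; truncating the intercept SE would push it to ≈ 3.6 %).
  Both slope and intercept p-values use t with n−2 df.
- **Weighted median** of the Wald ratios (weights `beta_exp,i²·w_i`),
  midpoint-adjusted cumulative weights with linear interpolation at 0.5;
  consistent while valid instruments carry > 50 % of the weight. SE from a
  seeded parametric bootstrap (default 1 000 draws) of both effect vectors.
- **Simple and weighted mode**: mode of the Gaussian-kernel-smoothed ratio
  density on a 512-point grid; bandwidth by the modified Silverman rule
  `0.9·min(sd, 1.4826·MAD)·n^(−1/5)` times a `bandwidth_factor` (default 1).
  Bootstrap SEs use the robust scale `1.4826·MAD` of the bootstrap modes.
- **Scaling**: estimates are computed per exposure unit and rescaled for
  reporting (×10 mmHg for SBP, ×5 for DBP, ×(−10) for drug classes). The
  SE scales by |factor|, the CI endpoints are reordered for negative
  factors, and the p-value is scale-invariant.
- **Multiple testing**: Bonferroni `0.05/n` rounded to three decimals
  (two exposures → 0.025; three drug classes → 0.017).

`estimate_all` returns the Wald ratio alone at n = 1, IVW alone at n = 2,
and all five estimators at n ≥ 3 (Egger, median and modes need ≥ 3).

## Sensitivity analyses

- **Cochran's Q** against the IVW fit (df = n−1) or the Egger fit
  (df = n−2), p from the upper chi-square tail.
- **Egger intercept test**: see above; a nonzero intercept indicates
  directional pleiotropy.
- **MR-PRESSO** (needs n ≥ 4): the observed statistic is the weighted sum
  of squared *leave-one-out* IVW residuals. The null distribution comes
  from `n_sim` (default 1 000) parametric datasets
  `beta_out,i ~ Normal(beta_IVW·beta_exp,i, se_out,i)` scored the same way;
  the global p uses the add-one estimator `(1 + #{sim ≥ obs})/(1 + n_sim)`,
  so it is never exactly zero and is exactly uniform under exchangeability
  (with `n_sim = 499`, P(p ≤ 0.05) = 0.05 exactly). Outliers are SNPs whose
  observed squared residual exceeds its simulated distribution at the
  Bonferroni level `0.05/n`; note `n_sim` must exceed `n/0.05` for flagging
  to be possible at all. The distortion test compares the estimate shift
  after removing the flagged SNPs to the shift from removing random subsets
  of the same size. Everything is seeded and bit-reproducible.

## Multivariable MR

Zero-intercept multiple WLS of `beta_out` on the matrix of per-exposure
effects (weights `w_i`), over the union of each exposure's univariable
instruments restricted to SNPs present in every dataset and harmonized to
the first exposure's alleles (an exposure missing > 50 % of the union is a
fatal error). SEs use `max(1, sqrt(Q/(n−k)))` inflation. A rank-deficient
design raises an error naming the collinear exposure pair. The conditional
instrument-strength statistic (weighted residual variation of one
exposure's effects given the others, per remaining df) is **approximate** —
two-sample summary data lack the cross-exposure sampling covariance — and
is reported as a diagnostic only, never filtered on.

## Synthetic generator

`mrpipe.simulate` draws from the model above with every nuisance explicit
and seeded:

| Parameter | Default | Rationale |
|---|---|---|
| `n_snps` | 400 | order of a large-GWAS instrument candidate set |
| `n_exposure` / `n_outcome` | 757 601 / 9 064 | a large consortium exposure GWAS vs a small disease-cohort outcome GWAS |
| `trait_sd` / `outcome_sd` | 21.5 / 5.0 | SBP in mmHg; outcome in years |
| `variance_explained_target` | 0.016 | instruments jointly explain ~1.6 % of exposure variance; `gamma` is rescaled to hit the target exactly |
| `gamma_distribution` | `normal` | `halfnormal` makes all true effects positive so *directional* pleiotropy produces a one-sided bias (with sign-symmetric gamma the expected IVW bias of directional alpha is zero) |
| `palindromic_fraction`, `swap_fraction`, `strand_scramble_fraction` | 0.2 / 0.3 / 0.1 | exercise every harmonization branch; the planted intermediate-frequency palindromic count is echoed for exact bookkeeping tests |
| `invalid_fraction` | 0 | share of total ratio-scale IVW weight carried by pleiotropic instruments, approximated to within one instrument's weight (never systematically overshooting) |
| `outlier_shift_se` | 10 | outliers displace `beta_out` by a stated multiple of its SE |
| LD layout | blocks ≥ 15 Mb apart | distinct blocks always fall outside the 10 000 kb clumping window; drug-target regions get *complete* pairwise r² coverage (within-block 0.8, cross-block 0.05) so windowless clumping never hits a missing pair |

Standard errors follow the GWAS approximation
`se = SD/sqrt(2·EAF·(1−EAF)·N)`, so instrument strength is realistic for
the configured sample sizes. A correlated second exposure
(`CorrelatedExposureSpec`, default DBP-like: SD 11.4, R² 1.7 %, effect
correlation 0.7) shares variants, positions and allele coding with the
first, enabling MVMR scenarios. The truth echo reports the realized
`gamma`, `alpha`, invalid/outlier SNP ids, and the planted palindromic
count.

**Scope and limits.** The generator produces summary statistics, not
individual-level genotypes: LD is injected as pairwise r² labels and does
*not* correlate the sampling errors of nearby SNPs; EAFs are independent
uniform draws rather than a realistic frequency spectrum; the two samples
are exactly independent (no sample overlap); winner's curse, population
stratification, and assortative mating are not modelled.

## Numerical choices

- Closed-form WLS algebra (scalar 2×2 solve for Egger, Cholesky-free
  `solve` for MVMR) rather than iterative fitting; cross-checked against
  statsmodels WLS to 12 significant digits in the tests.
- MR-PRESSO's leave-one-out residuals are computed from running sums
  (`beta_loo,i = (S_xy − w_i x_i y_i)/(S_xx − w_i x_i²)`), vectorized over
  all simulated datasets at once.
- All bootstrap/simulation RNG is `numpy.random.default_rng` with explicit
  seeds; pipeline stages derive child seeds < 2³¹ from the run seed and a
  stage tag, so `report.json` is byte-identical across reruns.
- TSV round-trips use full repr precision; reading back a written file
  reproduces the frame bit-for-bit.

## Problem sizes

The defaults above (400 SNPs, N = 757 601 / 9 064, SD 21.5 / 11.4 / 5.0,
R² targets 1.6 % / 1.7 %, scaling per 10 / 5 mmHg) are package choices that
emulate a realistic blood-pressure-to-disease-modifier analysis; nothing in
the code depends on them, and all are plain config fields.

## Limitations

- The Egger slope's truncated SE inflation (`max(1, ·)`) makes its CI
  conservative on underdispersed data; the intercept test is exactly
  calibrated (see above).
- The weighted-median/mode bootstrap SEs are parametric (normal resampling
  of both effect vectors), not the jackknife some other implementations use.
- MR-PRESSO simulates the null around the full-sample IVW fit; its global
  p is exchangeable-uniform only to the extent the estimated slope stands
  in for the true one (negligible at n ≳ 20, and type-I stays inside
  [3.5 %, 6.5 %] in the acceptance tests).
- The MVMR conditional-F diagnostic is approximate (no cross-exposure
  sampling covariance in two-sample summary data).
- No correlated-instrument estimators: all methods assume clumped,
  effectively independent instruments.
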