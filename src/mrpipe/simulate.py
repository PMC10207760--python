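"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generative model follows the instrumental-variable structure of
two-sample MR. Per SNP i with true exposure effect gamma_i:

    beta_exp,i ~ Normal(gamma_i, se_exp,i)
    beta_out,i ~ Normal(beta_causal * gamma_i + alpha_i, se_out,i)

alpha_i is horizontal pleiotropy (zero for valid instruments; balanced or
directional for the invalid share), and designated outliers have their
outcome effect displaced by a stated multiple of se_out. Standard errors
follow the usual GWAS approximation se ~ SD / sqrt(2 p (1-p) N), so
instrument strength is realistic for the configured sample sizes. Defaults
emulate an SBP exposure (SD 21.5 mmHg, N = 757,601; instruments explaining
~1.6% of variance) against a modifier-scale outcome measured in years on
N = 9,064 cases.

Allele coding stress for the harmonizer: a configurable fraction of SNPs is
palindromic (A/T, C/G), and the outcome copy gets randomly swapped allele
order and strand-complemented labels. LD is emitted as block structure with
full pairwise coverage inside drug-target gene regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .io import ConfounderTable, GeneRegion, LDReference, SummaryStatSet

_NONPAL_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: spacing that keeps distinct LD blocks outside the 10 000 kb clumping window
_BLOCK_SPACING_BP = 15_000_000
_REGION_BLOCK_SPACING_BP = 50_000
_SNP_SPACING_BP = 10_000


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults emulate the SBP analysis conditions: exposure GWAS of 757,601
    Europeans with trait SD 21.5 mmHg, outcome GWAS of 9,064 patients, and
    instruments that jointly explain ~1.6% of exposure variance.
    """

    n_snps: int = 400
    n_exposure: int = 757_601
    n_outcome: int = 9_064
    trait_sd: float = 21.5
    outcome_sd: float = 5.0
    variance_explained_target: float = 0.016
    eaf_range: tuple[float, float] = (0.05, 0.95)
    palindromic_fraction: float = 0.2
    strand_scramble_fraction: float = 0.1
    swap_fraction: float = 0.3
    ld_block_size: int = 1
    ld_block_r2: float = 0.8
    cross_block_r2: float = 0.05
    #: "normal" or "halfnormal"; halfnormal makes every true exposure effect
    #: positive so directional pleiotropy translates into a one-sided bias
    gamma_distribution: str = "normal"
    af_window: float = 0.08
    n_confounded: int = 0
    #: (drug_class, gene_symbol, n_blocks) triples; each gene gets its own chromosome
    drug_regions: tuple = ()
    trait_label: str = "SBP"
    outcome_label: str = "residual_AAO"

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in ("palindromic_fraction", "strand_scramble_fraction", "swap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.cross_block_r2 <= 1.0 or not 0.0 <= self.ld_block_r2 <= 1.0:
            raise ValueError("LD r² parameters must lie in [0, 1]")
        if self.trait_sd <= 0 or self.outcome_sd <= 0:
            raise ValueError("trait SDs must be positive")
        if self.gamma_distribution not in ("normal", "halfnormal"):
            raise ValueError(
                f"gamma_distribution must be 'normal' or 'halfnormal', got {self.gamma_distribution!r}"
            )


@dataclass
class SyntheticTruth:
    """Generating parameters against which recovery is tested."""

    beta_causal: float = 0.0  # outcome units per exposure unit (per mmHg)
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0  # share of total IV weight that is invalid
    outlier_indices: tuple = ()
    outlier_shift_se: float = 10.0
    seed: int = 0

    def validate(self, n_snps: int) -> None:
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not 0.0 <= self.invalid_fraction < 1.0:
            raise ValueError("invalid_fraction must lie in [0, 1)")
        if self.invalid_fraction > 0 and self.pleiotropy_mode == "none":
            raise ValueError("invalid_fraction > 0 requires a pleiotropy mode")
        if self.pleiotropy_mode != "none" and self.invalid_fraction > 0 and self.pleiotropy_sd <= 0:
            raise ValueError("pleiotropy_sd must be positive when instruments are invalid")
        if any(i < 0 or i >= n_snps for i in self.outlier_indices):
            raise ValueError("outlier index out of range")


@dataclass
class CorrelatedExposureSpec:
    """A second exposure sharing variants and allele coding with the first.

    True per-SNP effects correlate with the first exposure's at ``rho``
    (emulating SBP/DBP from one meta-analysis); ``beta_causal`` is this
    exposure's *direct* effect on the outcome, per exposure unit.
    """

    label: str = "DBP"
    trait_sd: float = 11.4
    variance_explained_target: float = 0.017
    rho: float = 0.7
    beta_causal: float = 0.0


@dataclass
class TruthEcho:
    """What was actually generated — for assertions in tests and reports."""

    truth: SyntheticTruth
    snp_ids: list[str]
    gamma: np.ndarray
    alpha: np.ndarray
    invalid_ids: list[str]
    outlier_ids: list[str]
    n_palindromic_intermediate: int
    confounded_ids: list[str] = field(default_factory=list)
    gamma2: np.ndarray | None = None


@dataclass
class SimulatedStudy:
    exposure: SummaryStatSet
    outcome: SummaryStatSet
    ld: LDReference
    truth: TruthEcho
    gene_regions: list[GeneRegion] | None = None
    exposure2: SummaryStatSet | None = None


def _positions(config: ScenarioConfig):
    """Assign (chrom, pos) per SNP and lay out LD blocks.

    Drug-target regions come first, one gene per chromosome with its blocks
    close together; remaining blocks are spread far apart (beyond the
    clumping window) on the remaining chromosomes. Returns per-SNP chrom/pos,
    per-SNP block index, per-block region index (-1 = none) and the
    GeneRegion list.
    """
    bs = config.ld_block_size
    n_blocks = int(np.ceil(config.n_snps / bs))
    region_defs = list(config.drug_regions)
    n_region_blocks = sum(nb for _, _, nb in region_defs)
    if n_region_blocks > n_blocks:
        raise ValueError("drug_regions require more LD blocks than n_snps provides")

    chroms = np.empty(config.n_snps, dtype=object)
    pos = np.empty(config.n_snps, dtype=np.int64)
    block_of = np.repeat(np.arange(n_blocks), bs)[: config.n_snps]
    region_of_block = np.full(n_blocks, -1)

    regions: list[GeneRegion] = []
    block = 0
    for ridx, (klass, gene, nb) in enumerate(region_defs):
        chrom = str(ridx + 1)
        start = 1_000_000
        for b in range(nb):
            region_of_block[block] = ridx
            for j in range(bs):
                i = block * bs + j
                if i < config.n_snps:
                    chroms[i] = chrom
                    pos[i] = start + b * _REGION_BLOCK_SPACING_BP + j * 100
            block += 1
        end = start + nb * _REGION_BLOCK_SPACING_BP + bs * 100
        regions.append(GeneRegion(gene, klass, chrom, start - 500, end + 500))

    free_chroms = [str(c) for c in range(len(region_defs) + 1, 23)] or ["22"]
    for k, b in enumerate(range(block, n_blocks)):
        chrom = free_chroms[k % len(free_chroms)]
        slot = k // len(free_chroms)
        base = 1_000_000 + slot * _BLOCK_SPACING_BP
        for j in range(bs):
            i = b * bs + j
            if i < config.n_snps:
                chroms[i] = chrom
                pos[i] = base + j * _SNP_SPACING_BP
    return chroms, pos, block_of, region_of_block, regions


def _alleles(config: ScenarioConfig, rng: np.random.Generator):
    n = config.n_snps
    pal = rng.random(n) < config.palindromic_fraction
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    pal_choice = rng.integers(0, len(_PAL_PAIRS), size=n)
    nonpal_choice = rng.integers(0, len(_NONPAL_PAIRS), size=n)
    for i in range(n):
        ea[i], oa[i] = _PAL_PAIRS[pal_choice[i]] if pal[i] else _NONPAL_PAIRS[nonpal_choice[i]]
    return ea, oa, pal


def _invalid_set(truth: SyntheticTruth, gamma, se_out, rng) -> np.ndarray:
    """Pick a random instrument subset whose share of total ratio-scale IVW
    weight is as close as possible to invalid_fraction (greedy in random
    order; the crossing instrument is included only if that lands nearer the
    target than stopping short, so the share never systematically overshoots)."""
    n = gamma.size
    mask = np.zeros(n, dtype=bool)
    if truth.invalid_fraction == 0:
        return mask
    weights = (gamma / se_out) ** 2
    weights = weights / weights.sum()
    target = truth.invalid_fraction
    acc = 0.0
    for i in rng.permutation(n):
        if acc >= target:
            break
        if acc + weights[i] <= target or abs(acc + weights[i] - target) <= abs(acc - target):
            mask[i] = True
            acc += weights[i]
    return mask


def generate_two_sample(
    config: ScenarioConfig,
    truth: SyntheticTruth,
    second: CorrelatedExposureSpec | None = None,
) -> SimulatedStudy:
    """Generate exposure and outcome summary statistics, LD and truth echo.

    Deterministic given ``truth.seed``; the outcome copy carries scrambled
    allele encodings so harmonization is genuinely exercised. With
    ``second``, a correlated second exposure is emitted (``exposure2``) and
    the outcome mean becomes beta_causal·gamma₁ + second.beta_causal·gamma₂
    + alpha, the multivariable-MR data-generating model.
    """
    config.validate()
    truth.validate(config.n_snps)
    rng = np.random.default_rng(truth.seed)
    n = config.n_snps
    snp_ids = [f"rs{i + 1}" for i in range(n)]

    chroms, pos, block_of, region_of_block, regions = _positions(config)
    ea, oa, _ = _alleles(config, rng)
    eaf = rng.uniform(*config.eaf_range, size=n)
    eaf_out = np.clip(eaf + rng.normal(0.0, 0.01, size=n), 0.02, 0.98)

    # true exposure effects scaled to the target total variance explained
    raw = rng.normal(size=n)
    if config.gamma_distribution == "halfnormal":
        raw = np.abs(raw)
    het = 2.0 * eaf * (1.0 - eaf)
    scale = np.sqrt(config.variance_explained_target * config.trait_sd**2 / np.sum(het * raw**2))
    gamma = raw * scale

    se_exp = config.trait_sd / np.sqrt(het * config.n_exposure)
    se_out = config.outcome_sd / np.sqrt(2.0 * eaf_out * (1.0 - eaf_out) * config.n_outcome)

    gamma2 = None
    if second is not None:
        raw2 = second.rho * raw + np.sqrt(1.0 - second.rho**2) * rng.normal(size=n)
        scale2 = np.sqrt(
            second.variance_explained_target * second.trait_sd**2 / np.sum(het * raw2**2)
        )
        gamma2 = raw2 * scale2

    invalid = _invalid_set(truth, gamma, se_out, rng)
    alpha = np.zeros(n)
    if truth.pleiotropy_mode == "balanced":
        alpha[invalid] = rng.normal(0.0, truth.pleiotropy_sd, size=int(invalid.sum()))
    elif truth.pleiotropy_mode == "directional":
        alpha[invalid] = np.abs(rng.normal(0.0, truth.pleiotropy_sd, size=int(invalid.sum())))

    beta_exp = rng.normal(gamma, se_exp)
    mu_out = truth.beta_causal * gamma + alpha
    if gamma2 is not None:
        mu_out = mu_out + second.beta_causal * gamma2
    beta_out = rng.normal(mu_out, se_out)
    outlier_idx = np.asarray(truth.outlier_indices, dtype=int)
    if outlier_idx.size:
        beta_out[outlier_idx] += truth.outlier_shift_se * se_out[outlier_idx]

    p_exp = 2.0 * sps.norm.sf(np.abs(beta_exp / se_exp))
    p_out = 2.0 * sps.norm.sf(np.abs(beta_out / se_out))

    exposure = SummaryStatSet(
        config.trait_label,
        config.trait_sd,
        pd.DataFrame(
            {
                "snp_id": snp_ids, "chrom": chroms, "pos": pos,
                "effect_allele": ea, "other_allele": oa,
                "eaf": eaf, "beta": beta_exp, "se": se_exp,
                "pval": np.clip(p_exp, 1e-300, 1.0),
            }
        ),
    )

    # outcome copy with scrambled encodings
    ea_o, oa_o = ea.copy(), oa.copy()
    b_o, e_o = beta_out.copy(), eaf_out.copy()
    swap = rng.random(n) < config.swap_fraction
    ea_o[swap], oa_o[swap] = oa[swap], ea[swap]
    b_o[swap] *= -1.0
    e_o[swap] = 1.0 - e_o[swap]
    scramble = rng.random(n) < config.strand_scramble_fraction
    for i in np.flatnonzero(scramble):
        ea_o[i], oa_o[i] = _COMP[ea_o[i]], _COMP[oa_o[i]]
    outcome = SummaryStatSet(
        config.outcome_label,
        config.outcome_sd,
        pd.DataFrame(
            {
                "snp_id": snp_ids, "chrom": chroms, "pos": pos,
                "effect_allele": ea_o, "other_allele": oa_o,
                "eaf": e_o, "beta": b_o, "se": se_out,
                "pval": np.clip(p_out, 1e-300, 1.0),
            }
        ),
    )

    exposure2 = None
    if gamma2 is not None:
        se_exp2 = second.trait_sd / np.sqrt(het * config.n_exposure)
        beta_exp2 = rng.normal(gamma2, se_exp2)
        p_exp2 = 2.0 * sps.norm.sf(np.abs(beta_exp2 / se_exp2))
        exposure2 = SummaryStatSet(
            second.label,
            second.trait_sd,
            pd.DataFrame(
                {
                    "snp_id": snp_ids, "chrom": chroms, "pos": pos,
                    "effect_allele": ea, "other_allele": oa,
                    "eaf": eaf, "beta": beta_exp2, "se": se_exp2,
                    "pval": np.clip(p_exp2, 1e-300, 1.0),
                }
            ),
        )

    ld = _build_ld(config, snp_ids, chroms, pos, block_of, region_of_block)

    pal_mask = np.array([ {a, b} in ({"A", "T"}, {"C", "G"}) for a, b in zip(ea, oa)])
    w = config.af_window
    intermediate = (np.abs(eaf - 0.5) < w) | (np.abs(eaf_out - 0.5) < w)
    echo = TruthEcho(
        truth=truth,
        snp_ids=snp_ids,
        gamma=gamma,
        alpha=alpha,
        invalid_ids=[snp_ids[i] for i in np.flatnonzero(invalid)],
        outlier_ids=[snp_ids[i] for i in outlier_idx],
        n_palindromic_intermediate=int(np.sum(pal_mask & intermediate)),
        gamma2=gamma2,
    )
    return SimulatedStudy(
        exposure, outcome, ld, echo, gene_regions=regions or None, exposure2=exposure2
    )


def _build_ld(config, snp_ids, chroms, pos, block_of, region_of_block) -> LDReference:
    """Within-block pairs at ld_block_r2; full pairwise coverage (cross-block
    at cross_block_r2) inside drug-target regions."""
    ld = LDReference(positions={s: (c, int(p)) for s, c, p in zip(snp_ids, chroms, pos)})
    n = len(snp_ids)
    for i in range(n):
        for j in range(i + 1, n):
            bi, bj = block_of[i], block_of[j]
            if bi == bj:
                ld.add(snp_ids[i], snp_ids[j], config.ld_block_r2)
            elif region_of_block[bi] >= 0 and region_of_block[bi] == region_of_block[bj]:
                ld.add(snp_ids[i], snp_ids[j], config.cross_block_r2)
    return ld


def generate_confounder_table(config: ScenarioConfig, truth: SyntheticTruth) -> ConfounderTable:
    """Local confounder lookup with ``config.n_confounded`` planted hits.

    Designated SNPs get a sub-threshold association (p = 1e-10) with one of
    the screened confounder traits; every other listed SNP sits well above
    the genome-wide threshold. The designated ids are exposed as the
    ``designated`` attribute.
    """
    rng = np.random.default_rng([17, truth.seed])
    snp_ids = [f"rs{i + 1}" for i in range(config.n_snps)]
    traits = ["coffee consumption", "lifetime smoking index", "telomere length"]
    designated = sorted(
        rng.choice(config.n_snps, size=config.n_confounded, replace=False).tolist()
    ) if config.n_confounded else []
    rows = []
    for k, i in enumerate(designated):
        rows.append({"snp_id": snp_ids[i], "confounder_trait": traits[k % 3], "pval": 1e-10})
    # background: a sprinkling of comfortably non-significant associations
    n_bg = min(config.n_snps, 25)
    for i in rng.choice(config.n_snps, size=n_bg, replace=False):
        if i not in designated:
            rows.append(
                {
                    "snp_id": snp_ids[i],
                    "confounder_trait": traits[int(rng.integers(3))],
                    "pval": float(rng.uniform(1e-4, 1.0)),
                }
            )
    table = ConfounderTable(pd.DataFrame(rows, columns=["snp_id", "confounder_trait", "pval"]))
    table.designated = [snp_ids[i] for i in designated]
    return table


def read_scenario(path) -> tuple[ScenarioConfig, SyntheticTruth]:
    """Load a scenario YAML with ``config`` and ``truth`` sections."""
    doc = yaml.safe_load(open(path))
    cfg = doc.get("config", {})
    if "eaf_range" in cfg:
        cfg["eaf_range"] = tuple(cfg["eaf_range"])
    if "drug_regions" in cfg:
        cfg["drug_regions"] = tuple(tuple(r) for r in cfg["drug_regions"])
    tr = doc.get("truth", {})
    if "outlier_indices" in tr:
        tr["outlier_indices"] = tuple(tr["outlier_indices"])
    return ScenarioConfig(**cfg), SyntheticTruth(**tr)


def write_scenario(config: ScenarioConfig, truth: SyntheticTruth, path) -> None:
    doc = {"config": asdict(config), "truth": asdict(truth)}
    doc["config"]["eaf_range"] = list(config.eaf_range)
    doc["config"]["drug_regions"] = [list(r) for r in config.drug_regions]
    doc["truth"]["outlier_indices"] = list(truth.outlier_indices)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
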