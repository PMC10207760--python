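"""Drug-target instrument construction.

Variants inside the gene bodies or regulatory intervals of a drug class's
pharmacologic-target genes (ACEI, BB, CCB), significantly associated with
SBP (p < 5e-8), oriented so the recorded effect allele is the SBP-lowering
allele, and clumped at a lenient LD threshold (r² < 0.4 primary, r² < 0.2
sensitivity) with every within-region pair checked (no distance window).
Downstream estimates for these sets are scaled per 10 mmHg SBP *decrease*
(scale factor −10).
"""

from __future__ import annotations

import logging

from .io import GeneRegion, LDReference, SummaryStatSet
from .selection import GWS_P_THRESHOLD, clump, filter_genome_wide

logger = logging.getLogger("mrpipe")

DRUG_CLUMP_R2_PRIMARY = 0.4
DRUG_CLUMP_R2_STRICT = 0.2
#: mmHg per reported unit for drug-class estimates: 10 mmHg SBP decrease
DRUG_SCALE_FACTOR = -10.0

NOT_IN_REGION = "NOT_IN_REGION"
NULL_EXPOSURE_EFFECT = "NULL_EXPOSURE_EFFECT"


def variants_in_regions(
    stats: SummaryStatSet, regions: list[GeneRegion], drug_class: str
) -> SummaryStatSet:
    """Variants whose position lies in any gene or regulatory interval of the class.

    Membership is 1-based inclusive containment.
    """
    class_regions = [r for r in regions if r.drug_class == drug_class]
    if not class_regions:
        raise ValueError(f"no gene regions declared for drug class {drug_class!r}")
    mask = [
        any(r.contains(row.chrom, row.pos) for r in class_regions)
        for row in stats.records.itertuples()
    ]
    return stats.replace(stats.records[mask])


def orient_to_drug_effect(stats: SummaryStatSet) -> SummaryStatSet:
    """Re-express every variant so the effect allele is the SBP-lowering one.

    Variants with beta > 0 have alleles swapped, beta negated and eaf
    complemented; beta == 0 variants are excluded with a warning (no
    lowering allele exists). Idempotent, and Wald-ratio magnitudes are
    unchanged because exposure and outcome signs cancel.
    """
    df = stats.records.copy()
    zero = df["beta"] == 0
    for snp in df.loc[zero, "snp_id"]:
        logger.warning("%s excluded from drug proxies: exposure beta is 0", snp)
    df = df[~zero].copy()
    flip = df["beta"] > 0
    df.loc[flip, ["effect_allele", "other_allele"]] = df.loc[
        flip, ["other_allele", "effect_allele"]
    ].to_numpy()
    df.loc[flip, "beta"] = -df.loc[flip, "beta"]
    df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
    return stats.replace(df)


def select_drug_instruments(
    stats: SummaryStatSet,
    regions: list[GeneRegion],
    drug_class: str,
    ld: LDReference,
    p_thresh: float = GWS_P_THRESHOLD,
    r2_max: float = DRUG_CLUMP_R2_PRIMARY,
) -> SummaryStatSet:
    """Per-class proxy selection: region containment → p filter → orientation
    → windowless greedy clumping at ``r2_max``."""
    in_region = variants_in_regions(stats, regions, drug_class)
    significant = filter_genome_wide(in_region, p_thresh)
    oriented = orient_to_drug_effect(significant)
    clumped = clump(oriented, ld, window_kb=None, r2_max=r2_max)
    if len(clumped) == 0:
        logger.warning("drug class %s: no significant variant in its target regions", drug_class)
    elif len(clumped) == 1:
        logger.warning(
            "drug class %s: single proxy (%s); downstream estimate falls back to a Wald ratio",
            drug_class,
            clumped.records["snp_id"].iloc[0],
        )
    return clumped
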