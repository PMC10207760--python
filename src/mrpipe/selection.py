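"""Genome-wide instrument selection for a blood-pressure exposure.

The pipeline order is fixed: genome-wide significance filter (p < 5e-8),
greedy LD clumping (10 000 kb window, r² < 0.001), confounder screen
against a local lookup table, and instrument-strength filter (remove
F = β²/se² < 10). Each stage logs per-SNP exclusion reasons into a
:class:`SelectionReport` whose stage counts are non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ConfounderTable, LDReference, SummaryStatSet

logger = logging.getLogger("mrpipe")

#: machine-readable exclusion reason codes
NOT_GWS = "NOT_GWS"
CLUMPED = "CLUMPED"
CONFOUNDER = "CONFOUNDER"
WEAK_F = "WEAK_F"

GWS_P_THRESHOLD = 5e-8
CLUMP_WINDOW_KB = 10_000
CLUMP_R2 = 0.001
F_MIN = 10.0


@dataclass
class SelectionReport:
    """Counts at each filter stage plus per-SNP exclusion reasons."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    exclusions: list[tuple[str, str, str]] = field(default_factory=list)  # (snp_id, code, detail)

    def record_stage(self, name: str, count: int) -> None:
        if self.stage_counts and count > min(self.stage_counts.values()):
            # stages only ever remove variants
            raise ValueError(f"stage {name} count {count} exceeds an earlier stage")
        self.stage_counts[name] = count

    def exclude(self, snp_id: str, code: str, detail: str = "") -> None:
        self.exclusions.append((snp_id, code, detail))


def f_statistic(beta, se):
    """Instrument strength F = β²/se². Vectorizes over arrays."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def variance_explained(beta, eaf, trait_sd):
    """Per-SNP exposure variance explained, R² = 2 β² EAF (1−EAF) / SD²."""
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("eaf must lie strictly between 0 and 1")
    if not trait_sd > 0:
        raise ValueError("trait_sd must be positive")
    out = 2.0 * beta**2 * eaf * (1.0 - eaf) / trait_sd**2
    return float(out) if out.ndim == 0 else out


def filter_genome_wide(
    stats: SummaryStatSet,
    p_thresh: float = GWS_P_THRESHOLD,
    report: SelectionReport | None = None,
) -> SummaryStatSet:
    """Retain variants with p strictly below the genome-wide threshold."""
    keep = stats.records["pval"] < p_thresh
    if report is not None:
        for snp in stats.records.loc[~keep, "snp_id"]:
            report.exclude(snp, NOT_GWS, f"p >= {p_thresh:g}")
    out = stats.replace(stats.records[keep])
    if len(out) == 0:
        logger.warning("%s: no variant passes p < %g", stats.trait_label, p_thresh)
    return out


def clump(
    stats: SummaryStatSet,
    ld: LDReference,
    window_kb: float | None = CLUMP_WINDOW_KB,
    r2_max: float = CLUMP_R2,
    report: SelectionReport | None = None,
) -> SummaryStatSet:
    """Greedy LD clumping by ascending p-value.

    Repeatedly takes the remaining variant with the smallest p-value as
    index (ties broken by chrom, pos, snp_id) and discards remaining
    variants on the same chromosome within ``window_kb`` (center-to-center)
    whose r² with the index is >= ``r2_max``. ``window_kb=None`` removes the
    distance restriction and checks every pair (the within-region drug-target
    mode). Pairs absent from the LD reference count as r² = 1 inside the
    window (unknown LD is never trusted) and r² = 0 beyond it.
    """
    df = stats.records.sort_values(
        ["pval", "chrom", "pos", "snp_id"], kind="stable"
    ).reset_index(drop=True)
    remaining = list(df.itertuples())
    kept_ids: list[str] = []
    while remaining:
        index = remaining.pop(0)
        kept_ids.append(index.snp_id)
        survivors = []
        for v in remaining:
            in_window = window_kb is None or (
                v.chrom == index.chrom and abs(v.pos - index.pos) <= window_kb * 1000
            )
            if not in_window:
                survivors.append(v)
                continue
            if not ld.has_pair(index.snp_id, v.snp_id):
                logger.warning(
                    "LD unknown for in-window pair (%s, %s); treating r²=1 (conservative)",
                    index.snp_id,
                    v.snp_id,
                )
            r2 = ld.r2(index.snp_id, v.snp_id, default=1.0)
            if r2 >= r2_max:
                if report is not None:
                    report.exclude(v.snp_id, CLUMPED, f"r²={r2:g} with index {index.snp_id}")
            else:
                survivors.append(v)
        remaining = survivors
    out = stats.replace(stats.records[stats.records["snp_id"].isin(kept_ids)])
    return out


def screen_confounders(
    stats: SummaryStatSet,
    table: ConfounderTable,
    p_thresh: float = GWS_P_THRESHOLD,
    report: SelectionReport | None = None,
) -> SummaryStatSet:
    """Remove variants associated with any confounder at p < ``p_thresh``."""
    if len(table) == 0:
        return stats.replace(stats.records)
    hits = table.rows[table.rows["pval"] < p_thresh]
    flagged = hits.groupby("snp_id")["confounder_trait"].agg(", ".join)
    drop = stats.records["snp_id"].isin(flagged.index)
    for snp in stats.records.loc[drop, "snp_id"]:
        detail = flagged[snp]
        logger.info("%s removed by confounder screen (%s)", snp, detail)
        if report is not None:
            report.exclude(snp, CONFOUNDER, detail)
    return stats.replace(stats.records[~drop])


def filter_instrument_strength(
    stats: SummaryStatSet,
    f_min: float = F_MIN,
    report: SelectionReport | None = None,
) -> SummaryStatSet:
    """Remove weak instruments: the removal condition is F < ``f_min``
    (F = f_min exactly is kept)."""
    f = f_statistic(stats.records["beta"].to_numpy(), stats.records["se"].to_numpy())
    weak = f < f_min
    if report is not None:
        for snp, fv in zip(stats.records.loc[weak, "snp_id"], np.atleast_1d(f)[weak]):
            report.exclude(snp, WEAK_F, f"F={fv:.3g}")
    return stats.replace(stats.records[~weak])


def select_instruments(
    stats: SummaryStatSet,
    ld: LDReference,
    confounders: ConfounderTable | None = None,
    p_thresh: float = GWS_P_THRESHOLD,
    window_kb: float = CLUMP_WINDOW_KB,
    r2_max: float = CLUMP_R2,
    f_min: float = F_MIN,
) -> tuple[SummaryStatSet, SelectionReport]:
    """Full selection pipeline: significance → clump → confounder screen → F filter."""
    report = SelectionReport()
    report.record_stage("input", len(stats))
    gws = filter_genome_wide(stats, p_thresh, report)
    report.record_stage("genome_wide_significant", len(gws))
    clumped = clump(gws, ld, window_kb, r2_max, report)
    report.record_stage("post_clump", len(clumped))
    screened = screen_confounders(clumped, confounders or ConfounderTable.empty(), p_thresh, report)
    report.record_stage("post_confounder_screen", len(screened))
    strong = filter_instrument_strength(screened, f_min, report)
    report.record_stage("post_f_filter", len(strong))
    return strong, report
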