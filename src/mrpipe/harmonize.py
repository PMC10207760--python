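"""Harmonization of exposure and outcome summary statistics.

Aligns both studies onto the exposure's effect allele so that every
per-SNP (beta_exp, beta_out) pair refers to the same allele. Handles
swapped allele order (sign flip + eaf complement), opposite-strand
reporting (relabel via base complement, non-palindromic only), and
palindromic A/T and C/G variants: those with an intermediate allele
frequency on either side are excluded (the strand is unresolvable), the
rest are aligned by matching minor/major allele frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SummaryStatSet

logger = logging.getLogger("mrpipe")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PALINDROMIC = "PALINDROMIC"
IRRECONCILABLE = "IRRECONCILABLE"

AF_WINDOW_DEFAULT = 0.08

INSTRUMENT_COLUMNS = (
    "snp_id",
    "effect_allele",
    "other_allele",
    "beta_exp",
    "se_exp",
    "eaf_exp",
    "beta_out",
    "se_out",
    "eaf_out",
    "flipped",
)


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizationAudit:
    """Count conservation: intersection = retained + palindromic + irreconcilable."""

    n_intersection: int = 0
    n_retained: int = 0
    n_palindromic_dropped: int = 0
    n_irreconcilable: int = 0
    dropped: list[tuple[str, str, str]] = field(default_factory=list)  # (snp, code, detail)

    def balanced(self) -> bool:
        return (
            self.n_intersection
            == self.n_retained + self.n_palindromic_dropped + self.n_irreconcilable
        )


@dataclass
class InstrumentSet:
    """Harmonized per-SNP exposure/outcome effect pairs — the input every
    causal estimator consumes. The container is trait-agnostic; units are
    whatever the outcome study reports (e.g. years of residual age at onset).
    """

    data: pd.DataFrame
    audit: HarmonizationAudit | None = None

    def __post_init__(self) -> None:
        missing = [c for c in INSTRUMENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"InstrumentSet missing columns: {missing}")
        if np.any(self.data["se_exp"] <= 0) or np.any(self.data["se_out"] <= 0):
            raise ValueError("standard errors must be positive")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out, snp_id=None, **extra) -> "InstrumentSet":
        """Build an instrument set directly from effect arrays (allele
        bookkeeping already resolved); used heavily in simulation."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        n = beta_exp.size
        df = pd.DataFrame(
            {
                "snp_id": snp_id if snp_id is not None else [f"snp{i}" for i in range(n)],
                "effect_allele": extra.get("effect_allele", ["A"] * n),
                "other_allele": extra.get("other_allele", ["G"] * n),
                "beta_exp": beta_exp,
                "se_exp": np.asarray(se_exp, dtype=float),
                "eaf_exp": extra.get("eaf_exp", np.full(n, 0.3)),
                "beta_out": np.asarray(beta_out, dtype=float),
                "se_out": np.asarray(se_out, dtype=float),
                "eaf_out": extra.get("eaf_out", np.full(n, 0.3)),
                "flipped": extra.get("flipped", np.zeros(n, dtype=bool)),
            }
        )
        return cls(df)

    @property
    def beta_exp(self) -> np.ndarray:
        return self.data["beta_exp"].to_numpy(dtype=float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.data["se_exp"].to_numpy(dtype=float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.data["beta_out"].to_numpy(dtype=float)

    @property
    def se_out(self) -> np.ndarray:
        return self.data["se_out"].to_numpy(dtype=float)

    def subset(self, mask) -> "InstrumentSet":
        return InstrumentSet(self.data[np.asarray(mask)].copy())

    def to_frame(self) -> pd.DataFrame:
        return self.data.copy()


def _intermediate(eaf: float, af_window: float) -> bool:
    return abs(eaf - 0.5) < af_window


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    af_window: float = AF_WINDOW_DEFAULT,
) -> InstrumentSet:
    """Harmonize exposure and outcome associations onto common effect alleles.

    Per shared SNP: (i) same allele order → keep; (ii) swapped order → negate
    beta_out and complement eaf_out; (iii) strand complement (non-palindromic
    only) → relabel, then (i)/(ii); (iv) palindromic with eaf within
    ``af_window`` of 0.5 on either side → dropped and counted; palindromic
    outside the window → aligned so minor alleles correspond; (v) anything
    else → dropped as irreconcilable.
    """
    merged = exposure.records.merge(
        outcome.records, on="snp_id", suffixes=("_exp", "_out"), how="inner"
    )
    if len(merged) == 0:
        raise ValueError("exposure and outcome share no snp_id: nothing to harmonize")
    audit = HarmonizationAudit(n_intersection=len(merged))

    rows = []
    for r in merged.itertuples():
        ea_e, oa_e = r.effect_allele_exp, r.other_allele_exp
        ea_o, oa_o = r.effect_allele_out, r.other_allele_out
        beta_out, eaf_out = r.beta_out, r.eaf_out
        flipped = False

        if is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                audit.n_irreconcilable += 1
                audit.dropped.append((r.snp_id, IRRECONCILABLE, f"alleles {ea_o}/{oa_o} vs {ea_e}/{oa_e}"))
                continue
            if pd.isna(r.eaf_exp) or pd.isna(eaf_out):
                audit.n_palindromic_dropped += 1
                audit.dropped.append((r.snp_id, PALINDROMIC, "missing eaf, cannot frequency-align"))
                continue
            if _intermediate(r.eaf_exp, af_window) or _intermediate(eaf_out, af_window):
                audit.n_palindromic_dropped += 1
                audit.dropped.append((r.snp_id, PALINDROMIC, "intermediate allele frequency"))
                continue
            # nominal label alignment, then strand resolution by frequency
            if ea_o != ea_e:
                beta_out, eaf_out, flipped = -beta_out, 1.0 - eaf_out, not flipped
            if abs(r.eaf_exp - eaf_out) > abs(r.eaf_exp - (1.0 - eaf_out)):
                beta_out, eaf_out, flipped = -beta_out, 1.0 - eaf_out, not flipped
        else:
            pair_o = (ea_o, oa_o)
            comp_pair = (COMPLEMENT[ea_o], COMPLEMENT[oa_o])
            if set(pair_o) == {ea_e, oa_e}:
                pass
            elif set(comp_pair) == {ea_e, oa_e}:
                ea_o, oa_o = comp_pair  # opposite-strand report: relabel
            else:
                audit.n_irreconcilable += 1
                audit.dropped.append((r.snp_id, IRRECONCILABLE, f"alleles {ea_o}/{oa_o} vs {ea_e}/{oa_e}"))
                continue
            if ea_o != ea_e:
                beta_out, eaf_out, flipped = -beta_out, 1.0 - eaf_out, True

        rows.append(
            {
                "snp_id": r.snp_id,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "beta_exp": r.beta_exp,
                "se_exp": r.se_exp,
                "eaf_exp": r.eaf_exp,
                "beta_out": beta_out,
                "se_out": r.se_out,
                "eaf_out": eaf_out,
                "flipped": flipped,
            }
        )
        audit.n_retained += 1

    for snp, code, detail in audit.dropped:
        logger.info("harmonization dropped %s (%s): %s", snp, code, detail)
    data = pd.DataFrame(rows, columns=list(INSTRUMENT_COLUMNS))
    return InstrumentSet(data, audit=audit)


def write_instrument_set(instruments: InstrumentSet, path) -> None:
    """Write a harmonized set as TSV with the flip audit column."""
    instruments.data.to_csv(path, sep="\t", index=False)


def read_instrument_set(path) -> InstrumentSet:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    df["flipped"] = df["flipped"].astype(bool)
    return InstrumentSet(df)
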