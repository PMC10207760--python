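"""Readers, writers and validated containers for GWAS summary statistics.

Everything downstream (instrument selection, harmonization, estimation)
consumes the containers defined here:

* :class:`SummaryStatSet` — per-variant associations with one trait,
* :class:`LDReference`   — pairwise r² lookup used by clumping,
* :class:`GeneRegion`    — drug-target gene/regulatory intervals,
* :class:`ConfounderTable` — local variant-to-confounder association lookup.

All on-disk formats are plain text: tab-separated summary statistics with a
header (gzip transparently supported), BED-style region files, long-format
LD tables. Internal coordinates are 1-based inclusive; BED input is
converted once at the boundary.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mrpipe")

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
DRUG_CLASSES = frozenset({"ACEI", "BB", "CCB"})

#: canonical column order of a summary-statistics table
SUMMARY_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
)


class SummaryStatsError(ValueError):
    """Fatal problem with a summary-statistics, LD or region file."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` in trait
    units; ``eaf`` is the effect-allele frequency.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise SummaryStatsError(
                f"{self.snp_id}: alleles must be single bases from A/C/G/T "
                f"(got {self.effect_allele!r}/{self.other_allele!r})"
            )
        if self.effect_allele == self.other_allele:
            raise SummaryStatsError(f"{self.snp_id}: effect and other allele are identical")
        if not 0.0 < self.eaf < 1.0:
            raise SummaryStatsError(f"{self.snp_id}: eaf {self.eaf} outside (0, 1)")
        if not self.se > 0.0:
            raise SummaryStatsError(f"{self.snp_id}: se {self.se} must be positive")
        if not 0.0 < self.pval <= 1.0:
            raise SummaryStatsError(f"{self.snp_id}: pval {self.pval} outside (0, 1]")


@dataclass
class LoadReport:
    """Bookkeeping from a summary-stats load: no row vanishes silently."""

    n_input: int = 0
    n_loaded: int = 0
    n_duplicates_removed: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)  # (line number, reason)

    def balanced(self) -> bool:
        return self.n_input == self.n_loaded + self.n_duplicates_removed + len(self.rejects)


@dataclass
class SummaryStatSet:
    """Validated GWAS summary statistics for one trait.

    ``records`` is a DataFrame with :data:`SUMMARY_COLUMNS`, unique by
    ``snp_id``. ``trait_sd`` is the phenotype standard deviation in trait
    units (e.g. 21.5 mmHg for SBP, 11.4 for DBP) and feeds the variance-
    explained formula R² = 2 β² EAF (1−EAF) / SD².
    """

    trait_label: str
    trait_sd: float
    records: pd.DataFrame
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        if not self.trait_sd > 0:
            raise SummaryStatsError(f"trait_sd must be positive, got {self.trait_sd}")
        missing = [c for c in SUMMARY_COLUMNS if c not in self.records.columns]
        if missing:
            raise SummaryStatsError(f"records missing columns: {missing}")
        if self.records["snp_id"].duplicated().any():
            dups = self.records.loc[self.records["snp_id"].duplicated(), "snp_id"].tolist()
            raise SummaryStatsError(f"duplicate snp_id after loading: {dups[:5]}")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> pd.Series:
        return self.records["snp_id"]

    def subset(self, snp_ids) -> "SummaryStatSet":
        keep = self.records[self.records["snp_id"].isin(set(snp_ids))]
        return SummaryStatSet(self.trait_label, self.trait_sd, keep.copy())

    def replace(self, records: pd.DataFrame) -> "SummaryStatSet":
        return SummaryStatSet(self.trait_label, self.trait_sd, records.reset_index(drop=True))


def read_dialect(path) -> dict:
    """Load a column-mapping config (canonical name -> file column) from YAML/JSON."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _validate_rows(df: pd.DataFrame, first_data_line: int) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Vectorized row validation; returns (valid rows, rejects with line numbers)."""
    lines = np.arange(first_data_line, first_data_line + len(df))
    reasons = pd.Series([""] * len(df), index=df.index)

    alleles_ok = df["effect_allele"].isin(VALID_ALLELES) & df["other_allele"].isin(VALID_ALLELES)
    reasons[~alleles_ok] = "alleles must be single bases A/C/G/T (multi-allelic/indel rejected)"
    same = alleles_ok & (df["effect_allele"] == df["other_allele"])
    reasons[same] = "effect and other allele identical"
    with np.errstate(invalid="ignore"):
        bad_eaf = ~((df["eaf"] > 0) & (df["eaf"] < 1))
        bad_se = ~(df["se"] > 0)
        bad_p = ~((df["pval"] > 0) & (df["pval"] <= 1))
    reasons[(reasons == "") & bad_eaf] = "eaf outside (0, 1)"
    reasons[(reasons == "") & bad_se] = "se not positive"
    reasons[(reasons == "") & bad_p] = "pval outside (0, 1]"

    bad = reasons != ""
    rejects = [(int(line), f"{df.loc[i, 'snp_id']}: {reasons[i]}") for i, line in zip(df.index[bad], lines[bad])]
    return df[~bad], rejects


def read_summary_stats(
    path,
    dialect: dict | None = None,
    trait_label: str = "trait",
    trait_sd: float = 1.0,
) -> SummaryStatSet:
    """Read a tab-separated summary-statistics file into a validated set.

    ``dialect`` maps canonical column names (see :data:`SUMMARY_COLUMNS`) to
    the file's column names; omitted entries default to the canonical name.
    Duplicate ``snp_id`` rows are resolved by keeping the smallest p-value;
    invalid rows are rejected with their line number in the load report.
    """
    path = Path(path)
    if not path.exists():
        raise SummaryStatsError(f"summary-statistics file not found: {path}")
    mapping = {c: c for c in SUMMARY_COLUMNS}
    if dialect:
        mapping.update({k: v for k, v in dialect.items() if k in mapping})

    df = pd.read_csv(path, sep="\t", dtype={mapping["snp_id"]: str, mapping["chrom"]: str})
    missing = [v for v in mapping.values() if v not in df.columns]
    if missing:
        raise SummaryStatsError(f"{path}: missing required column(s) {missing}")
    df = df.rename(columns={v: k for k, v in mapping.items()})[list(SUMMARY_COLUMNS)]
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    report = LoadReport(n_input=len(df))
    valid, report.rejects = _validate_rows(df, first_data_line=2)
    for line, reason in report.rejects:
        logger.warning("%s line %d rejected: %s", path.name, line, reason)

    # duplicate snp_id: keep the smallest p-value (stable on ties)
    valid = valid.sort_values("pval", kind="stable")
    deduped = valid.drop_duplicates("snp_id", keep="first")
    report.n_duplicates_removed = len(valid) - len(deduped)
    if report.n_duplicates_removed:
        logger.info(
            "%s: %d duplicate snp_id rows removed (kept minimum p-value)",
            path.name,
            report.n_duplicates_removed,
        )
    deduped = deduped.sort_index().reset_index(drop=True)
    deduped["pos"] = deduped["pos"].astype(np.int64)
    report.n_loaded = len(deduped)
    return SummaryStatSet(trait_label, trait_sd, deduped, load_report=report)


def write_summary_stats(stats: SummaryStatSet, path) -> None:
    """Write a summary-stats set as TSV (gzip when the path ends in .gz).

    Floats are written with repr precision, so write→read round-trips
    bit-identically.
    """
    stats.records[list(SUMMARY_COLUMNS)].to_csv(path, sep="\t", index=False)


class LDReference:
    """Symmetric pairwise-r² lookup with an optional variant position table.

    Missing pairs default to r² = 0 (the distant-pair convention); callers
    that must be conservative about unknown local LD (clumping) pass
    ``default=1.0`` for within-window queries.
    """

    def __init__(self, pairs: dict | None = None, positions: dict | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        self.positions: dict[str, tuple[str, int]] = dict(positions or {})
        for (a, b), r2 in (pairs or {}).items():
            self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise SummaryStatsError(f"r² for ({a}, {b}) outside [0, 1]: {r2}")
        if a != b:
            self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str, default: float = 0.0) -> float:
        """r² between two variants; self-pairs are 1, missing pairs ``default``."""
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), default)

    def has_pair(self, a: str, b: str) -> bool:
        return a == b or self._key(a, b) in self._r2

    def __len__(self) -> int:
        return len(self._r2)


def read_ld_reference(pairs_path, variants_path=None) -> LDReference:
    """Read a long-format LD table (snp_a, snp_b, r2) plus optional variant positions."""
    df = pd.read_csv(pairs_path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise SummaryStatsError(f"{pairs_path}: missing column {col}")
    if ((df["r2"] < 0) | (df["r2"] > 1)).any():
        bad = df[(df["r2"] < 0) | (df["r2"] > 1)].iloc[0]
        raise SummaryStatsError(f"{pairs_path}: r² outside [0, 1] for ({bad.snp_a}, {bad.snp_b}): {bad.r2}")
    positions = None
    if variants_path is not None:
        vt = pd.read_csv(variants_path, sep="\t", dtype={"snp": str, "chrom": str})
        positions = {r.snp: (r.chrom, int(r.pos)) for r in vt.itertuples()}
    ld = LDReference(positions=positions)
    for row in df.itertuples():
        ld.add(row.snp_a, row.snp_b, row.r2)
    return ld


def write_ld_reference(ld: LDReference, pairs_path, variants_path=None) -> None:
    rows = [{"snp_a": a, "snp_b": b, "r2": r2} for (a, b), r2 in sorted(ld._r2.items())]
    pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(pairs_path, sep="\t", index=False)
    if variants_path is not None:
        vt = [{"snp": s, "chrom": c, "pos": p} for s, (c, p) in sorted(ld.positions.items())]
        pd.DataFrame(vt, columns=["snp", "chrom", "pos"]).to_csv(variants_path, sep="\t", index=False)


@dataclass
class GeneRegion:
    """A drug-target gene with its regulatory intervals (1-based inclusive)."""

    gene_symbol: str
    drug_class: str
    chrom: str
    start: int
    end: int
    regulatory_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.drug_class not in DRUG_CLASSES:
            raise SummaryStatsError(
                f"unknown drug class {self.drug_class!r} for {self.gene_symbol} (expected one of {sorted(DRUG_CLASSES)})"
            )
        if self.start > self.end:
            raise SummaryStatsError(f"{self.gene_symbol}: start {self.start} > end {self.end}")
        for c, s, e in self.regulatory_intervals:
            if s > e:
                raise SummaryStatsError(f"{self.gene_symbol}: malformed regulatory interval ({c}, {s}, {e})")

    def contains(self, chrom: str, pos: int) -> bool:
        """1-based inclusive containment in the gene body or any regulatory interval."""
        if chrom == self.chrom and self.start <= pos <= self.end:
            return True
        return any(chrom == c and s <= pos <= e for c, s, e in self.regulatory_intervals)


def read_gene_regions(path) -> list[GeneRegion]:
    """Read drug-target regions from a BED-like file.

    Columns: chrom, start, end, gene_symbol, drug_class[, feature]. BED
    coordinates are 0-based half-open on disk and converted to 1-based
    inclusive. ``feature`` is ``gene`` (default) or ``regulatory``;
    regulatory lines attach to the gene line with the same symbol/class.
    """
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    genes: dict[tuple[str, str], GeneRegion] = {}
    pending_reg: list[tuple[str, str, str, int, int, int]] = []
    with opener(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise SummaryStatsError(f"{path} line {lineno}: expected >=5 columns, got {len(parts)}")
            chrom, start0, end0, gene, klass = parts[:5]
            feature = parts[5] if len(parts) > 5 else "gene"
            if klass not in DRUG_CLASSES:
                raise SummaryStatsError(f"{path} line {lineno}: unknown drug class {klass!r}")
            start1, end1 = int(start0) + 1, int(end0)  # BED -> 1-based inclusive
            if feature == "gene":
                genes[(gene, klass)] = GeneRegion(gene, klass, chrom, start1, end1)
            elif feature == "regulatory":
                pending_reg.append((gene, klass, chrom, start1, end1, lineno))
            else:
                raise SummaryStatsError(f"{path} line {lineno}: unknown feature {feature!r}")
    for gene, klass, chrom, s, e, lineno in pending_reg:
        key = (gene, klass)
        if key not in genes:
            raise SummaryStatsError(f"{path} line {lineno}: regulatory interval for unknown gene {gene} ({klass})")
        genes[key].regulatory_intervals.append((chrom, s, e))
    return list(genes.values())


def write_gene_regions(regions: list[GeneRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_symbol}\t{r.drug_class}\tgene\n")
            for c, s, e in r.regulatory_intervals:
                fh.write(f"{c}\t{s - 1}\t{e}\t{r.gene_symbol}\t{r.drug_class}\tregulatory\n")


@dataclass
class ConfounderTable:
    """Local lookup of variant-confounder associations (stands in for a live
    PhenoScanner query; reproducible offline)."""

    rows: pd.DataFrame  # snp_id, confounder_trait, pval

    def __post_init__(self) -> None:
        for col in ("snp_id", "confounder_trait", "pval"):
            if col not in self.rows.columns:
                raise SummaryStatsError(f"confounder table missing column {col}")
        bad = ~((self.rows["pval"] > 0) & (self.rows["pval"] <= 1))
        if bad.any():
            raise SummaryStatsError(f"confounder table: {int(bad.sum())} pval(s) outside (0, 1]")

    @classmethod
    def empty(cls) -> "ConfounderTable":
        return cls(pd.DataFrame(columns=["snp_id", "confounder_trait", "pval"]))

    def __len__(self) -> int:
        return len(self.rows)


def read_confounder_table(path) -> ConfounderTable:
    return ConfounderTable(pd.read_csv(path, sep="\t", dtype={"snp_id": str, "confounder_trait": str}))


def write_confounder_table(table: ConfounderTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
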