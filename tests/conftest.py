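import numpy as np
import pandas as pd
import pytest

from mrpipe.io import SUMMARY_COLUMNS, LDReference, SummaryStatSet


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a summary-stats frame from partial row dicts with sane defaults."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pval": 1e-10,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["snp_id"] = f"rs{i + 1}"
        rec["pos"] = 1000 + i * 100_000
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out, columns=list(SUMMARY_COLUMNS))


def make_stats(rows: list[dict], label: str = "SBP", sd: float = 21.5) -> SummaryStatSet:
    return SummaryStatSet(label, sd, make_records(rows))


@pytest.fixture
def five_snp_instruments():
    """A fixed five-instrument set with hand-pickable numbers."""
    from mrpipe.harmonize import InstrumentSet

    return InstrumentSet.from_arrays(
        beta_exp=[0.12, 0.08, 0.15, 0.05, 0.10],
        se_exp=[0.01, 0.012, 0.009, 0.011, 0.010],
        beta_out=[0.030, 0.018, 0.042, 0.011, 0.020],
        se_out=[0.010, 0.012, 0.011, 0.013, 0.009],
    )


@pytest.fixture
def empty_ld():
    return LDReference()


def brute_force_clump(records: pd.DataFrame, ld, window_kb, r2_max):
    """Independent greedy-clumping oracle: explicit set bookkeeping, no early
    removal — a variant survives iff no already-kept index on the same
    chromosome within the window has r² >= threshold with it."""
    order = records.sort_values(["pval", "chrom", "pos", "snp_id"]).itertuples()
    kept = []
    for v in order:
        conflicted = False
        for k in kept:
            close = window_kb is None or (
                k.chrom == v.chrom and abs(k.pos - v.pos) <= window_kb * 1000
            )
            if close and ld.r2(k.snp_id, v.snp_id, default=1.0) >= r2_max:
                conflicted = True
                break
        if not conflicted:
            kept.append(v)
    return sorted(k.snp_id for k in kept)
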