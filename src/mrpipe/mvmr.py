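"""Multivariable Mendelian randomization (MVMR).

Estimates the direct effect of each exposure (e.g. SBP and DBP, which are
strongly correlated) on the outcome jointly, by zero-intercept multiple
weighted least squares of SNP-outcome effects on the matrix of SNP-exposure
effects, weights 1/se_out². The instrument set is the union of each
exposure's univariable instruments, restricted to SNPs available in every
summary set and harmonized to a common effect allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import MREstimate, Z95, scale_estimate
from .harmonize import harmonize
from .io import SummaryStatSet

logger = logging.getLogger("mrpipe")


@dataclass
class MultiInstrumentSet:
    """Per-SNP effects on several exposures plus the outcome, one row per SNP.

    Columns: ``snp_id``, ``beta_exp_<label>``/``se_exp_<label>`` per
    exposure, ``beta_out``, ``se_out``.
    """

    exposures: list[str]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        for label in self.exposures:
            for col in (f"beta_exp_{label}", f"se_exp_{label}"):
                if col not in self.data.columns:
                    raise ValueError(f"MultiInstrumentSet missing column {col}")
        if np.any(self.data["se_out"] <= 0):
            raise ValueError("se_out must be positive")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def exposure_matrix(self) -> np.ndarray:
        return np.column_stack([self.data[f"beta_exp_{l}"].to_numpy(float) for l in self.exposures])


def build_multi_set(
    exposure_sets: list[SummaryStatSet],
    outcome: SummaryStatSet,
    instrument_ids=None,
    af_window: float = 0.08,
) -> MultiInstrumentSet:
    """Assemble the joint instrument set for MVMR.

    ``instrument_ids`` is the union of per-exposure instruments (defaults to
    the union of all SNPs in ``exposure_sets``). SNPs missing from any
    exposure or the outcome are dropped and logged; an exposure missing more
    than half of the union is a fatal error. All effects are harmonized to
    the first exposure's effect alleles.
    """
    if len(exposure_sets) < 2:
        raise ValueError("MVMR requires at least two exposures")
    labels = [s.trait_label for s in exposure_sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"exposure labels must be unique, got {labels}")
    union = set(instrument_ids) if instrument_ids is not None else set()
    if not union:
        for s in exposure_sets:
            union |= set(s.snp_ids)

    for s in exposure_sets:
        missing = union - set(s.snp_ids)
        if len(missing) > 0.5 * len(union):
            raise ValueError(
                f"exposure {s.trait_label} is missing {len(missing)}/{len(union)} of the instrument union"
            )
        for snp in sorted(missing):
            logger.info("MVMR: %s dropped (absent from %s)", snp, s.trait_label)

    present = set.intersection(*(set(s.snp_ids) for s in exposure_sets)) & union
    dropped_outcome = present - set(outcome.snp_ids)
    for snp in sorted(dropped_outcome):
        logger.info("MVMR: %s dropped (absent from outcome %s)", snp, outcome.trait_label)
    present &= set(outcome.snp_ids)
    if not present:
        raise ValueError("no instrument is present in every exposure and the outcome")

    anchor = exposure_sets[0].subset(present)
    # outcome aligned to the anchor exposure's effect alleles
    h_out = harmonize(anchor, outcome.subset(present), af_window=af_window)
    frame = h_out.data[["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"]].rename(
        columns={
            "beta_exp": f"beta_exp_{labels[0]}",
            "se_exp": f"se_exp_{labels[0]}",
        }
    )
    # every other exposure aligned the same way (treated as an 'outcome' of the anchor)
    for s in exposure_sets[1:]:
        h = harmonize(anchor, s.subset(present), af_window=af_window)
        cols = h.data[["snp_id", "beta_out", "se_out"]].rename(
            columns={"beta_out": f"beta_exp_{s.trait_label}", "se_out": f"se_exp_{s.trait_label}"}
        )
        frame = frame.merge(cols, on="snp_id", how="inner")
    return MultiInstrumentSet(labels, frame.reset_index(drop=True))


def mvmr_ivw(
    multi: MultiInstrumentSet,
    scale_factors: dict[str, float] | None = None,
    random_effects: bool = True,
) -> list[MREstimate]:
    """Zero-intercept multiple WLS of beta_out on the exposure-effect matrix.

    Returns one estimate per exposure, with multiplicative random-effects SE
    inflation max(1, sqrt(Q/(n−k))). ``scale_factors`` maps exposure label to
    the reporting scale (e.g. {'SBP': 10, 'DBP': 5}).
    """
    n, k = len(multi), len(multi.exposures)
    if n <= k:
        raise ValueError(f"MVMR needs more instruments ({n}) than exposures ({k})")
    X = multi.exposure_matrix()
    y = multi.data["beta_out"].to_numpy(float)
    w = 1.0 / multi.data["se_out"].to_numpy(float) ** 2
    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(Xw) < k:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (multi.exposures[i], multi.exposures[j])
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient exposure matrix; collinear exposures: {pairs or multi.exposures}")

    xtx = Xw.T @ Xw
    beta = np.linalg.solve(xtx, X.T @ (w * y))
    cov = np.linalg.inv(xtx)
    q = float(np.sum(w * (y - X @ beta) ** 2))
    infl = max(1.0, np.sqrt(q / (n - k))) if random_effects else 1.0
    ses = np.sqrt(np.diag(cov)) * infl

    estimates = []
    for j, label in enumerate(multi.exposures):
        p = 2.0 * sps.norm.sf(abs(beta[j] / ses[j]))
        est = MREstimate(
            method=f"mvmr_ivw[{label}]",
            beta=float(beta[j]),
            se=float(ses[j]),
            ci_low=float(beta[j] - Z95 * ses[j]),
            ci_high=float(beta[j] + Z95 * ses[j]),
            pval=float(p),
            n_snps=n,
        )
        if scale_factors and label in scale_factors:
            est = scale_estimate(est, scale_factors[label])
        estimates.append(est)
    return estimates


def conditional_f(multi: MultiInstrumentSet) -> dict[str, float]:
    """Conditional instrument-strength diagnostic per exposure.

    Weighted regression of one exposure's effects on the others (weights
    1/se_exp²); the weighted residual sum of squares over its degrees of
    freedom measures how much independent instrument signal remains.
    Approximate (cross-exposure sampling covariance is not available from
    two-sample summary data); reported for information only, never filtered on.
    """
    n, k = len(multi), len(multi.exposures)
    X = multi.exposure_matrix()
    out: dict[str, float] = {}
    for j, label in enumerate(multi.exposures):
        xj = X[:, j]
        others = np.delete(X, j, axis=1)
        wj = 1.0 / multi.data[f"se_exp_{label}"].to_numpy(float) ** 2
        ow = others * np.sqrt(wj)[:, None]
        coef, *_ = np.linalg.lstsq(ow, xj * np.sqrt(wj), rcond=None)
        qj = float(np.sum(wj * (xj - others @ coef) ** 2))
        out[label] = qj / (n - (k - 1))
    return out
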