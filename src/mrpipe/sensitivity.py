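"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q against the IVW or Egger fit, the MR-Egger intercept test, and
MR-PRESSO (global residual-sum-of-squares test, per-SNP outlier test with
Bonferroni correction, and a distortion test comparing estimates before and
after outlier removal). MR-PRESSO p-values use the add-one empirical
estimator (1 + #{sim ≥ obs})/(1 + n_sim), so they are never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .estimators import MREstimate, PleiotropyResult, _egger_fit, ivw, mr_egger
from .harmonize import InstrumentSet

logger = logging.getLogger("mrpipe")


@dataclass
class HeterogeneityResult:
    """Cochran's Q with its chi-square upper-tail p-value."""

    method: str  # "ivw" or "egger"
    q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    """MR-PRESSO global/outlier/distortion results, fully seeded."""

    global_rss_pval: float
    outlier_indices: list[int]
    outlier_pvals: np.ndarray
    distortion_pval: float | None
    estimate_before: MREstimate
    estimate_after: MREstimate | None
    n_sim: int
    seed: int | None


def cochran_q(instruments: InstrumentSet, method: str = "ivw") -> HeterogeneityResult:
    """Q = Σ wᵢ (beta_outᵢ − fitᵢ)², w = 1/se_out², with the fit from the
    zero-intercept (IVW, df = n−1) or free-intercept (Egger, df = n−2)
    weighted regression."""
    n = len(instruments)
    bx, _, by, sy = instruments.beta_exp, instruments.se_exp, instruments.beta_out, instruments.se_out
    w = 1.0 / sy**2
    if method == "ivw":
        if n < 2:
            raise ValueError("cochran_q (ivw) requires at least 2 instruments")
        beta = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
        q = float(np.sum(w * (by - beta * bx) ** 2))
        df = n - 1
    elif method == "egger":
        if n < 3:
            raise ValueError("cochran_q (egger) requires at least 3 instruments")
        *_, q = _egger_fit(bx, by, sy)
        df = n - 2
    else:
        raise ValueError(f"unknown method {method!r} (expected 'ivw' or 'egger')")
    pval = float(sps.chi2.sf(q, df))
    return HeterogeneityResult(method, q, df, pval)


def egger_intercept_test(instruments: InstrumentSet) -> PleiotropyResult:
    """Directional-pleiotropy test: the MR-Egger regression intercept."""
    return mr_egger(instruments)[1]


def _loo_rss(bx, by, w):
    """Leave-one-out IVW residual machinery, vectorized.

    Returns (per-SNP weighted squared LOO residuals, their sum). ``by`` may
    be a (n_sim, n) matrix for the simulated null datasets.
    """
    by = np.atleast_2d(by)
    sxx = np.sum(w * bx * bx)
    sxy = by @ (w * bx)  # (n_sim,)
    denom = sxx - w * bx * bx  # (n,)
    beta_loo = (sxy[:, None] - by * (w * bx)[None, :]) / denom[None, :]
    res_sq = w[None, :] * (by - beta_loo * bx[None, :]) ** 2
    return res_sq, res_sq.sum(axis=1)


def mr_presso(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """MR-PRESSO: pleiotropy residual sum of squares and outlier test.

    Observed RSS is the weighted sum of squared leave-one-out IVW residuals.
    The null distribution comes from ``n_sim`` parametric datasets with
    beta_out,i ~ Normal(beta_IVW · beta_exp,i, se_out,i), each scored the
    same leave-one-out way. Outliers are SNPs whose observed squared
    residual exceeds its simulated distribution at the Bonferroni-corrected
    level ``outlier_alpha / n``; the distortion test compares the
    with/without-outlier estimate shift to the shift from removing random
    same-size subsets.
    """
    n = len(instruments)
    if n < 4:
        raise ValueError(f"mr_presso requires at least 4 instruments, got {n}")
    bx, by, sy = instruments.beta_exp, instruments.beta_out, instruments.se_out
    w = 1.0 / sy**2
    rng = np.random.default_rng(seed)

    obs_res_sq, obs_rss = _loo_rss(bx, by, w)
    obs_res_sq, obs_rss = obs_res_sq[0], float(obs_rss[0])

    beta_full = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    y_sim = rng.normal(beta_full * bx, sy, size=(n_sim, n))
    sim_res_sq, sim_rss = _loo_rss(bx, y_sim, w)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (1 + n_sim))
    outlier_pvals = (1 + np.sum(sim_res_sq >= obs_res_sq[None, :], axis=0)) / (1 + n_sim)
    flagged = np.flatnonzero(outlier_pvals < outlier_alpha / n)

    estimate_before = ivw(instruments)
    estimate_after = None
    distortion_p = None
    if flagged.size and n - flagged.size >= 2:
        keep = np.ones(n, dtype=bool)
        keep[flagged] = False
        estimate_after = ivw(instruments.subset(keep))
        b_after = estimate_after.beta
        if b_after != 0:
            d_obs = (b_after - estimate_before.beta) / abs(b_after)
            d_sim = np.empty(n_sim)
            for i in range(n_sim):
                drop = rng.choice(n, size=flagged.size, replace=False)
                m = np.ones(n, dtype=bool)
                m[drop] = False
                b_sub = float(np.sum(w[m] * bx[m] * by[m]) / np.sum(w[m] * bx[m] * bx[m]))
                d_sim[i] = (b_sub - estimate_before.beta) / abs(b_sub) if b_sub != 0 else np.inf
            distortion_p = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (1 + n_sim))
        logger.info(
            "mr_presso flagged %d outlier(s): %s",
            flagged.size,
            instruments.data["snp_id"].iloc[flagged].tolist(),
        )
    return PressoResult(
        global_rss_pval=global_p,
        outlier_indices=flagged.tolist(),
        outlier_pvals=outlier_pvals,
        distortion_pval=distortion_p,
        estimate_before=estimate_before,
        estimate_after=estimate_after,
        n_sim=n_sim,
        seed=seed,
    )


def observed_presso_rss(instruments: InstrumentSet) -> float:
    """The observed leave-one-out RSS alone (useful for diagnostics/tests)."""
    bx, by, sy = instruments.beta_exp, instruments.beta_out, instruments.se_out
    _, rss = _loo_rss(bx, by, 1.0 / sy**2)
    return float(rss[0])
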