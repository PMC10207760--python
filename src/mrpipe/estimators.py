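"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a harmonized :class:`~mrpipe.harmonize.InstrumentSet`
and return :class:`MREstimate` rows. Conventions:

* IVW is a zero-intercept weighted regression of SNP-outcome effects on
  SNP-exposure effects with weights 1/se_out²; the random-effects variant
  inflates the standard error multiplicatively by max(1, sqrt(Q/(n−1)))
  and never deflates it.
* MR-Egger adds a free intercept (the directional-pleiotropy test) and
  orients instruments to positive exposure effects first. The slope SE is
  inflated by max(1, sqrt(Q/(n−2))); the intercept SE uses the free
  residual-variance estimate. Both use a t reference with n−2 df.
* Weighted median and the mode estimators work on per-SNP Wald ratios with
  first-order delta-method standard errors and obtain their SEs from a
  seeded parametric bootstrap.

Estimates are reported per 1 exposure unit and rescaled with
:func:`scale_estimate` (e.g. ×10 for "per 10 mmHg SBP increment", ×(−10)
for "per 10 mmHg SBP decrease" in the drug-class analyses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import stats as sps

from .harmonize import InstrumentSet

logger = logging.getLogger("mrpipe")

Z95 = float(sps.norm.ppf(0.975))  # 1.959964...


@dataclass
class MREstimate:
    """A method-tagged causal effect with normal-approximation 95% CI."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    scale_factor: float = 1.0

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
            "scale_factor": self.scale_factor,
        }


@dataclass
class PleiotropyResult:
    """MR-Egger intercept: estimate, SE and two-sided p (t, n−2 df).

    A nonzero intercept indicates directional horizontal pleiotropy.
    """

    intercept: float
    se: float
    pval: float
    n_snps: int


def _make_estimate(method: str, beta: float, se: float, pval: float, n: int) -> MREstimate:
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(pval),
        n_snps=int(n),
    )


def _arrays(instruments: InstrumentSet):
    return instruments.beta_exp, instruments.se_exp, instruments.beta_out, instruments.se_out


def wald_ratio(instruments: InstrumentSet) -> MREstimate:
    """Single-SNP ratio estimate beta_out/beta_exp with first-order SE
    se_out/|beta_exp|."""
    if len(instruments) != 1:
        raise ValueError(f"wald_ratio needs exactly 1 instrument, got {len(instruments)}")
    bx, _, by, sy = (a[0] for a in _arrays(instruments))
    if bx == 0:
        raise ValueError("wald_ratio undefined for beta_exp = 0")
    beta = by / bx
    se = sy / abs(bx)
    pval = 2.0 * sps.norm.sf(abs(beta / se))
    return _make_estimate("wald_ratio", beta, se, pval, 1)


def ivw(instruments: InstrumentSet, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate (zero-intercept WLS).

    Falls back to the Wald ratio with a warning at n = 1. With
    ``random_effects`` the SE is inflated by max(1, sqrt(Q/(n−1))).
    """
    n = len(instruments)
    if n == 0:
        raise ValueError("ivw requires at least one instrument")
    if n == 1:
        logger.warning("ivw: single instrument, falling back to Wald ratio")
        est = wald_ratio(instruments)
        return dc_replace(est, method="ivw")
    bx, _, by, sy = _arrays(instruments)
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se = np.sqrt(1.0 / sxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    if random_effects:
        se *= max(1.0, np.sqrt(q / (n - 1)))
    pval = 2.0 * sps.norm.sf(abs(beta / se))
    return _make_estimate("ivw" if random_effects else "ivw_fixed", beta, se, pval, n)


def _egger_fit(bx, by, sy):
    """Weighted regression with intercept, oriented to positive exposure effects.

    Returns (slope, slope_se, intercept, intercept_se, Q). The slope SE is
    multiplicatively inflated by max(1, sqrt(Q/(n−2))) (random-effects, never
    deflating); the intercept SE uses the free residual-variance estimate
    sqrt(Q/(n−2)) so the pleiotropy test is exactly t(n−2)-calibrated."""
    sgn = np.where(bx < 0, -1.0, 1.0)
    x = bx * sgn
    y = by * sgn
    w = 1.0 / sy**2
    sw, swx = np.sum(w), np.sum(w * x)
    swxx, swy, swxy = np.sum(w * x * x), np.sum(w * y), np.sum(w * x * y)
    det = sw * swxx - swx**2
    if det <= 0:
        raise ValueError("degenerate exposure effects: Egger regression is singular")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    n = x.size
    sigma = np.sqrt(q / (n - 2))
    slope_se = np.sqrt(sw / det) * max(1.0, sigma)
    intercept_se = np.sqrt(swxx / det) * sigma
    return slope, slope_se, intercept, intercept_se, q


def mr_egger(instruments: InstrumentSet) -> tuple[MREstimate, PleiotropyResult]:
    """MR-Egger regression: slope (causal estimate) and intercept (pleiotropy test)."""
    n = len(instruments)
    if n < 3:
        raise ValueError(f"mr_egger requires at least 3 instruments, got {n}")
    bx, _, by, sy = _arrays(instruments)
    slope, slope_se, icpt, icpt_se, _ = _egger_fit(bx, by, sy)
    p_slope = 2.0 * sps.t.sf(abs(slope / slope_se), df=n - 2)
    if icpt_se == 0.0:  # exact affine fit: the test degenerates
        p_icpt = 1.0 if icpt == 0.0 else 0.0
    else:
        p_icpt = 2.0 * sps.t.sf(abs(icpt / icpt_se), df=n - 2)
    est = _make_estimate("mr_egger", slope, slope_se, p_slope, n)
    return est, PleiotropyResult(float(icpt), float(icpt_se), float(p_icpt), n)


def _ratios(bx, by, sy):
    return by / bx, sy / np.abs(bx)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with midpoint-adjusted cumulative weights and linear
    interpolation at cumulative weight 0.5."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, v))


def weighted_median(instruments: InstrumentSet, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted median of per-SNP Wald ratios; consistent while valid
    instruments carry a majority of the weight. SE by seeded parametric
    bootstrap of (beta_exp, beta_out)."""
    n = len(instruments)
    if n < 3:
        raise ValueError(f"weighted_median requires at least 3 instruments, got {n}")
    bx, sx, by, sy = _arrays(instruments)
    r, sr = _ratios(bx, by, sy)
    w = 1.0 / sr**2
    beta = _weighted_median(r, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, n))
    by_b = rng.normal(by, sy, size=(n_boot, n))
    r_b = by_b / bx_b
    w_b = (bx_b / sy) ** 2
    boots = np.empty(n_boot)
    order = np.argsort(r_b, axis=1)
    r_sorted = np.take_along_axis(r_b, order, axis=1)
    w_sorted = np.take_along_axis(w_b, order, axis=1)
    w_sorted /= w_sorted.sum(axis=1, keepdims=True)
    cum = np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted
    for i in range(n_boot):
        boots[i] = np.interp(0.5, cum[i], r_sorted[i])
    se = float(np.std(boots, ddof=1))
    pval = 2.0 * sps.norm.sf(abs(beta / se))
    return _make_estimate("weighted_median", beta, se, pval, n)


def _silverman_bandwidth(r: np.ndarray, factor: float) -> float:
    """Modified Silverman rule on the ratio scale: 0.9·min(sd, 1.4826·MAD)·n^(−1/5)."""
    sd = float(np.std(r, ddof=1))
    mad = 1.4826 * float(np.median(np.abs(r - np.median(r))))
    s = min(sd, mad) if mad > 0 else sd
    h = factor * 0.9 * s / len(r) ** 0.2
    if h <= 0:  # all ratios identical: density is a point mass
        h = max(abs(np.mean(r)), 1.0) * 1e-9
    return h


def _kde_mode(r: np.ndarray, weights: np.ndarray, h: float) -> float:
    lo, hi = r.min() - 3 * h, r.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ weights
    return float(grid[np.argmax(dens)])


def mode_estimators(
    instruments: InstrumentSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[MREstimate, MREstimate]:
    """Simple (unweighted) and weighted mode of the smoothed Wald-ratio density.

    Bandwidth follows the modified Silverman rule times ``bandwidth_factor``;
    bootstrap SEs use 1.4826·MAD of the bootstrap modes (robust scale).
    """
    n = len(instruments)
    if n < 3:
        raise ValueError(f"mode_estimators require at least 3 instruments, got {n}")
    bx, sx, by, sy = _arrays(instruments)
    r, sr = _ratios(bx, by, sy)
    h = _silverman_bandwidth(r, bandwidth_factor)
    w_simple = np.full(n, 1.0 / n)
    w_ivw = (1.0 / sr**2) / np.sum(1.0 / sr**2)
    beta_simple = _kde_mode(r, w_simple, h)
    beta_weighted = _kde_mode(r, w_ivw, h)

    rng = np.random.default_rng(seed)
    boots_s = np.empty(n_boot)
    boots_w = np.empty(n_boot)
    r_b = rng.normal(r, sr, size=(n_boot, n))
    for i in range(n_boot):
        hb = _silverman_bandwidth(r_b[i], bandwidth_factor)
        boots_s[i] = _kde_mode(r_b[i], w_simple, hb)
        boots_w[i] = _kde_mode(r_b[i], w_ivw, hb)
    se_s = 1.4826 * float(np.median(np.abs(boots_s - np.median(boots_s))))
    se_w = 1.4826 * float(np.median(np.abs(boots_w - np.median(boots_w))))
    p_s = 2.0 * sps.norm.sf(abs(beta_simple / se_s)) if se_s > 0 else 0.0
    p_w = 2.0 * sps.norm.sf(abs(beta_weighted / se_w)) if se_w > 0 else 0.0
    return (
        _make_estimate("simple_mode", beta_simple, se_s, p_s, n),
        _make_estimate("weighted_mode", beta_weighted, se_w, p_w, n),
    )


def scale_estimate(est: MREstimate, factor: float) -> MREstimate:
    """Rescale an estimate to ``factor`` exposure units (e.g. +10, +5, −10 mmHg).

    Beta and CI carry the factor's sign; SE is scaled by |factor|; the
    p-value is scale-invariant.
    """
    if factor == 0:
        raise ValueError("scale factor must be nonzero")
    lo, hi = est.ci_low * factor, est.ci_high * factor
    return MREstimate(
        method=est.method,
        beta=est.beta * factor,
        se=est.se * abs(factor),
        ci_low=min(lo, hi),
        ci_high=max(lo, hi),
        pval=est.pval,
        n_snps=est.n_snps,
        scale_factor=factor,
    )


def significance_threshold(n_comparisons: int) -> float:
    """Bonferroni threshold 0.05/n, rounded to 3 decimals as conventionally
    printed (2 → 0.025, 3 → 0.017, 1 → 0.05)."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return round(0.05 / n_comparisons, 3)


def estimate_all(
    instruments: InstrumentSet,
    scale_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[MREstimate]:
    """IVW (random effects), MR-Egger, weighted median and both modes, scaled.

    With a single instrument only the Wald ratio is returned (the
    single-proxy fallback); with two, IVW only.
    """
    n = len(instruments)
    if n == 1:
        return [scale_estimate(wald_ratio(instruments), scale_factor)]
    ests = [ivw(instruments, random_effects=True)]
    if n >= 3:
        ests.append(mr_egger(instruments)[0])
        ests.append(weighted_median(instruments, n_boot=n_boot, seed=seed))
        ests.extend(mode_estimators(instruments, n_boot=n_boot, seed=seed))
    return [scale_estimate(e, scale_factor) for e in ests]
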