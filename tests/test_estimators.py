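import numpy as np
import pytest

from mrpipe.estimators import (
    MREstimate,
    estimate_all,
    ivw,
    mode_estimators,
    mr_egger,
    scale_estimate,
    significance_threshold,
    wald_ratio,
    weighted_median,
)
from mrpipe.harmonize import InstrumentSet


def _iset(bx, sx, by, sy):
    return InstrumentSet.from_arrays(bx, sx, by, sy)


class TestWaldRatio:
    def test_direct_example(self):
        est = wald_ratio(_iset([0.1], [0.01], [0.03], [0.02]))
        assert est.beta == pytest.approx(0.3, rel=1e-12)
        assert est.se == pytest.approx(0.2, rel=1e-12)
        assert est.ci_low == pytest.approx(0.3 - 1.959963984540054 * 0.2, rel=1e-9)

    def test_sign_invariance_of_magnitude(self):
        a = wald_ratio(_iset([0.1], [0.01], [0.03], [0.02]))
        b = wald_ratio(_iset([-0.1], [0.01], [-0.03], [0.02]))
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_requires_single_instrument(self):
        with pytest.raises(ValueError, match="exactly 1"):
            wald_ratio(_iset([0.1, 0.2], [0.01] * 2, [0.03, 0.05], [0.02] * 2))

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError, match="beta_exp"):
            wald_ratio(_iset([0.0], [0.01], [0.03], [0.02]))


class TestIVW:
    def test_single_instrument_falls_back_to_wald(self):
        est = ivw(_iset([0.1], [0.01], [0.03], [0.02]))
        assert est.method == "ivw"
        assert est.beta == pytest.approx(0.3, rel=1e-12)
        assert est.se == pytest.approx(0.2, rel=1e-12)

    def test_two_identical_instruments(self):
        # exact proportionality: Q = 0, no inflation, se = single-SNP se / sqrt(2)
        est = ivw(_iset([0.1, 0.1], [0.01] * 2, [0.03, 0.03], [0.02] * 2))
        assert est.beta == pytest.approx(0.3, rel=1e-12)
        assert est.se == pytest.approx(0.2 / np.sqrt(2), rel=1e-12)

    def test_closed_form_and_statsmodels_oracle(self, five_snp_instruments):
        sm = pytest.importorskip("statsmodels.api")
        iset = five_snp_instruments
        bx, by, sy = iset.beta_exp, iset.beta_out, iset.se_out
        w = 1.0 / sy**2
        beta_hand = np.sum(w * bx * by) / np.sum(w * bx * bx)
        fit = sm.WLS(by, bx[:, None], weights=w).fit()
        est_fixed = ivw(iset, random_effects=False)
        assert est_fixed.beta == pytest.approx(beta_hand, rel=1e-12)
        assert est_fixed.beta == pytest.approx(fit.params[0], rel=1e-12)
        # random-effects beta identical, se never smaller
        est_re = ivw(iset, random_effects=True)
        assert est_re.beta == pytest.approx(est_fixed.beta, rel=1e-12)
        assert est_re.se >= est_fixed.se

    def test_equals_weighted_mean_of_wald_ratios(self, five_snp_instruments):
        iset = five_snp_instruments
        bx, by, sy = iset.beta_exp, iset.beta_out, iset.se_out
        ratios = by / bx
        w = bx**2 / sy**2
        expected = np.sum(w * ratios) / np.sum(w)
        assert ivw(iset, random_effects=False).beta == pytest.approx(expected, rel=1e-12)

    def test_random_effects_never_deflates(self):
        # strongly underdispersed data: Q/(n-1) << 1 must not shrink the se
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.5 * bx
        fixed = ivw(_iset(bx, [0.01] * 4, by, [0.02] * 4), random_effects=False)
        re = ivw(_iset(bx, [0.01] * 4, by, [0.02] * 4), random_effects=True)
        assert re.se == pytest.approx(fixed.se, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ivw(_iset([], [], [], []))


class TestEgger:
    def test_noise_free_slope_and_intercept_recovered(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.3, 8)
        by = 0.1 + 0.3 * bx  # exact line, all positive bx so orientation is a no-op
        est, pleio = mr_egger(_iset(bx, [0.01] * 8, by, [0.02] * 8))
        assert est.beta == pytest.approx(0.3, rel=1e-10)
        assert pleio.intercept == pytest.approx(0.1, rel=1e-10)
        assert pleio.pval < 1e-10  # exact fit: zero residual variance

    def test_statsmodels_oracle(self, five_snp_instruments):
        sm = pytest.importorskip("statsmodels.api")
        iset = five_snp_instruments
        bx, by, sy = iset.beta_exp, iset.beta_out, iset.se_out
        n = len(iset)
        X = np.column_stack([np.ones(n), bx])  # all bx > 0: no reorientation
        fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
        est, pleio = mr_egger(iset)
        assert est.beta == pytest.approx(fit.params[1], rel=1e-12)
        assert pleio.intercept == pytest.approx(fit.params[0], rel=1e-12)

    def test_orientation_invariance(self, five_snp_instruments):
        iset = five_snp_instruments
        flipped = _iset(-iset.beta_exp, iset.se_exp, -iset.beta_out, iset.se_out)
        a, pa = mr_egger(iset)
        b, pb = mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert pa.intercept == pytest.approx(pb.intercept, rel=1e-12)

    def test_requires_three(self):
        with pytest.raises(ValueError, match="at least 3"):
            mr_egger(_iset([0.1, 0.2], [0.01] * 2, [0.03, 0.05], [0.02] * 2))


class TestWeightedMedian:
    def test_middle_ratio_selected(self):
        # equal weights, ratios 0.1 / 0.2 / 0.9 -> median ratio 0.2
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.01, 0.02, 0.09])
        est = weighted_median(_iset(bx, [0.01] * 3, by, [0.02] * 3), seed=0)
        assert est.beta == pytest.approx(0.2, rel=1e-9)

    def test_seed_determinism(self, five_snp_instruments):
        a = weighted_median(five_snp_instruments, seed=42)
        b = weighted_median(five_snp_instruments, seed=42)
        assert (a.beta, a.se, a.pval) == (b.beta, b.se, b.pval)

    def test_dominant_weight_pulls_median(self):
        # one ratio carries >50% of weight: the weighted median sits on it
        bx = np.array([0.5, 0.05, 0.05])
        by = np.array([0.10, 0.04, 0.045])
        sy = np.array([0.01, 0.05, 0.05])
        est = weighted_median(_iset(bx, [0.01] * 3, by, sy), seed=1)
        assert est.beta == pytest.approx(0.2, rel=0.05)

    def test_requires_three(self):
        with pytest.raises(ValueError):
            weighted_median(_iset([0.1], [0.01], [0.02], [0.02]))


class TestModes:
    def test_cluster_dominates(self):
        bx = np.array([0.1, 0.1, 0.1, 0.1])
        by = np.array([0.020, 0.0205, 0.0195, 0.09])  # three ratios ~0.2, one at 0.9
        s, w = mode_estimators(_iset(bx, [0.01] * 4, by, [0.02] * 4), seed=3)
        assert s.beta == pytest.approx(0.2, abs=0.02)
        assert w.beta == pytest.approx(0.2, abs=0.02)

    def test_identical_ratios_exact(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 0.3 * bx
        s, w = mode_estimators(_iset(bx, [0.01] * 3, by, [0.02] * 3), seed=4)
        assert s.beta == pytest.approx(0.3, abs=1e-6)
        assert w.beta == pytest.approx(0.3, abs=1e-6)

    def test_seed_determinism(self, five_snp_instruments):
        a = mode_estimators(five_snp_instruments, seed=7)
        b = mode_estimators(five_snp_instruments, seed=7)
        assert a[0].se == b[0].se and a[1].se == b[1].se


class TestScaleEstimate:
    BASE = MREstimate("ivw", 0.0041, 0.002, 0.0001, 0.0081, 0.046, 435)

    def test_times_ten(self):
        out = scale_estimate(self.BASE, 10.0)
        assert out.beta == pytest.approx(0.041)
        assert out.se == pytest.approx(0.02)
        assert (out.ci_low, out.ci_high) == (pytest.approx(0.001), pytest.approx(0.081))
        assert out.pval == self.BASE.pval
        assert out.scale_factor == 10.0

    def test_identity(self):
        out = scale_estimate(self.BASE, 1.0)
        assert out.beta == self.BASE.beta and out.ci_low == self.BASE.ci_low

    def test_negative_factor_reorders_ci(self):
        out = scale_estimate(self.BASE, -10.0)
        assert out.beta == pytest.approx(-0.041)
        assert out.ci_low == pytest.approx(-0.081)
        assert out.ci_high == pytest.approx(-0.001)
        assert out.ci_low < out.ci_high
        assert out.se == pytest.approx(0.02)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            scale_estimate(self.BASE, 0.0)


class TestThresholds:
    @pytest.mark.parametrize("n,expected", [(1, 0.05), (2, 0.025), (3, 0.017)])
    def test_values(self, n, expected):
        assert significance_threshold(n) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            significance_threshold(0)


class TestEstimateAll:
    def test_single_instrument_wald_only(self):
        out = estimate_all(_iset([0.1], [0.01], [0.03], [0.02]))
        assert [e.method for e in out] == ["wald_ratio"]

    def test_two_instruments_ivw_only(self):
        out = estimate_all(_iset([0.1, 0.2], [0.01] * 2, [0.03, 0.05], [0.02] * 2))
        assert [e.method for e in out] == ["ivw"]

    def test_full_panel(self, five_snp_instruments):
        out = estimate_all(five_snp_instruments, scale_factor=10.0, seed=0)
        assert [e.method for e in out] == [
            "ivw", "mr_egger", "weighted_median", "simple_mode", "weighted_mode"
        ]
        assert all(e.scale_factor == 10.0 for e in out)

    def test_joint_sign_flip_invariance(self, five_snp_instruments):
        """Flipping effect alleles of every SNP (negating both betas) leaves
        every estimator's point estimate unchanged."""
        iset = five_snp_instruments
        flipped = _iset(-iset.beta_exp, iset.se_exp, -iset.beta_out, iset.se_out)
        a = estimate_all(iset, seed=11)
        b = estimate_all(flipped, seed=11)
        for ea, eb in zip(a, b):
            assert ea.beta == pytest.approx(eb.beta, rel=1e-9), ea.method
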