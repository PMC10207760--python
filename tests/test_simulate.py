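import numpy as np
import pandas as pd
import pytest

from mrpipe.estimators import ivw
from mrpipe.harmonize import harmonize
from mrpipe.selection import variance_explained
from mrpipe.simulate import (
    CorrelatedExposureSpec,
    ScenarioConfig,
    SyntheticTruth,
    generate_confounder_table,
    generate_two_sample,
    read_scenario,
    write_scenario,
)


def _frames_equal(a, b):
    pd.testing.assert_frame_equal(a.records, b.records)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = ScenarioConfig(n_snps=50, drug_regions=(("CCB", "CACNA1C", 3),))
        a = generate_two_sample(cfg, SyntheticTruth(beta_causal=0.01, seed=11))
        b = generate_two_sample(cfg, SyntheticTruth(beta_causal=0.01, seed=11))
        _frames_equal(a.exposure, b.exposure)
        _frames_equal(a.outcome, b.outcome)
        np.testing.assert_array_equal(a.truth.gamma, b.truth.gamma)
        assert a.ld._r2 == b.ld._r2 and a.ld.positions == b.ld.positions

    def test_different_seed_differs(self):
        cfg = ScenarioConfig(n_snps=20)
        a = generate_two_sample(cfg, SyntheticTruth(seed=1))
        b = generate_two_sample(cfg, SyntheticTruth(seed=2))
        assert not np.array_equal(a.exposure.records["beta"], b.exposure.records["beta"])


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_snps": 0},
            {"palindromic_fraction": 1.5},
            {"swap_fraction": -0.1},
            {"ld_block_r2": 2.0},
            {"trait_sd": 0.0},
            {"gamma_distribution": "cauchy"},
        ],
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_two_sample(ScenarioConfig(**kwargs), SyntheticTruth(seed=0))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pleiotropy_mode": "weird"},
            {"invalid_fraction": 1.0, "pleiotropy_mode": "balanced", "pleiotropy_sd": 0.1},
            {"invalid_fraction": 0.3},  # no pleiotropy mode
            {"invalid_fraction": 0.3, "pleiotropy_mode": "balanced"},  # sd missing
            {"outlier_indices": (99,)},
        ],
    )
    def test_bad_truth_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_two_sample(ScenarioConfig(n_snps=10), SyntheticTruth(seed=0, **kwargs))


class TestGenerativeModel:
    def test_variance_explained_matches_target(self):
        cfg = ScenarioConfig(n_snps=100)
        study = generate_two_sample(cfg, SyntheticTruth(seed=4))
        eaf = study.exposure.records["eaf"].to_numpy()
        total = np.sum(variance_explained(study.truth.gamma, eaf, cfg.trait_sd))
        assert total == pytest.approx(cfg.variance_explained_target, rel=1e-10)

    def test_outliers_displaced_exactly(self):
        cfg = ScenarioConfig(n_snps=20, swap_fraction=0.0, strand_scramble_fraction=0.0)
        clean = generate_two_sample(cfg, SyntheticTruth(seed=7))
        spiked = generate_two_sample(cfg, SyntheticTruth(seed=7, outlier_indices=(3, 8)))
        diff = spiked.outcome.records["beta"] - clean.outcome.records["beta"]
        se = clean.outcome.records["se"]
        assert diff[3] == pytest.approx(10 * se[3], rel=1e-12)
        assert diff[8] == pytest.approx(10 * se[8], rel=1e-12)
        assert (diff.drop([3, 8]) == 0).all()
        assert spiked.truth.outlier_ids == ["rs4", "rs9"]

    def test_invalid_fraction_measured_by_weight(self):
        cfg = ScenarioConfig(n_snps=60)
        truth = SyntheticTruth(seed=9, pleiotropy_mode="balanced",
                               pleiotropy_sd=0.1, invalid_fraction=0.4)
        study = generate_two_sample(cfg, truth)
        idx = {s: i for i, s in enumerate(study.truth.snp_ids)}
        se_out = study.outcome.records["se"].to_numpy()
        w = (study.truth.gamma / se_out) ** 2
        w = w / w.sum()
        share = sum(w[idx[s]] for s in study.truth.invalid_ids)
        # the share approximates the target to within one instrument's weight
        assert abs(share - 0.4) <= w.max()
        assert share > 0.3
        # alpha nonzero exactly on the invalid set
        nz = {study.truth.snp_ids[i] for i in np.flatnonzero(study.truth.alpha)}
        assert nz == set(study.truth.invalid_ids)

    def test_halfnormal_gamma_all_positive(self):
        cfg = ScenarioConfig(n_snps=50, gamma_distribution="halfnormal")
        study = generate_two_sample(cfg, SyntheticTruth(seed=3))
        assert (study.truth.gamma > 0).all()

    def test_ld_blocks_and_region_coverage(self):
        cfg = ScenarioConfig(n_snps=30, ld_block_size=2,
                             drug_regions=(("CCB", "CACNA1C", 3),))
        study = generate_two_sample(cfg, SyntheticTruth(seed=5))
        recs = study.exposure.records
        (region,) = study.gene_regions
        in_region = [
            r.snp_id for r in recs.itertuples() if region.contains(r.chrom, r.pos)
        ]
        assert len(in_region) == 6  # 3 blocks x block size 2
        # full pairwise coverage inside the region
        for i, a in enumerate(in_region):
            for b in in_region[i + 1:]:
                assert study.ld.has_pair(a, b)
        # within-block pair at block r2, cross-block pair at background r2
        assert study.ld.r2(in_region[0], in_region[1]) == cfg.ld_block_r2
        assert study.ld.r2(in_region[0], in_region[2]) == cfg.cross_block_r2

    def test_free_blocks_beyond_clump_window(self):
        cfg = ScenarioConfig(n_snps=40)
        study = generate_two_sample(cfg, SyntheticTruth(seed=6))
        recs = study.exposure.records
        for chrom, grp in recs.groupby("chrom"):
            pos = np.sort(grp["pos"].to_numpy())
            if len(pos) > 1:
                assert np.all(np.diff(pos) > 10_000 * 1000)


class TestRecovery:
    def test_null_calibration(self):
        """beta_causal = 0: the mean IVW estimate over 300 replicates is
        within 3 Monte-Carlo SEs of zero."""
        cfg = ScenarioConfig(n_snps=40, palindromic_fraction=0.0,
                             swap_fraction=0.0, strand_scramble_fraction=0.0)
        est = np.empty(300)
        for r in range(300):
            study = generate_two_sample(cfg, SyntheticTruth(beta_causal=0.0, seed=10_000 + r))
            iset = harmonize(study.exposure, study.outcome)
            est[r] = ivw(iset).beta
        mc_se = est.std(ddof=1) / np.sqrt(300)
        assert abs(est.mean()) < 3 * mc_se

    def test_effect_recovered_on_reporting_scale(self):
        """beta_causal = 0.02 per mmHg (0.2 per 10 mmHg): single large study
        recovers it within 3 IVW SEs, and the scaled estimate is near 0.2."""
        cfg = ScenarioConfig(n_snps=200)
        study = generate_two_sample(cfg, SyntheticTruth(beta_causal=0.02, seed=21))
        iset = harmonize(study.exposure, study.outcome)
        est = ivw(iset)
        assert abs(est.beta - 0.02) < 3 * est.se
        assert est.beta * 10 == pytest.approx(0.2, abs=3 * est.se * 10)

    def test_directional_pleiotropy_with_halfnormal_gamma_biases_ivw(self):
        cfg = ScenarioConfig(n_snps=50, gamma_distribution="halfnormal",
                             palindromic_fraction=0.0, swap_fraction=0.0,
                             strand_scramble_fraction=0.0)
        truth = SyntheticTruth(beta_causal=0.0, seed=31, pleiotropy_mode="directional",
                               pleiotropy_sd=0.2, invalid_fraction=0.5)
        est = np.empty(60)
        for r in range(60):
            study = generate_two_sample(cfg, SyntheticTruth(
                beta_causal=0.0, seed=31_000 + r, pleiotropy_mode="directional",
                pleiotropy_sd=0.2, invalid_fraction=0.5))
            iset = harmonize(study.exposure, study.outcome)
            est[r] = ivw(iset).beta
        # positive alpha on positive gamma: systematic upward bias
        assert est.mean() > 5 * est.std(ddof=1) / np.sqrt(60)

    def test_correlated_second_exposure(self):
        cfg = ScenarioConfig(n_snps=150)
        spec = CorrelatedExposureSpec(rho=0.7, beta_causal=0.0)
        study = generate_two_sample(cfg, SyntheticTruth(beta_causal=0.01, seed=41), second=spec)
        assert study.exposure2 is not None
        # shared allele coding and positions
        pd.testing.assert_series_equal(
            study.exposure.records["effect_allele"], study.exposure2.records["effect_allele"]
        )
        r = np.corrcoef(study.truth.gamma, study.truth.gamma2)[0, 1]
        assert r == pytest.approx(0.7, abs=0.15)


class TestConfounderTable:
    def test_designated_planted_and_significant(self):
        cfg = ScenarioConfig(n_snps=40, n_confounded=3)
        table = generate_confounder_table(cfg, SyntheticTruth(seed=8))
        assert len(table.designated) == 3
        hits = table.rows[table.rows["pval"] < 5e-8]
        assert sorted(hits["snp_id"]) == sorted(table.designated)

    def test_no_confounding_all_above_threshold(self):
        cfg = ScenarioConfig(n_snps=40, n_confounded=0)
        table = generate_confounder_table(cfg, SyntheticTruth(seed=8))
        assert table.designated == []
        assert (table.rows["pval"] >= 5e-8).all()

    def test_deterministic(self):
        cfg = ScenarioConfig(n_snps=40, n_confounded=2)
        a = generate_confounder_table(cfg, SyntheticTruth(seed=12))
        b = generate_confounder_table(cfg, SyntheticTruth(seed=12))
        pd.testing.assert_frame_equal(a.rows, b.rows)


class TestScenarioIO:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = ScenarioConfig(n_snps=25, drug_regions=(("CCB", "CACNA1C", 2),),
                             eaf_range=(0.1, 0.9), gamma_distribution="halfnormal")
        truth = SyntheticTruth(beta_causal=0.05, seed=13, outlier_indices=(1, 4),
                               pleiotropy_mode="balanced", pleiotropy_sd=0.1,
                               invalid_fraction=0.2)
        p = tmp_path / "scenario.yaml"
        write_scenario(cfg, truth, p)
        cfg2, truth2 = read_scenario(p)
        assert cfg2 == cfg
        assert truth2 == truth
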