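"""Synthetic GWAS generator: determinism, sampling moments, artifacts, LD blocks."""

import numpy as np
import pytest

from mrkit.estimators import ivw
from mrkit.harmonize import harmonize
from conftest import per_snp_gwas
from mrkit.synthgwas import (
    SimConfig,
    realized_r2_xz,
    replicate_summary_stats,
    simulate_individual,
    simulate_two_sample,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"J": 0},
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.2, 0.6)},
            {"case_fraction": 1.2},
            {"pleiotropy": "weird"},
            {"frac_palindromic": 1.5},
            {"n_outliers": 99},
            {"ld_blocks": [(50, 0.5)], "J": 10},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestDeterminismAndStructure:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(J=12, seed=5, frac_palindromic=0.3, frac_allele_swapped=0.2)
        a = simulate_two_sample(cfg)
        b = simulate_two_sample(cfg)
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert np.array_equal(a[2].gamma, b[2].gamma)

    def test_different_seeds_differ(self):
        a = simulate_two_sample(SimConfig(J=12, seed=5))
        b = simulate_two_sample(SimConfig(J=12, seed=6))
        assert a[0] != b[0]

    def test_tables_share_snp_ids_and_alleles_without_artifacts(self):
        exposure, outcome, truth, _ = simulate_two_sample(SimConfig(J=15, seed=1))
        assert exposure.snp_ids == outcome.snp_ids == truth.snp_id
        for ex, ou in zip(exposure, outcome):
            assert (ex.effect_allele, ex.other_allele) == (ou.effect_allele, ou.other_allele)

    def test_binary_outcome_carries_case_counts(self):
        _, outcome, _, _ = simulate_two_sample(SimConfig(J=5, seed=2))
        assert outcome.trait_type == "binary"
        assert outcome.n_cases + outcome.n_controls == outcome.records[0].n

    def test_ld_blocks_emitted_with_block_r2(self):
        cfg = SimConfig(J=8, seed=3, ld_blocks=[(3, 0.8), (2, 0.5)])
        _, _, truth, ld = simulate_two_sample(cfg)
        assert ld.r2(truth.snp_id[0], truth.snp_id[1]) == 0.8
        assert ld.r2(truth.snp_id[0], truth.snp_id[2]) == 0.8
        assert ld.r2(truth.snp_id[3], truth.snp_id[4]) == 0.5
        assert ld.r2(truth.snp_id[0], truth.snp_id[3]) == 0.0
        # block members are close enough to clump; singletons far apart
        exposure = simulate_two_sample(cfg)[0]
        assert abs(exposure.records[0].pos - exposure.records[2].pos) < 100_000
        assert abs(exposure.records[5].pos - exposure.records[6].pos) > 10_000_000


class TestSamplingModel:
    def test_observed_effects_standardize_to_unit_noise(self):
        """sd of (beta_hat_x - gamma)/se_x over many draws is 1 within 5%."""
        cfg = SimConfig(J=50, seed=10, outcome_type="continuous")
        batch = replicate_summary_stats(cfg, n_reps=200)
        z = (batch.beta_x - batch.truth.gamma) / batch.se_x
        assert np.std(z) == pytest.approx(1.0, abs=0.05)
        zy = (batch.beta_y - cfg.theta * batch.truth.gamma) / batch.se_y
        assert np.std(zy) == pytest.approx(1.0, abs=0.05)

    def test_pvalues_match_reported_z_scores(self):
        from scipy import stats

        exposure, _, _, _ = simulate_two_sample(SimConfig(J=10, seed=4))
        for rec in exposure:
            expected = 2 * stats.norm.sf(abs(rec.beta) / rec.se)
            assert rec.pval == pytest.approx(max(expected, 1e-300), rel=1e-12)

    def test_directional_pleiotropy_confined_to_invalid_fraction(self):
        cfg = SimConfig(
            J=200, seed=6, pleiotropy="directional", mu=0.05, tau=0.001, frac_invalid=0.3
        )
        _, _, truth, _ = simulate_two_sample(cfg)
        frac = np.mean(truth.alpha != 0)
        assert 0.2 < frac < 0.4
        assert np.mean(truth.alpha[truth.alpha != 0]) == pytest.approx(0.05, abs=0.01)

    def test_outliers_recorded_in_truth(self):
        cfg = SimConfig(J=20, seed=7, n_outliers=2, outlier_scale=10)
        _, _, truth, _ = simulate_two_sample(cfg)
        assert len(truth.outlier_ids) == 2
        idx = [truth.snp_id.index(s) for s in truth.outlier_ids]
        assert np.all(np.abs(truth.alpha[idx]) >= 9.99 * truth.se_y[idx])


class TestArtifacts:
    def test_artifacts_invisible_after_harmonization(self):
        """Strand flips and allele swaps are exactly undone by harmonization."""
        base = dict(J=30, seed=8, frac_palindromic=0.0, outcome_type="continuous")
        clean = simulate_two_sample(SimConfig(**base))
        messy = simulate_two_sample(
            SimConfig(**base, frac_strand_flipped=0.3, frac_allele_swapped=0.3)
        )
        h_clean = harmonize(clean[0], clean[1])
        h_messy = harmonize(messy[0], messy[1])
        assert np.array_equal(h_clean.beta_y, h_messy.beta_y)
        assert ivw(h_clean) == ivw(h_messy)

    def test_palindromic_fraction_produces_at_cg_pairs(self):
        exposure, _, _, _ = simulate_two_sample(
            SimConfig(J=200, seed=9, frac_palindromic=0.5)
        )
        frac = np.mean(
            [{r.effect_allele, r.other_allele} in ({"A", "T"}, {"C", "G"}) for r in exposure]
        )
        assert 0.4 < frac < 0.6


class TestIndividualLevel:
    def test_doses_are_allele_counts(self):
        doses, _, _, _ = simulate_individual(SimConfig(J=6, seed=11), 500)
        assert set(np.unique(doses)) <= {0.0, 1.0, 2.0}

    def test_binary_outcome_near_case_fraction(self):
        cfg = SimConfig(J=6, seed=12, outcome_type="binary", case_fraction=0.3)
        _, _, outcome, _ = simulate_individual(cfg, 4000)
        assert np.mean(outcome) == pytest.approx(0.3, abs=0.05)

    def test_null_genetics_gives_calibrated_association(self):
        """With gamma = 0 and theta = 0, genotype-trait association is null."""
        from mrkit.grs import grs_association, grs_individual

        rejections = 0
        reps = 200
        for seed in range(reps):
            cfg = SimConfig(
                J=5, seed=seed, gamma_sd=0.0, theta=0.0, outcome_type="continuous"
            )
            doses, _, outcome, _ = simulate_individual(cfg, 300)
            weights = np.full(5, 0.1)  # any fixed weights: score is pure noise
            est = grs_association(grs_individual(doses, weights), outcome, "continuous")
            if est.pval < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09

    def test_recovery_of_theta_from_derived_summary_stats(self):
        """IVW on summary stats computed from individual data recovers theta."""
        from mrkit.harmonize import HarmonizedSet

        hits = 0
        reps = 100
        for seed in range(reps):
            cfg = SimConfig(
                J=10, seed=seed, theta=0.3, gamma_sd=0.3, outcome_type="continuous"
            )
            doses, exposure, outcome, truth = simulate_individual(cfg, 2000)
            bx, sx = per_snp_gwas(doses, exposure)
            by, sy = per_snp_gwas(doses, outcome)
            h = HarmonizedSet(
                snp_id=np.array(truth.snp_id, dtype=object),
                beta_x=bx, se_x=sx, beta_y=by, se_y=sy, eaf=truth.maf,
            )
            est = ivw(h)
            if abs(est.beta - 0.3) < 2 * est.se:
                hits += 1
        assert hits / reps >= 0.93
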