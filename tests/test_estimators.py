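"""Causal estimators: Wald ratio, IVW, MR-Egger, weighted median, OR conversion."""

import numpy as np
import pytest
from scipy import stats

from mrkit.estimators import (
    egger,
    ivw,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mrkit.exceptions import EstimationImpossibleError
from mrkit.harmonize import HarmonizedSet

from conftest import make_hset


def hset_from_arrays(bx, sx, by, sy):
    j = len(bx)
    return HarmonizedSet(
        snp_id=np.array([f"rs{i}" for i in range(j)], dtype=object),
        beta_x=np.asarray(bx, float),
        se_x=np.asarray(sx, float),
        beta_y=np.asarray(by, float),
        se_y=np.asarray(sy, float),
        eaf=np.full(j, np.nan),
    )


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)

    def test_null_outcome_gives_or_one(self):
        est = wald_ratio(0.5, 0.05, 0.0, 0.02)
        assert est.beta == 0.0
        assert est.or_ == 1.0

    def test_negating_exposure_negates_estimate(self):
        a = wald_ratio(0.5, 0.05, 0.1, 0.02)
        b = wald_ratio(-0.5, 0.05, 0.1, 0.02)
        assert b.beta == -a.beta
        assert b.se == a.se

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError, match="beta_x"):
            wald_ratio(0.0, 0.05, 0.1, 0.02)

    def test_second_order_se_larger(self):
        first = wald_ratio(0.5, 0.05, 0.1, 0.02)
        second = wald_ratio(0.5, 0.05, 0.1, 0.02, second_order=True)
        assert second.se > first.se


class TestIVW:
    def test_single_instrument_reduces_to_wald(self):
        h = hset_from_arrays([0.5], [0.05], [0.1], [0.02])
        est = ivw(h, model="fixed")
        wald = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert est.beta == wald.beta
        assert est.se == wald.se

    def test_single_instrument_random_effects_impossible(self):
        h = hset_from_arrays([0.5], [0.05], [0.1], [0.02])
        with pytest.raises(EstimationImpossibleError):
            ivw(h, model="multiplicative_random")

    def test_perfect_proportionality_recovers_theta(self, rng):
        h = make_hset(rng, 6)
        h.beta_y = 0.3 * h.beta_x
        fixed = ivw(h, model="fixed")
        mre = ivw(h, model="multiplicative_random")
        assert fixed.beta == pytest.approx(0.3, abs=1e-12)
        assert mre.se == fixed.se  # zero residuals: no inflation

    def test_matches_weighted_least_squares_oracle(self):
        bx = np.array([0.2, 0.5, 0.8])
        by = np.array([0.05, 0.12, 0.2])
        sy = np.array([0.02, 0.03, 0.04])
        h = hset_from_arrays(bx, [0.01] * 3, by, sy)
        # normal equations for through-origin WLS
        w = 1 / sy**2
        expected = np.sum(w * bx * by) / np.sum(w * bx**2)
        est = ivw(h, model="fixed")
        assert est.beta == pytest.approx(expected, abs=1e-12)
        assert est.se == pytest.approx(np.sqrt(1 / np.sum(w * bx**2)), abs=1e-12)

    def test_fixed_equals_meta_analysis_of_wald_ratios(self, rng):
        for _ in range(20):
            h = make_hset(rng, int(rng.integers(2, 12)))
            ratios = h.beta_y / h.beta_x
            ses = np.abs(h.se_y / h.beta_x)
            w = 1 / ses**2
            meta_beta = np.sum(w * ratios) / np.sum(w)
            meta_se = np.sqrt(1 / np.sum(w))
            est = ivw(h, model="fixed")
            assert est.beta == pytest.approx(meta_beta, abs=1e-10)
            assert est.se == pytest.approx(meta_se, abs=1e-10)

    def test_mre_never_narrower_than_fixed(self, rng):
        h = make_hset(rng, 10)
        assert ivw(h).se >= ivw(h, model="fixed").se

    def test_zero_instruments_impossible(self):
        h = hset_from_arrays([], [], [], [])
        with pytest.raises(EstimationImpossibleError):
            ivw(h)


class TestEgger:
    def test_exact_fit_recovers_intercept_and_slope(self, rng):
        h = make_hset(rng, 8)
        h.beta_x = np.abs(h.beta_x)
        h.beta_y = 0.03 + 0.4 * h.beta_x
        fit = egger(h)
        assert fit.intercept == pytest.approx(0.03, abs=1e-12)
        assert fit.slope.beta == pytest.approx(0.4, abs=1e-12)

    def test_zero_intercept_data(self, rng):
        h = make_hset(rng, 10)
        h.beta_x = np.abs(h.beta_x)
        h.beta_y = 0.25 * h.beta_x
        fit = egger(h)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.slope.beta == pytest.approx(ivw(h, model="fixed").beta, abs=1e-9)

    def test_orientation_invariance(self, rng):
        h = make_hset(rng, 7)
        flipped = h.subset(np.arange(h.j))
        flipped.beta_x = h.beta_x.copy()
        flipped.beta_y = h.beta_y.copy()
        flipped.beta_x[2] *= -1
        flipped.beta_y[2] *= -1
        a, b = egger(h), egger(flipped)
        assert a.slope.beta == pytest.approx(b.slope.beta, abs=1e-14)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-14)

    def test_too_few_instruments(self, rng):
        with pytest.raises(EstimationImpossibleError):
            egger(make_hset(rng, 2))

    def test_pvalues_use_t_reference(self, rng):
        h = make_hset(rng, 5)
        fit = egger(h)
        t = abs(fit.slope.beta) / fit.slope.se
        assert fit.slope.pval == pytest.approx(2 * stats.t.sf(t, h.j - 2), rel=1e-12)


class TestWeightedMedian:
    def test_constant_ratio_recovered_regardless_of_weights(self, rng):
        h = make_hset(rng, 6)
        h.beta_y = 0.15 * h.beta_x
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.15, abs=1e-12)

    def test_hand_interpolation_oracle(self):
        # equal weights, ratios {0.1, 0.2, 0.9}: midpoint 0.5 sits on the middle value
        sy = np.array([1.0, 2.0, 9.0])  # makes bx^2/sy^2 equal across SNPs
        bx = np.array([1.0, 2.0, 9.0])
        by = np.array([0.1, 0.4, 8.1])  # ratios 0.1, 0.2, 0.9
        h = hset_from_arrays(bx, [0.1] * 3, by, sy)
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_estimate_within_ratio_range(self, rng):
        for _ in range(10):
            h = make_hset(rng, int(rng.integers(3, 10)))
            ratios = h.beta_y / h.beta_x
            est = weighted_median(h, n_boot=20, seed=1)
            assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12

    def test_fixed_seed_is_bit_identical(self, rng):
        h = make_hset(rng, 8)
        a = weighted_median(h, n_boot=300, seed=7)
        b = weighted_median(h, n_boot=300, seed=7)
        assert a == b

    def test_different_seeds_agree_within_mc_error(self, rng):
        h = make_hset(rng, 8)
        ses = [weighted_median(h, n_boot=2000, seed=s).se for s in (1, 2)]
        assert ses[0] == pytest.approx(ses[1], rel=0.15)

    def test_zero_exposure_effect_excluded(self, rng):
        h = make_hset(rng, 5)
        h.beta_x[0] = 0.0
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.n_snp == 4


class TestEquivariance:
    def test_exposure_rescaling_divides_estimates(self, rng):
        """Multiplying every (beta_x, se_x) by c > 0 divides causal estimates by c."""
        h = make_hset(rng, 9)
        c = 2.5
        scaled = hset_from_arrays(c * h.beta_x, c * h.se_x, h.beta_y, h.se_y)
        scaled.snp_id = h.snp_id
        assert ivw(scaled).beta == pytest.approx(ivw(h).beta / c, rel=1e-12)
        assert egger(scaled).slope.beta == pytest.approx(egger(h).slope.beta / c, rel=1e-12)
        wm, wm_scaled = weighted_median(h, seed=3), weighted_median(scaled, seed=3)
        assert wm_scaled.beta == pytest.approx(wm.beta / c, rel=1e-12)
        assert wm_scaled.se == pytest.approx(wm.se / c, rel=1e-12)

    def test_sign_coherence(self, rng):
        """Negating the outcome effects negates every point estimate exactly
        (joint negation of both sides leaves the ratios invariant instead)."""
        h = make_hset(rng, 8)
        neg = hset_from_arrays(h.beta_x, h.se_x, -h.beta_y, h.se_y)
        both = hset_from_arrays(-h.beta_x, h.se_x, -h.beta_y, h.se_y)
        assert ivw(both).beta == ivw(h).beta
        assert ivw(neg).beta == -ivw(h).beta
        assert egger(neg).slope.beta == pytest.approx(-egger(h).slope.beta, rel=1e-12)
        assert weighted_median(neg, seed=5).beta == pytest.approx(
            -weighted_median(h, seed=5).beta, rel=1e-12
        )


class TestOddsRatioConversion:
    def test_null_beta_gives_symmetric_interval(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_degenerate_se_collapses_interval(self):
        or_, lo, hi = to_odds_ratio(np.log(2), 1e-12)
        assert or_ == pytest.approx(2.0)
        assert lo == pytest.approx(2.0, abs=1e-9)
        assert hi == pytest.approx(2.0, abs=1e-9)

    def test_arithmetic_example(self):
        or_, lo, hi = to_odds_ratio(-0.2, 0.1)
        assert lo == pytest.approx(np.exp(-0.396), abs=1e-3)
        assert hi == pytest.approx(np.exp(-0.004), abs=1e-3)

    def test_estimate_invariants(self, rng):
        h = make_hset(rng, 6)
        est = ivw(h)
        assert est.ci_low < est.or_ < est.ci_high
        assert est.or_ == pytest.approx(np.exp(est.beta), rel=1e-15)
        assert 0 < est.pval <= 1
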