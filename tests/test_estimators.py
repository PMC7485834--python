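"""MR estimators against independent oracles and closed forms."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrkit.estimators import (
    Z95,
    mr_egger,
    mr_ivw,
    mr_mode,
    mr_power,
    mr_wald,
    mr_weighted_median,
    ratio_estimates,
    steiger_test,
)
from mrkit.exceptions import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from mrkit.simulate import SimulationConfig, simulate_gwas_pair

from conftest import toy_harmonized


class TestRatioEstimates:
    def test_direct_arithmetic(self):
        h = toy_harmonized([0.1], [0.01], [0.05], [0.01])
        [r] = ratio_estimates(h)
        assert r.r_j == pytest.approx(0.5)
        assert r.se_rj == pytest.approx(0.1)
        assert r.w_j == pytest.approx(100.0)

    def test_joint_sign_flip_leaves_ratio_unchanged(self):
        h1 = toy_harmonized([0.1], [0.01], [0.05], [0.01])
        h2 = toy_harmonized([-0.1], [0.01], [-0.05], [0.01])
        assert ratio_estimates(h1)[0].r_j == ratio_estimates(h2)[0].r_j

    def test_three_snp_hand_table(self):
        h = toy_harmonized([0.2, 0.5, 0.1], [0.02, 0.05, 0.01],
                           [0.04, 0.15, -0.02], [0.01, 0.02, 0.01])
        rs = ratio_estimates(h)
        assert [r.r_j for r in rs] == pytest.approx([0.2, 0.3, -0.2])
        assert [r.se_rj for r in rs] == pytest.approx([0.05, 0.04, 0.1])
        assert [r.w_j for r in rs] == pytest.approx([400.0, 625.0, 100.0])

    def test_zero_exposure_beta_rejected(self):
        h = toy_harmonized([0.0, 0.1], [0.01] * 2, [0.0, 0.05], [0.01] * 2)
        with pytest.raises(DegenerateInstrumentError):
            ratio_estimates(h)


class TestIvw:
    def test_zero_dispersion_both_models_agree(self):
        h = toy_harmonized([0.1, 0.2, 0.4], [0.01] * 3,
                           [0.05, 0.10, 0.20], [0.01] * 3)
        fe, het_fe = mr_ivw(h, model="fixed")
        mre, het_mre = mr_ivw(h, model="multiplicative_random")
        assert fe.beta == mre.beta == pytest.approx(0.5)
        assert het_fe.Q == pytest.approx(0.0, abs=1e-18)
        assert fe.se == mre.se

    def test_two_snp_closed_form(self):
        # w = (100, 400), r = (0.2, 0.1): beta = 0.12, Q = 0.80
        h = toy_harmonized([0.1, 0.2], [0.01] * 2, [0.02, 0.02], [0.01, 0.01])
        est, het = mr_ivw(h, model="fixed")
        assert est.beta == pytest.approx(0.12, rel=1e-12)
        assert het.Q == pytest.approx(0.80, rel=1e-12)
        assert est.se == pytest.approx(500 ** -0.5, rel=1e-12)
        # IVW with k=2 equals the weighted average of the two Wald ratios
        assert est.beta == pytest.approx((100 * 0.2 + 400 * 0.1) / 500, rel=1e-14)

    def test_outcome_se_scaling_property(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.3, 6)
        by = 0.3 * bx + rng.normal(0, 0.01, 6)
        sy = rng.uniform(0.005, 0.02, 6)
        h1 = toy_harmonized(bx, np.full(6, 0.01), by, sy)
        h2 = toy_harmonized(bx, np.full(6, 0.01), by, 3.0 * sy)
        e1, _ = mr_ivw(h1, model="fixed")
        e2, _ = mr_ivw(h2, model="fixed")
        assert e2.beta == pytest.approx(e1.beta, rel=1e-12)
        assert e2.se == pytest.approx(3.0 * e1.se, rel=1e-12)

    def test_mre_floor_never_shrinks_se(self):
        h = toy_harmonized([0.1, 0.2, 0.4], [0.01] * 3,
                           [0.050001, 0.1, 0.2], [0.01] * 3)
        fe, _ = mr_ivw(h, model="fixed")
        mre, _ = mr_ivw(h, model="multiplicative_random")
        assert mre.se >= fe.se

    def test_ci_and_or_construction(self):
        h = toy_harmonized([0.1, 0.2], [0.01] * 2, [0.02, 0.02], [0.01] * 2)
        est, _ = mr_ivw(h)
        assert est.or_ == pytest.approx(math.exp(est.beta))
        assert est.ci_low == pytest.approx(math.exp(est.beta - Z95 * est.se))
        assert est.ci_high == pytest.approx(math.exp(est.beta + Z95 * est.se))

    def test_single_instrument_requires_wald(self):
        h = toy_harmonized([0.1], [0.01], [0.05], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            mr_ivw(h)
        est = mr_wald(h)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.03 + 0.5 * bx
        h = toy_harmonized(bx, np.full(4, 0.01), by, np.full(4, 0.01))
        res = mr_egger(h)
        assert res.intercept == pytest.approx(0.03, rel=1e-10)
        assert res.slope.beta == pytest.approx(0.5, rel=1e-10)

    def test_matches_statsmodels_wls_oracle(self):
        bx = np.array([0.12, 0.25, 0.31, 0.44])
        by = np.array([0.05, 0.16, 0.13, 0.25])
        sy = np.array([0.01, 0.02, 0.015, 0.03])
        h = toy_harmonized(bx, np.full(4, 0.01), by, sy)
        res = mr_egger(h)

        w = 1.0 / sy**2
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=w).fit()
        assert res.intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert res.slope.beta == pytest.approx(fit.params[1], rel=1e-10)
        # statsmodels scales the covariance by Q/(k-2); mrkit floors the
        # dispersion at 1, so rescale for comparison
        q = float(np.sum(w * fit.resid**2))
        disp = max(1.0, math.sqrt(q / 2))
        sm_base_se = fit.bse / math.sqrt(q / 2)
        assert res.slope.se == pytest.approx(sm_base_se[1] * disp, rel=1e-10)
        assert res.intercept_se == pytest.approx(sm_base_se[0] * disp, rel=1e-10)

    def test_origin_constrained_reproduces_ivw(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.05, 0.4, 7)
        by = 0.3 * bx + rng.normal(0, 0.02, 7)
        sy = rng.uniform(0.005, 0.03, 7)
        h = toy_harmonized(bx, np.full(7, 0.01), by, sy)
        ivw, _ = mr_ivw(h, model="fixed")
        w = 1.0 / sy**2
        slope_origin = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert slope_origin == pytest.approx(ivw.beta, rel=1e-12)

    def test_orientation_convention(self):
        """Flipping the sign of one instrument's (b_X, b_Y) jointly cannot
        change the Egger fit (internal b_X > 0 orientation)."""
        bx = np.array([0.1, -0.2, 0.3, 0.4])
        by = np.array([0.06, -0.12, 0.18, 0.25])
        h1 = toy_harmonized(bx, np.full(4, 0.01), by, np.full(4, 0.01))
        h2 = toy_harmonized(np.abs(bx), np.full(4, 0.01),
                            by * np.sign(bx), np.full(4, 0.01))
        r1, r2 = mr_egger(h1), mr_egger(h2)
        assert r1.slope.beta == pytest.approx(r2.slope.beta, rel=1e-14)
        assert r1.intercept == pytest.approx(r2.intercept, rel=1e-14)

    def test_directional_pleiotropy_detected(self):
        """With a mean direct effect on the outcome, the Egger intercept
        test should reject in most seeds at large k and n."""
        from mrkit.simulate import PleiotropyConfig

        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                m_snps=1000, exposure_names=("x",), theta=(0.1,),
                prop_causal=0.15, h2_x=0.08, effect_corr=((1.0,),),
                pleiotropy=PleiotropyConfig(prop_invalid=0.5,
                                            mean_direct_effect=0.02,
                                            sd_direct_effect=0.005),
                seed=seed,
            )
            study = simulate_gwas_pair(cfg)
            mask = study.exposures[0].records["pval"].to_numpy() < 5e-8
            h = study.harmonized(mask=mask)
            if h.k < 10:
                continue
            if mr_egger(h).intercept_pval < 0.05:
                hits += 1
        assert hits > 10


class TestWeightedMedian:
    def test_equal_weights_is_middle_ratio(self):
        h = toy_harmonized([0.1, 0.1, 0.1], [0.01] * 3,
                           [0.01, 0.05, 0.09], [0.01] * 3)
        est = mr_weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_hand_interpolation_oracle(self):
        # ratios (0.1, 0.2, 0.3) with weights (1, 1, 8):
        # p = (0.1, 0.1, 0.8), s = cum(p) - p/2 = (0.05, 0.15, 0.60)
        # interpolate 0.5 between s2 and s3: 0.2 + 0.1*(0.35/0.45) = 5/18
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.3])
        # se_r = se_y/|b_x|; weights 1/se_r^2 = (1, 1, 8)
        sy = np.array([1.0, 1.0, 1.0 / math.sqrt(8)])
        h = toy_harmonized(bx, np.full(3, 0.01), by, sy)
        est = mr_weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(5 / 18, rel=1e-12)

    def test_equal_weights_equals_plain_median_odd_k(self):
        rng = np.random.default_rng(4)
        by = rng.normal(0.3, 0.2, 7)
        h = toy_harmonized(np.ones(7), np.full(7, 0.01), by, np.ones(7))
        est = mr_weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(np.median(by), rel=1e-12)

    def test_bootstrap_se_reproducible(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.1, 0.4, 8)
        by = 0.2 * bx + rng.normal(0, 0.02, 8)
        h = toy_harmonized(bx, np.full(8, 0.01), by, np.full(8, 0.02))
        a = mr_weighted_median(h, n_boot=200, seed=42)
        b = mr_weighted_median(h, n_boot=200, seed=42)
        assert a.se == b.se

    def test_robust_to_minority_invalid_instruments(self):
        """With 40% of instruments carrying large directional pleiotropy,
        the weighted median stays closer to the truth than IVW."""
        from mrkit.simulate import PleiotropyConfig

        closer = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                m_snps=600, exposure_names=("x",), theta=(0.2,),
                prop_causal=0.15, h2_x=0.08, effect_corr=((1.0,),),
                pleiotropy=PleiotropyConfig(prop_invalid=0.4,
                                            mean_direct_effect=0.05,
                                            sd_direct_effect=0.01),
                seed=seed,
            )
            study = simulate_gwas_pair(cfg)
            mask = study.exposures[0].records["pval"].to_numpy() < 5e-8
            h = study.harmonized(mask=mask)
            if h.k < 10:
                continue
            ivw, _ = mr_ivw(h)
            wm = mr_weighted_median(h, n_boot=50, seed=seed)
            if abs(wm.beta - 0.2) < abs(ivw.beta - 0.2):
                closer += 1
        assert closer >= 0.8 * n_seeds


class TestMode:
    def test_degenerate_identical_ratios(self):
        h = toy_harmonized([0.1, 0.2, 0.4], [0.01] * 3,
                           [0.05, 0.10, 0.20], [0.01] * 3)
        est = mr_mode(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_symmetric_cluster_mode_is_center(self):
        # ratios symmetric about 0.5 with equal weights: the kernel density
        # is symmetric, so its argmax is exactly 0.5
        by = np.array([0.40, 0.45, 0.50, 0.55, 0.60])
        h = toy_harmonized(np.ones(5), np.full(5, 0.01), by, np.ones(5))
        est = mr_mode(h, weighted=False, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-10)

    def test_bimodal_set_tracks_majority_cluster(self):
        by = np.array([0.2] * 7 + [1.0] * 3) + np.linspace(-0.01, 0.01, 10)
        h = toy_harmonized(np.ones(10), np.full(10, 0.01), by, np.ones(10))
        est = mr_mode(h, weighted=False, n_boot=50, seed=1)
        assert abs(est.beta - 0.2) < 0.05

        # independent dense grid-search oracle on the same kernel density
        ratios = by
        sd = np.std(ratios, ddof=1)
        iqr = np.subtract(*np.percentile(ratios, [75, 25]))
        bw = 0.9 * min(sd, iqr / 1.349) * 10 ** (-0.2)
        grid = np.linspace(ratios.min(), ratios.max(), 200_001)
        dens = np.zeros_like(grid)
        for r in ratios:
            dens += np.exp(-0.5 * ((grid - r) / bw) ** 2)
        oracle = grid[np.argmax(dens)]
        assert est.beta == pytest.approx(oracle, abs=1e-4)

    def test_weighting_moves_mode_toward_heavy_cluster(self):
        by = np.array([0.2] * 3 + [1.0] * 4)
        # minority (0.2) cluster gets tiny outcome SEs -> huge weights
        sy = np.array([0.01] * 3 + [1.0] * 4)
        h = toy_harmonized(np.ones(7), np.full(7, 0.01), by, sy)
        unweighted = mr_mode(h, weighted=False, n_boot=20, seed=1)
        weighted = mr_mode(h, weighted=True, n_boot=20, seed=1)
        assert abs(weighted.beta - 0.2) < abs(unweighted.beta - 0.2)


class TestSteiger:
    def test_direction_from_r2_ordering(self):
        h = toy_harmonized([0.14], [0.01], [0.01], [0.01])
        res = steiger_test(h, 10_000, 5_000, 5_000)
        assert res.r2_exposure > res.r2_outcome
        assert res.direction_correct

    def test_symmetric_null_pvalue_near_one(self):
        h = toy_harmonized([0.1], [0.01], [0.1], [0.01])
        # effective outcome n = 4/(1/20k + 1/20k) = 40k matches n_exposure
        res = steiger_test(h, 40_000, 20_000, 20_000)
        # equal t-statistics and equal effective n -> no evidence either way
        assert res.pval == pytest.approx(1.0, abs=1e-9)

    def test_simulated_forward_model_confirms_direction(self):
        correct = 0
        for seed in range(20):
            cfg = SimulationConfig(
                m_snps=300, exposure_names=("x",), theta=(0.1,),
                prop_causal=0.1, h2_x=0.05, effect_corr=((1.0,),),
                n_exposure=100_000, n_case=60_000, n_control=50_000, seed=seed,
            )
            study = simulate_gwas_pair(cfg)
            mask = study.exposures[0].records["pval"].to_numpy() < 5e-8
            h = study.harmonized(mask=mask)
            res = steiger_test(h, 100_000, 60_000, 50_000)
            correct += res.direction_correct
        assert correct == 20


class TestPower:
    def test_null_or_gives_alpha(self):
        assert mr_power(60_000, 50_000, 0.02, 1.0, alpha=0.01) == pytest.approx(0.01)
        assert mr_power(60_000, 50_000, 0.02, 1.0, alpha=0.05) == pytest.approx(0.05)

    def test_monotone_in_r2_and_effect(self):
        p = [mr_power(60_000, 50_000, r2, 1.05) for r2 in (0.01, 0.02, 0.05)]
        assert p[0] < p[1] < p[2]
        q = [mr_power(60_000, 50_000, 0.02, o) for o in (1.02, 1.05, 1.10)]
        assert q[0] < q[1] < q[2]
        # symmetric in direction of effect
        assert mr_power(60_000, 50_000, 0.02, 1.05) == pytest.approx(
            mr_power(60_000, 50_000, 0.02, 1 / 1.05), rel=1e-12
        )
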