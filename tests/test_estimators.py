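"""Causal-effect estimators: IVW, MR-Egger, weighted median/mode."""

import numpy as np
import pytest
import statsmodels.api as sm
from sklearn.base import clone

from mrkit.estimators import (
    EggerEstimator,
    IVWEstimator,
    WeightedMedianEstimator,
    WeightedModeEstimator,
    egger,
    ivw,
    wald_ratios,
    weighted_median,
    weighted_median_point,
    weighted_mode,
)
from mrkit.summary_io import HarmonizedSet


def hset(gamma, se_gamma, Gamma, se_Gamma):
    return HarmonizedSet.from_arrays(gamma, se_gamma, Gamma, se_Gamma)


def random_hset(rng, j=10, beta=0.05):
    gamma = rng.uniform(0.2, 1.5, j) * rng.choice([-1, 1], j)
    se_gamma = np.full(j, 0.05)
    se_Gamma = rng.uniform(0.005, 0.05, j)
    Gamma = beta * gamma + rng.normal(0, se_Gamma)
    return hset(gamma, se_gamma, Gamma, se_Gamma)


class TestWaldRatios:
    def test_arithmetic_and_sign(self):
        h = hset([0.5, -0.5], [0.05, 0.05], [0.025, 0.025], [0.01, 0.01])
        out = wald_ratios(h)
        assert out["ratio"].tolist() == pytest.approx([0.05, -0.05])
        assert out["ratio_se"].tolist() == pytest.approx([0.02, 0.02])

    def test_zero_gamma_names_snp(self):
        h = HarmonizedSet.from_arrays([0.5, 0.0], [0.05] * 2, [0.01] * 2, [0.01] * 2,
                                      snp_ids=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            wald_ratios(h)

    def test_null_simulation_mean_ratio_near_zero(self):
        rng = np.random.default_rng(11)
        j = 1000
        gamma = rng.uniform(0.3, 1.0, j)
        se_Gamma = np.full(j, 0.01)
        Gamma = rng.normal(0, se_Gamma)
        out = wald_ratios(hset(gamma, np.full(j, 0.01), Gamma, se_Gamma))
        mean = out["ratio"].mean()
        se_mean = out["ratio"].std(ddof=1) / np.sqrt(j)
        assert abs(mean) < 3 * se_mean


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        h = hset([0.5], [0.05], [0.025], [0.01])
        est = ivw(h, mode="fixed")
        assert est.beta == pytest.approx(0.05)
        assert est.se == pytest.approx(0.02)

    def test_equal_weights_symmetry(self):
        h = hset([1.0, 1.0], [0.05, 0.05], [0.04, 0.06], [0.01, 0.01])
        assert ivw(h).beta == pytest.approx(0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wls_through_origin_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = random_hset(rng)
        est = ivw(h, mode="fixed")
        fit = sm.WLS(h.Gamma, h.gamma, weights=1.0 / h.se_Gamma**2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
        # de-scale the statsmodels SE by the residual standard deviation
        assert est.se == pytest.approx(fit.bse[0] / np.sqrt(fit.scale), abs=1e-10)

    def test_mre_se_never_below_fe(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            h = random_hset(rng)
            assert ivw(h, mode="mre").se >= ivw(h, mode="fixed").se

    def test_mre_equals_fe_when_underdispersed(self):
        # identical ratios: Q = 0 <= J-1, so no inflation
        h = hset([1.0, 2.0, 4.0], [0.05] * 3, [0.05, 0.10, 0.20], [0.01] * 3)
        assert ivw(h, mode="mre").se == ivw(h, mode="fixed").se

    def test_mre_requires_two_snps(self):
        with pytest.raises(ValueError):
            ivw(hset([0.5], [0.05], [0.02], [0.01]), mode="mre")

    def test_reordering_invariance(self):
        rng = np.random.default_rng(4)
        h = random_hset(rng)
        perm = rng.permutation(h.n_snps)
        h_perm = h.subset(perm)
        assert ivw(h).beta == pytest.approx(ivw(h_perm).beta, rel=1e-12)
        assert egger(h).beta == pytest.approx(egger(h_perm).beta, rel=1e-12)


class TestEgger:
    def test_exact_line_recovered(self):
        gamma = np.array([0.2, 0.5, 0.9, 1.4])
        Gamma = 0.01 + 0.05 * gamma
        est = egger(hset(gamma, [0.05] * 4, Gamma, [0.01] * 4))
        assert est.intercept == pytest.approx(0.01, abs=1e-12)
        assert est.beta == pytest.approx(0.05, abs=1e-12)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(2)
        h = random_hset(rng, j=8)
        flipped = h.pairs.copy()
        flipped.loc[3, ["gamma", "Gamma"]] *= -1
        est1 = egger(h)
        est2 = egger(HarmonizedSet(flipped))
        assert est1.beta == pytest.approx(est2.beta, rel=1e-12)
        assert est1.intercept == pytest.approx(est2.intercept, rel=1e-12)

    def test_matches_statsmodels_wls_oracle(self):
        rng = np.random.default_rng(8)
        h = random_hset(rng, j=12)
        flip = np.sign(h.gamma)
        X = sm.add_constant(h.gamma * flip)
        fit = sm.WLS(h.Gamma * flip, X, weights=1.0 / h.se_Gamma**2).fit()
        est = egger(h)
        assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        scale_factor = max(1.0, np.sqrt(fit.scale))
        assert est.se == pytest.approx(fit.bse[1] / np.sqrt(fit.scale) * scale_factor, abs=1e-10)
        assert est.pval == pytest.approx(
            float(2 * __import__("scipy.stats", fromlist=["t"]).t.sf(
                abs(est.beta) / est.se, h.n_snps - 2)), rel=1e-9)

    def test_requires_three_snps(self):
        with pytest.raises(ValueError):
            egger(hset([0.5, 1.0], [0.05] * 2, [0.02, 0.05], [0.01] * 2))

    def test_directional_pleiotropy_recovered_ivw_biased(self):
        # InSIDE holds: pleiotropy independent of instrument strength
        rng = np.random.default_rng(42)
        j, beta_true = 200, 0.05
        gamma = rng.uniform(0.2, 1.5, j)
        alpha = rng.normal(0.02, 0.005, j)
        se_Gamma = np.full(j, 0.01)
        Gamma = beta_true * gamma + alpha + rng.normal(0, se_Gamma)
        h = hset(gamma, np.full(j, 0.01), Gamma, se_Gamma)
        e = egger(h)
        assert abs(e.beta - beta_true) < 3 * e.se
        assert ivw(h).beta > beta_true + 3 * ivw(h).se  # upward bias


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        assert weighted_median_point([0.1, 0.2, 0.3], [1, 1, 1]) == pytest.approx(0.2)

    def test_midpoint_interpolation_two_points(self):
        assert weighted_median_point([0.1, 0.3], [1, 1]) == pytest.approx(0.2)

    def test_matches_brute_force_oracle(self):
        def brute(ratios, weights):
            ratios = np.asarray(ratios, float)
            weights = np.asarray(weights, float)
            order = np.argsort(ratios)
            r, w = ratios[order], weights[order] / weights.sum()
            p = np.cumsum(w) - w / 2
            return float(np.interp(0.5, p, r))

        rng = np.random.default_rng(5)
        for _ in range(20):
            ratios = rng.normal(0.05, 0.1, 10)
            weights = rng.uniform(0.1, 10, 10)
            assert weighted_median_point(ratios, weights) == pytest.approx(
                brute(ratios, weights), abs=1e-14
            )

    def test_estimator_point_and_bootstrap(self):
        rng = np.random.default_rng(1)
        h = random_hset(rng, j=20)
        est = weighted_median(h, n_boot=200, seed=3)
        assert est.se > 0
        assert abs(est.beta - 0.05) < 5 * est.se

    def test_breakdown_under_half_invalid(self):
        # 40% of weight invalid (two pleiotropic clusters, one each side):
        # under half the weight is invalid, so the median stays consistent
        rng = np.random.default_rng(6)
        j = 100
        gamma = rng.uniform(0.3, 1.2, j)
        se_Gamma = np.full(j, 0.01)
        alpha = np.zeros(j)
        alpha[:20] = 0.05
        alpha[20:40] = -0.05
        Gamma = 0.05 * gamma + alpha + rng.normal(0, se_Gamma)
        est = weighted_median(hset(gamma, np.full(j, 0.01), Gamma, se_Gamma),
                              n_boot=200, seed=0)
        assert abs(est.beta - 0.05) < 3 * est.se


class TestWeightedMode:
    def test_degenerate_identical_ratios(self):
        h = hset([1.0, 2.0, 0.5], [0.05] * 3, [0.07, 0.14, 0.035], [0.01] * 3)
        est = weighted_mode(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.07)

    def test_majority_cluster_wins(self):
        gamma = np.ones(10)
        Gamma = np.array([0.05] * 7 + [0.30] * 3)
        rng = np.random.default_rng(0)
        Gamma = Gamma + rng.normal(0, 1e-4, 10)
        h = hset(gamma, np.full(10, 0.01), Gamma, np.full(10, 0.01))
        est = weighted_mode(h, n_boot=50, seed=0)
        # within one grid step of the dominant cluster
        spread = Gamma.max() - Gamma.min()
        assert abs(est.beta - 0.05) < spread / 50

    def test_robust_to_minority_shared_pleiotropy(self):
        # 30% invalid with one shared pleiotropic value: mode beats IVW
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            j = 30
            gamma = rng.uniform(0.3, 1.2, j)
            alpha = np.zeros(j)
            alpha[rng.choice(j, 9, replace=False)] = 0.08
            se_Gamma = np.full(j, 0.005)
            Gamma = 0.05 * gamma + alpha + rng.normal(0, se_Gamma)
            h = hset(gamma, np.full(j, 0.01), Gamma, se_Gamma)
            mode_err = abs(weighted_mode(h, n_boot=1, seed=0).beta - 0.05)
            ivw_err = abs(ivw(h).beta - 0.05)
            wins += mode_err < ivw_err
        assert wins >= 32  # >= 80% of seeds


class TestOddsRatio:
    def test_null_effect_gives_unit_or(self):
        est = ivw(hset([1.0], [0.05], [0.0], [0.01]))
        assert est.or_ == pytest.approx(1.0)

    def test_published_style_conversion(self):
        h = hset([1.0], [0.05], [0.0497], [0.0119])
        est = ivw(h)
        assert est.or_ == pytest.approx(1.051, abs=5e-4)
        assert est.or_ci_low == pytest.approx(1.027, abs=5e-4)
        assert est.or_ci_high == pytest.approx(1.076, abs=5e-4)

    def test_ci_symmetric_on_log_scale(self):
        rng = np.random.default_rng(3)
        est = ivw(random_hset(rng))
        assert np.log(est.or_ci_high / est.or_) == pytest.approx(
            np.log(est.or_ / est.or_ci_low), rel=1e-9
        )


class TestSklearnProtocol:
    @pytest.mark.parametrize(
        "est",
        [IVWEstimator(mode="mre"), EggerEstimator(),
         WeightedMedianEstimator(n_boot=10, random_state=0),
         WeightedModeEstimator(n_boot=10, random_state=0)],
    )
    def test_get_params_clone_fit(self, est):
        rng = np.random.default_rng(0)
        h = random_hset(rng)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        fitted = cloned.fit(h)
        assert fitted.ci_low_ <= fitted.beta_ <= fitted.ci_high_
        assert 0 < fitted.pval_ <= 1
        assert fitted.n_snps_ == h.n_snps

    def test_array_input_accepted(self):
        X = np.column_stack([[1.0, 2.0, 0.5], [0.05] * 3, [0.05, 0.1, 0.025], [0.01] * 3])
        est = IVWEstimator().fit(X)
        assert est.beta_ == pytest.approx(0.05)

    def test_predict_reproduces_line(self):
        gamma = np.array([0.2, 0.5, 0.9, 1.4])
        Gamma = 0.01 + 0.05 * gamma
        fit = EggerEstimator().fit(hset(gamma, [0.05] * 4, Gamma, [0.01] * 4))
        assert fit.predict(gamma) == pytest.approx(Gamma, abs=1e-12)
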