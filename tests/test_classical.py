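"""Levene family, Bartlett, CLS and dglm against direct-formula and
library oracles, plus the shared dispatcher contract."""

import math

import numpy as np
import pytest
from scipy import stats

from vqtlkit.classical import (TestResult, bartlett_test, cls_test, dglm_test,
                               levene_family_test, round_dosage, run_test)
from vqtlkit.exceptions import InvalidArgumentError, NumericalError
from vqtlkit.simulate import SimulationConfig, simulate_dataset


def _random_grouped(seed, n=60, k=3):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, k, n).astype(float)
    y = rng.normal(0, 1 + 0.3 * x, n)
    return y, x


class TestLeveneFamily:
    def test_symmetric_equal_deviations_give_zero(self):
        res = levene_family_test(np.array([0.0, 2, 0, 2]),
                                 np.array([0.0, 0, 1, 1]), center="mean")
        assert res.statistic == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("center,scipy_center", [("mean", "mean"),
                                                     ("median", "median")])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_oracle(self, center, scipy_center, seed):
        y, x = _random_grouped(seed)
        res = levene_family_test(y, x, center=center)
        groups = [y[x == v] for v in np.unique(x)]
        w_ref, p_ref = stats.levene(*groups, center=scipy_center)
        assert abs(res.statistic - w_ref) < 1e-12
        assert abs(res.p_value - p_ref) < 1e-12

    def test_location_scale_invariance(self):
        y, x = _random_grouped(5)
        a = levene_family_test(y, x, center="mean")
        b = levene_family_test(5 * y + 7, x, center="mean")
        assert abs(a.statistic - b.statistic) < 1e-10
        assert abs(a.p_value - b.p_value) < 1e-10

    def test_rejects_continuous_covariate(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidArgumentError):
            levene_family_test(rng.normal(size=30), rng.uniform(0, 2, 30))

    def test_rejects_single_group(self):
        with pytest.raises(InvalidArgumentError):
            levene_family_test(np.arange(6.0), np.zeros(6))


class TestBartlett:
    def test_equal_variances_give_zero(self):
        y = np.array([1.0, 2, 3, 1, 2, 3])
        x = np.array([0.0, 0, 0, 1, 1, 1])
        res = bartlett_test(y, x)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        y, x = _random_grouped(7)
        res = bartlett_test(y, x)
        groups = [y[x == v] for v in np.unique(x)]
        k = len(groups)
        n = sum(g.size for g in groups)
        sp2 = sum((g.size - 1) * g.var(ddof=1) for g in groups) / (n - k)
        num = (n - k) * math.log(sp2) - sum(
            (g.size - 1) * math.log(g.var(ddof=1)) for g in groups)
        den = 1 + (sum(1 / (g.size - 1) for g in groups) - 1 / (n - k)) \
            / (3 * (k - 1))
        assert abs(res.statistic - num / den) < 1e-10

    def test_rejects_singleton_group(self):
        y = np.array([1.0, 2, 3, 4, 5])
        x = np.array([0.0, 0, 0, 0, 1])
        with pytest.raises(InvalidArgumentError):
            bartlett_test(y, x)

    def test_zero_variance_group_is_numerical_failure(self):
        y = np.array([1.0, 1, 1, 4, 5, 6])
        x = np.array([0.0, 0, 0, 1, 1, 1])
        with pytest.raises(NumericalError):
            bartlett_test(y, x)


class TestCls:
    def test_fully_tied_squared_residuals(self):
        res = cls_test(np.array([-1.0, 1, -1, 1]), np.array([0.0, 0, 1, 1]))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_perfect_linear_fit(self):
        x = np.array([0.0, 1, 2, 0, 1, 2])
        res = cls_test(2 * x + 3, x)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_rank_correlation_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 12)
        y = 1 + 0.5 * x + rng.normal(0, 1 + 0.5 * np.abs(x), 12)
        res = cls_test(y, x)
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r2 = (y - X @ coef) ** 2
        ra = stats.rankdata(r2)
        rb = stats.rankdata(x)
        rho = np.corrcoef(ra, rb)[0, 1]
        assert abs(res.statistic - rho) < 1e-12

    def test_exact_permutation_p_for_tiny_n(self):
        rng = np.random.default_rng(4)
        x = np.array([0.0, 1, 2, 0, 1, 2, 0, 1])
        y = rng.normal(0, 1 + x, 8)
        res = cls_test(y, x)
        assert 0.0 <= res.p_value <= 1.0

    def test_constant_covariate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cls_test(np.arange(6.0), np.ones(6))


class TestDglm:
    def test_large_variance_effect_detected(self):
        rng = np.random.default_rng(0)
        n = 2000
        x = np.repeat([0.0, 1.0], n // 2)
        y = rng.normal(0, np.where(x == 0, 1.0, 4.0))
        res = dglm_test(y, x)
        assert res.converged and res.p_value < 1e-6

    def test_constant_covariate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            dglm_test(np.random.default_rng(1).normal(size=20), np.ones(20))

    def test_dispersion_fit_matches_statsmodels(self):
        import statsmodels.api as sm

        from vqtlkit.classical import _gamma_irls_log_link

        rng = np.random.default_rng(8)
        x = rng.integers(0, 3, 200).astype(float)
        X = np.column_stack([np.ones_like(x), x])
        d = rng.gamma(0.5, 2 * np.exp(0.1 + 0.3 * x))
        lam = _gamma_irls_log_link(d, X, np.array([0.0, 0.0]))
        ref = sm.GLM(d, X,
                     family=sm.families.Gamma(sm.families.links.Log()),
                     var_weights=np.full(200, 0.5)).fit().params
        np.testing.assert_allclose(lam, ref, atol=1e-6)

    def test_convergence_rate_on_common_maf(self):
        ok = 0
        for k in range(100):
            cfg = SimulationConfig(n=300, pi_maf=0.2, beta0=1.0, beta=0.5,
                                   log_alpha=0.1, seed=500 + k)
            ds = simulate_dataset(cfg)
            ok += dglm_test(ds.y, ds.x).converged
        assert ok >= 95


class TestDispatcher:
    def test_levene_refuses_continuous(self):
        rng = np.random.default_rng(2)
        with pytest.raises(InvalidArgumentError):
            run_test("levene", rng.normal(size=30), rng.uniform(0, 2, 30))

    def test_cls_dispatch_identity(self, ideal_dataset):
        a = run_test("cls", ideal_dataset.y, ideal_dataset.x)
        b = cls_test(ideal_dataset.y, ideal_dataset.x)
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_brown_forsythe_is_median_centered_levene(self):
        y, x = _random_grouped(9)
        a = run_test("brown_forsythe", y, x)
        b = levene_family_test(y, x, center="median")
        assert a.statistic == b.statistic

    def test_round_dosage_maps_to_genotypes(self):
        x = np.array([0.1, 0.9, 1.4, 1.6, 2.0])
        np.testing.assert_array_equal(round_dosage(x), [0, 1, 1, 2, 2])

    def test_bth_dispatch_reports_bayes_factor(self, ideal_dataset):
        res = run_test("bth", ideal_dataset.y, ideal_dataset.x)
        assert res.log10_bf is not None and res.p_value is None
        assert res.score == res.log10_bf

    def test_unknown_method(self):
        with pytest.raises(InvalidArgumentError):
            run_test("anova", np.arange(6.0), np.arange(6.0))
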