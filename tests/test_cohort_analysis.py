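"""Summary statistics, OLS/HC3 machinery, incremental R², subgroup contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

from co2gap import cohort_analysis as ca
from co2gap.errors import SampleSizeError, SingularDesignError


def hc3_bruteforce(X, y):
    """Independent loop-based sandwich estimator (normal equations + explicit sums)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    xtx = np.zeros((k, k))
    xty = np.zeros(k)
    for i in range(n):
        for a in range(k):
            xty[a] += X[i, a] * y[i]
            for b in range(k):
                xtx[a, b] += X[i, a] * X[i, b]
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ xty
    e = np.array([y[i] - X[i] @ beta for i in range(n)])
    h = np.array([X[i] @ xtx_inv @ X[i] for i in range(n)])
    meat = np.zeros((k, k))
    for i in range(n):
        w = e[i] ** 2 / (1.0 - h[i]) ** 2
        for a in range(k):
            for b in range(k):
                meat[a, b] += w * X[i, a] * X[i, b]
    return beta, xtx_inv @ meat @ xtx_inv


class TestSummarize:
    def test_exceedance_proportion(self):
        values = [7.0] * 36 + [5.0] * 14
        s = ca.summarize(values, threshold=6.0)
        assert s.pct_above == pytest.approx(72.0)
        assert s.n_above == 36

    def test_median_and_iqr_convention(self):
        s = ca.summarize([1, 2, 3, 4, 5])
        assert (s.median, s.q25, s.q75) == (3.0, 2.0, 4.0)

    def test_single_value(self):
        s = ca.summarize([4.2])
        assert s.median == s.q25 == s.q75 == 4.2

    def test_missing_excluded_from_denominator(self):
        s = ca.summarize([7.0, math.nan, 5.0], threshold=6.0)
        assert s.n == 2
        assert s.pct_above == pytest.approx(50.0)

    def test_empty_input(self):
        s = ca.summarize([])
        assert s.empty
        assert math.isnan(s.median)


class TestOLS:
    def test_identity_outcome(self):
        x = np.arange(10.0)
        fit = ca.ols_fit(np.column_stack([np.ones(10), x]), x)
        assert fit.params[1] == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_outcome(self):
        x = np.arange(10.0)
        fit = ca.ols_fit(np.column_stack([np.ones(10), x]), np.full(10, 3.0))
        assert fit.params[1] == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_six_point_fixture_matches_normal_equations(self):
        X = np.array(
            [[1, 0.5, 2], [1, 1.5, 1], [1, 2.0, 4], [1, 3.5, 0], [1, 4.0, 3],
             [1, 5.5, 5]],
            dtype=float,
        )
        y = np.array([1.0, 2.2, 2.9, 4.1, 5.3, 6.8])
        fit = ca.ols_fit(X, y)
        beta, _ = hc3_bruteforce(X, y)
        assert fit.params == pytest.approx(beta, rel=1e-10)

    def test_rank_deficiency_raises(self):
        X = np.column_stack([np.ones(8), np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(SingularDesignError):
            ca.ols_fit(X, np.arange(8.0))


class TestHC3:
    def test_matches_bruteforce_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = rng.integers(6, 13)
            p = rng.integers(1, 4)
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
            y = rng.normal(size=n) * (1 + rng.random(n))
            fit = ca.ols_fit(X, y)
            _, V = hc3_bruteforce(X, y)
            assert ca.hc3_covariance(fit) == pytest.approx(V, rel=1e-10, abs=1e-12)

    def test_balanced_homoskedastic_proportional_to_classical(self):
        # two-point balanced design: equal leverages, equal squared residuals
        X = np.column_stack([np.ones(4), [-1.0, -1.0, 1.0, 1.0]])
        y = np.array([0.0, 2.0, 1.0, 3.0])
        fit = ca.ols_fit(X, y)
        V = ca.hc3_covariance(fit)
        xtx_inv = np.linalg.inv(X.T @ X)
        e2 = fit.resid[0] ** 2
        h = fit.leverage[0]
        # constant e² and h make the meat proportional to XᵀX, so
        # V = (XᵀX)⁻¹ · e²/(1−h)²
        assert V == pytest.approx(xtx_inv * e2 / (1 - h) ** 2, rel=1e-10)

    def test_zero_residuals_zero_covariance(self):
        x = np.arange(6.0)
        fit = ca.ols_fit(np.column_stack([np.ones(6), x]), 2 * x + 1)
        assert np.allclose(ca.hc3_covariance(fit), 0.0, atol=1e-20)


class TestUnivariateAssociation:
    def test_perfect_fit(self):
        x = np.arange(12.0)
        r = ca.univariate_association(3 * x - 1, x)
        assert r.coefficient == pytest.approx(3.0)
        assert r.r2_pct == pytest.approx(100.0)
        assert r.n == 12

    def test_n_floor_refusal(self):
        with pytest.raises(SampleSizeError):
            ca.univariate_association([1, 2, 3], [1, 2, 3])

    def test_null_predictor_small_slope(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(50):
            y = rng.normal(size=2000)
            x = rng.normal(size=2000)
            r = ca.univariate_association(y, x)
            assert abs(r.coefficient) < 0.1
            pvals.append(r.p_value)
        # p-values roughly uniform under the null
        assert 0.2 < np.mean(pvals) < 0.8

    def test_r2_invariant_slope_scales_under_affine_predictor_rescale(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=80)
        y = 2.0 * x + rng.normal(size=80)
        r1 = ca.univariate_association(y, x)
        r2 = ca.univariate_association(y, 10.0 * x + 5.0)
        assert r2.r2_pct == pytest.approx(r1.r2_pct, rel=1e-10)
        assert r2.coefficient == pytest.approx(r1.coefficient / 10.0, rel=1e-10)

    def test_listwise_deletion_reports_n(self):
        y = [1.0, 2.0, math.nan] + list(range(10))
        x = [1.0, math.nan, 3.0] + list(range(10))
        r = ca.univariate_association(y, x)
        assert r.n == 11

    def test_normal_vs_t_ci(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rt = ca.univariate_association(y, x, ci_dist="t")
        rn = ca.univariate_association(y, x, ci_dist="normal")
        assert rt.ci95_high - rt.ci95_low > rn.ci95_high - rn.ci95_low


class TestIncrementalR2:
    @pytest.fixture()
    def base_data(self):
        rng = np.random.default_rng(21)
        base = pd.DataFrame(
            {"lactate": rng.normal(size=40), "extraction": rng.normal(size=40)}
        )
        y = base["lactate"] * 0.5 + rng.normal(size=40)
        return y, base

    def test_constant_added_predictor_is_zero_gain(self, base_data):
        y, base = base_data
        inc = ca.incremental_r2(y, base, np.full(40, 7.0))
        assert inc.delta_r2 == 0.0
        assert inc.r2_full == inc.r2_base

    def test_duplicate_predictor_singular(self, base_data):
        y, base = base_data
        with pytest.raises(SingularDesignError):
            ca.incremental_r2(y, base, base["lactate"])

    def test_residual_completion_reaches_one(self, base_data):
        y, base = base_data
        X = np.column_stack([np.ones(40), base.to_numpy()])
        resid = ca.ols_fit(X, y).resid
        inc = ca.incremental_r2(y, base, resid)
        assert inc.r2_full == pytest.approx(1.0)
        assert inc.delta_r2 >= 0

    def test_monotone_nesting_random(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            base = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
            y = rng.normal(size=30)
            added = rng.normal(size=30)
            inc = ca.incremental_r2(y, base, added)
            assert inc.delta_r2 >= -1e-12
            assert inc.r2_full >= inc.r2_base - 1e-12


class TestSubgroupAssociation:
    def test_two_group_contrast_is_mean_difference(self):
        y = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0])
        g = ["I"] * 3 + ["IV"] * 4
        res = ca.subgroup_association(y, g)
        assert res.contrasts["IV"].coefficient == pytest.approx(
            np.mean(y[3:]) - np.mean(y[:3])
        )

    def test_constant_outcome_all_contrasts_zero(self):
        y = np.full(12, 5.0)
        g = ["I", "II", "III", "IV"] * 3
        res = ca.subgroup_association(y, g)
        for contrast in res.contrasts.values():
            assert contrast.coefficient == pytest.approx(0.0, abs=1e-12)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            ca.subgroup_association([1.0, 2.0], ["II", "III"])

    def test_singleton_groups_flagged_and_excluded(self):
        y = list(range(8))
        g = ["I"] * 5 + ["II"] * 2 + ["III"]
        res = ca.subgroup_association(y, g)
        assert res.small_groups == ("III",)
        # a single-member group has leverage 1 (HC3 undefined) so it
        # cannot contribute a robust contrast
        assert "III" not in res.contrasts
        assert "II" in res.contrasts

    def test_singleton_reference_group_refused(self):
        y = list(range(8))
        g = ["I"] + ["II"] * 4 + ["III"] * 3
        with pytest.raises(SampleSizeError, match="reference group 'I'"):
            ca.subgroup_association(y, g)

    def test_ordinal_variant_present(self):
        rng = np.random.default_rng(2)
        g = ["I", "II", "III", "IV"] * 10
        code = {"I": 1, "II": 2, "III": 3, "IV": 4}
        y = [code[x] * 2.0 + rng.normal() for x in g]
        res = ca.subgroup_association(y, g)
        assert res.overall is not None
        assert res.overall.coefficient == pytest.approx(2.0, abs=0.3)


class TestPredictorTransforms:
    def test_constant_series(self):
        out = ca.predictor_transforms({"H0": 5.0, "H6": 5.0, "H24": 5.0})
        assert out["ratio_h6_h0"] == 1.0
        assert out["ratio_h24_h0"] == 1.0

    def test_doubling(self):
        out = ca.predictor_transforms({"H0": 5.0, "H6": 10.0}, threshold=6.0)
        assert out["ratio_h6_h0"] == 2.0
        assert out["h0_high"] == 0.0
        assert math.isnan(out["ratio_h24_h0"])

    def test_missing_h0_propagates(self):
        out = ca.predictor_transforms({"H6": 10.0, "H24": 3.0}, threshold=6.0)
        assert all(math.isnan(v) for v in out.values())

    def test_zero_h0_undefined_ratio(self):
        out = ca.predictor_transforms({"H0": 0.0, "H6": 10.0})
        assert math.isnan(out["ratio_h6_h0"])
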