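"""Statistical core: adjusted OLS, BCa bootstrap, BH-FDR, residualization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from vascsynergy import (ConfigurationError, DegenerateIntervalError,
                         RankDeficientError, bca_interval, bh_fdr,
                         fit_adjusted_linear, multi_ols, residualize)
from vascsynergy.stats import bca_from_replicates, design_matrix, ols_fit


class TestAdjustedLinear:
    def test_perfect_correlation_beta_one(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        df["y"] = 2.0 * df["x"]
        est = fit_adjusted_linear(df, "y", "x", standardized=True)
        assert est.beta == pytest.approx(1.0, abs=1e-12)

    def test_null_simulation_small_beta(self):
        rng = np.random.default_rng(123)
        df = pd.DataFrame({"x": rng.normal(size=10_000),
                           "y": rng.normal(size=10_000)})
        est = fit_adjusted_linear(df, "y", "x")
        assert abs(est.beta) < 0.03

    def test_covariate_fully_explains_outcome(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(size=200),
                           "c": rng.normal(size=200)})
        df["y"] = 3.0 * df["c"]
        est = fit_adjusted_linear(df, "y", "x", covariates=["c"])
        assert abs(est.beta) < 1e-10

    def test_standardized_beta_equals_pearson_r(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        y = 0.4 * x + rng.normal(size=300)
        df = pd.DataFrame({"x": x, "y": y})
        est = fit_adjusted_linear(df, "y", "x", standardized=True)
        r = sps.pearsonr(x, y).statistic
        assert abs(est.beta - r) < 1e-10

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(21)
        df = pd.DataFrame(rng.normal(size=(150, 3)), columns=["y", "x", "c"])
        est = fit_adjusted_linear(df, "y", "x", covariates=["c"],
                                  standardized=False)
        ref = sm.OLS(df["y"], sm.add_constant(df[["x", "c"]])).fit()
        assert est.beta == pytest.approx(ref.params["x"], abs=1e-10)
        assert est.se == pytest.approx(ref.bse["x"], abs=1e-10)
        assert est.p_value == pytest.approx(ref.pvalues["x"], abs=1e-10)

    def test_rank_deficient_lists_columns(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]})
        df["y"] = df["x"] + 1
        df["dup"] = 2.0 * df["x"]
        with pytest.raises(RankDeficientError, match="dup"):
            fit_adjusted_linear(df, "y", "x", covariates=["dup"])

    def test_too_few_cases_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ConfigurationError):
            fit_adjusted_linear(df, "y", "x")


class TestMultiOls:
    def test_agrees_with_per_column_ols(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(80), rng.normal(size=(80, 2))])
        Y = rng.normal(size=(80, 5))
        beta, se, pval = multi_ols(X, Y)
        for j in range(5):
            b, s, p, _ = ols_fit(X, Y[:, j])
            assert np.allclose(beta[:, j], b, atol=1e-12)
            assert np.allclose(se[:, j], s, atol=1e-12)
            assert np.allclose(pval[:, j], p, atol=1e-12)


class TestResidualize:
    def test_outcome_equals_covariate(self):
        df = pd.DataFrame({"c": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = df["c"]
        assert np.allclose(residualize(df, "y", ["c"]), 0.0, atol=1e-12)

    def test_no_covariates_centers(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 6.0]})
        assert np.allclose(residualize(df, "y"), [-2.0, -1.0, 3.0])

    def test_residual_variance_approaches_noise(self):
        rng = np.random.default_rng(17)
        c = rng.normal(size=50_000)
        y = 2.0 + 1.5 * c + rng.normal(scale=0.7, size=50_000)
        df = pd.DataFrame({"c": c, "y": y})
        res = residualize(df, "y", ["c"])
        assert abs(res.mean()) < 1e-10
        assert res.std() == pytest.approx(0.7, rel=0.02)


class TestBCa:
    def test_symmetric_sample_reduces_to_percentile(self):
        """With z0 ≈ 0 and a ≈ 0 the BCa bounds coincide with the
        percentile bounds within one ordered-replicate spacing."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        x = np.concatenate([x, -x])  # exactly symmetric about 0
        ci = bca_interval(np.mean, x, B=2000, level=0.90, seed=0)
        assert abs(ci.z0) < 0.08
        assert abs(ci.a) < 0.02
        # reconstruct the replicate set with the same seed
        rng2 = np.random.default_rng(0)
        reps = np.array([np.mean(x[rng2.integers(0, len(x), len(x))])
                         for _ in range(2000)])
        lo_p, hi_p = np.quantile(reps, [0.05, 0.95])
        spacing = np.diff(np.sort(reps)).max()
        assert abs(ci.lo - lo_p) <= 2 * spacing + 1e-12
        assert abs(ci.hi - hi_p) <= 2 * spacing + 1e-12

    def test_max_statistic_negative_z0(self):
        """For the sample maximum, P(θ* < θ̂) = (9/10)¹⁰ exactly on a
        10-point sample with distinct values, so z0 = Φ⁻¹(0.3487) < 0."""
        x = np.arange(10.0)
        ci = bca_interval(np.max, x, B=5000, level=0.90, seed=4)
        exact = sps.norm.ppf((9 / 10) ** 10)
        assert ci.z0 < 0
        assert ci.z0 == pytest.approx(exact, abs=0.05)

    def test_deterministic_and_nested_levels(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(size=60)
        a = bca_interval(np.mean, x, B=1000, level=0.90, seed=7)
        b = bca_interval(np.mean, x, B=1000, level=0.90, seed=7)
        assert (a.lo, a.hi) == (b.lo, b.hi)
        wide = bca_interval(np.mean, x, B=1000, level=0.95, seed=7)
        assert wide.hi - wide.lo > a.hi - a.lo
        assert a.lo <= a.hi

    def test_degenerate_replicates_error(self):
        x = np.ones(30)
        with pytest.raises(DegenerateIntervalError):
            bca_interval(np.mean, x, B=500, level=0.90, seed=0)

    def test_jackknife_degenerate_falls_back_to_percentile(self):
        # the median of long duplicated runs is delete-one invariant, so
        # the jackknife spread is exactly zero -> percentile fallback
        y = np.repeat([1.0, 2.0, 3.0], 15)
        res = bca_interval(np.median, y, B=500, level=0.90, seed=1)
        assert res.method == "percentile"
        assert "jackknife degenerate" in " ".join(res.warnings)

    def test_stratified_resampling_preserves_group_sizes(self):
        """The stratum proportion is invariant under within-stratum
        resampling (hence degenerate) but varies under pooled resampling."""
        data = np.concatenate([np.zeros(30), np.ones(70)])
        stat = lambda d: float(np.mean(d == 0))
        with pytest.raises(DegenerateIntervalError):
            bca_interval(stat, data, B=300, level=0.90, strata=data, seed=0)
        pooled = bca_interval(stat, data, B=300, level=0.90, seed=0)
        assert pooled.lo < 0.3 < pooled.hi

    def test_matches_scipy_reference_on_mean(self):
        """Independent cross-check against scipy's BCa implementation."""
        rng = np.random.default_rng(100)
        x = rng.gamma(2.0, size=150)
        mine = bca_interval(np.mean, x, B=4000, level=0.90, seed=5)
        ref = sps.bootstrap((x,), np.mean, n_resamples=4000,
                            confidence_level=0.90, method="BCa",
                            random_state=np.random.default_rng(5))
        half = (mine.hi - mine.lo) / 2
        assert mine.lo == pytest.approx(ref.confidence_interval.low,
                                        abs=0.1 * half)
        assert mine.hi == pytest.approx(ref.confidence_interval.high,
                                        abs=0.1 * half)

    def test_small_B_rejected(self):
        with pytest.raises(ConfigurationError):
            bca_interval(np.mean, np.arange(10.0), B=100)


def _bh_bruteforce(p):
    """Step-up BH by direct definition: q_(k) = min_{j >= k} p_(j)·m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_p = p[order]
    for k in range(m):
        q[order[k]] = min(min(sorted_p[j] * m / (j + 1) for j in range(k, m)),
                          1.0)
    return q


class TestBhFdr:
    def test_hand_computed_example(self):
        res = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(res.q_values, [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr([0.2]).q_values[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0] * 5).q_values, 1.0)

    def test_q_dominates_p_and_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.random(48)
        res = bh_fdr(p)
        assert np.all(res.q_values >= res.p_values - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(res.q_values[order]) >= -1e-15)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=8))
    def test_matches_bruteforce_small_families(self, p):
        res = bh_fdr(p)
        assert np.allclose(res.q_values, _bh_bruteforce(p), atol=1e-12)

    def test_nan_propagates(self):
        res = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(res.q_values[1])
        assert res.family_size == 2
        assert np.allclose(res.q_values[[0, 2]],
                           _bh_bruteforce([0.01, 0.5]), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bh_fdr([0.1, 1.5])
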