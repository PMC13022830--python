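"""CSVD scoring, exclusions, mixture cut-off, tertiles, standardization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from vascsynergy import (ConfigurationError, CSVDGrade, ValidationError,
                         apply_exclusions, assign_tertiles,
                         compute_csvd_burden, fit_abeta_cutoff, standardize)


class TestCSVDBurden:
    def test_exhaustive_feature_patterns(self):
        """Agrees with direct enumeration over all 16 binary patterns."""
        for pattern in itertools.product([0, 1], repeat=4):
            b = compute_csvd_burden(pattern)
            assert b.total_score == sum(pattern)
            expected = (CSVDGrade.NONE if sum(pattern) == 0 else
                        CSVDGrade.MILD if sum(pattern) == 1 else
                        CSVDGrade.MODERATE_SEVERE)
            assert b.grade == expected

    @pytest.mark.parametrize("features,score,grade", [
        ((0, 0, 0, 0), 0, CSVDGrade.NONE),
        ((1, 1, 1, 1), 4, CSVDGrade.MODERATE_SEVERE),
        ((1, 0, 1, 0), 2, CSVDGrade.MODERATE_SEVERE),
    ])
    def test_examples(self, features, score, grade):
        b = compute_csvd_burden(features)
        assert (b.total_score, b.grade) == (score, grade)

    @pytest.mark.parametrize("bad", [(1, 0, 2, 0), (1, 0, float("nan"), 0),
                                     (1, 0, None, 0), (1, 0, 1)])
    def test_invalid_features_rejected(self, bad):
        with pytest.raises(ValidationError):
            compute_csvd_burden(bad, participant="P001")

    def test_error_names_participant(self):
        with pytest.raises(ValidationError, match="P042"):
            compute_csvd_burden((1, 0, 2, 0), participant="P042")


class TestExclusions:
    def test_nfl_threshold_is_strict(self):
        df = pd.DataFrame({"nfl": [150.0, 179.0, 180.0]})
        out, log = apply_exclusions(df, nfl_threshold=179.0)
        assert out["nfl"].tolist() == [150.0, 179.0]
        assert log.removed["nfl_above_threshold"] == 1

    def test_identity_when_nothing_violates(self):
        df = pd.DataFrame({"nfl": [10.0, 20.0], "MoCA": [25, 28]})
        out, log = apply_exclusions(df, require_complete=["MoCA"])
        pd.testing.assert_frame_equal(out, df)
        assert log.remaining_n == 2

    def test_missing_cognition_logged(self):
        df = pd.DataFrame({"nfl": [10.0, 20.0, 30.0],
                           "MoCA": [25, np.nan, 28]})
        out, log = apply_exclusions(df, require_complete=["MoCA"])
        assert len(out) == 2
        assert log.removed["missing_MoCA"] == 1
        assert log.input_n - sum(log.removed.values()) == log.remaining_n

    def test_order_preserved(self):
        df = pd.DataFrame({"nfl": [30.0, 200.0, 10.0, 20.0]})
        out, _ = apply_exclusions(df)
        assert out["nfl"].tolist() == [30.0, 10.0, 20.0]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_exclusions(pd.DataFrame({"nfl": [1.0] * 3}), nfl_threshold=0)


class TestMixtureCutoff:
    def test_recovers_analytic_equal_posterior_point(self):
        """Cut-off within ±0.15 of the analytic equal-posterior point of
        0.3·N(3, 0.5²) + 0.7·N(7, 1²)."""
        rng = np.random.default_rng(42)
        n = 5000
        comp = rng.random(n) < 0.3
        x = np.where(comp, rng.normal(3.0, 0.5, n), rng.normal(7.0, 1.0, n))
        x = np.abs(x)  # keep strictly positive

        def diff(v):
            return (np.log(0.3) + norm.logpdf(v, 3.0, 0.5)
                    - np.log(0.7) - norm.logpdf(v, 7.0, 1.0))
        analytic = brentq(diff, 3.0, 7.0)
        fit = fit_abeta_cutoff(x, seed=1)
        assert fit.converged
        assert abs(fit.cutoff - analytic) < 0.15
        assert min(fit.means) < fit.cutoff < max(fit.means)
        assert abs(sum(fit.weights) - 1.0) < 1e-9

    def test_well_separated_spikes(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([1.0 + 0.01 * rng.normal(size=100),
                            9.0 + 0.01 * rng.normal(size=100)])
        fit = fit_abeta_cutoff(x, seed=0)
        assert 1.0 < fit.cutoff < 9.0
        assert fit.means[0] == pytest.approx(1.0, abs=0.05)
        assert fit.means[1] == pytest.approx(9.0, abs=0.05)

    def test_equal_components_degenerate(self):
        """Identical components: either a converged fit with cut-off near
        the common mean, or a non-identifiable (unconverged) flag."""
        rng = np.random.default_rng(7)
        x = np.abs(rng.normal(5.0, 1.0, 2000))
        fit = fit_abeta_cutoff(x, seed=3)
        assert (not fit.converged) or abs(fit.cutoff - 5.0) < 1.0

    def test_agrees_with_sklearn_reference(self):
        """Component means match an independent EM implementation."""
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(4.0, 0.8, 1500),
                            rng.normal(8.0, 1.2, 500)])
        x = np.abs(x)
        fit = fit_abeta_cutoff(x, seed=2)
        gm = GaussianMixture(2, n_init=5, random_state=0).fit(x[:, None])
        ref = np.sort(gm.means_.ravel())
        assert np.allclose(np.sort(fit.means), ref, atol=0.1)

    def test_positivity_classification_sides(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(3, 0.5, 500), rng.normal(7, 1, 500)])
        x = np.abs(x)
        hi = fit_abeta_cutoff(x, seed=0, positivity_side="at_or_above")
        assert hi.classify(np.array([hi.cutoff])).item() == 1
        assert hi.classify(np.array([hi.cutoff - 1e-6])).item() == 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            fit_abeta_cutoff(np.linspace(1, 2, 10))


class TestTertiles:
    def test_one_to_nine(self):
        labels = assign_tertiles(np.arange(1.0, 10.0))
        assert list(labels) == ["low"] * 3 + ["mid"] * 3 + ["high"] * 3

    def test_remainder_to_lowest(self):
        labels = assign_tertiles(np.arange(10.0))
        sizes = pd.Series(labels).value_counts()
        assert (sizes["low"], sizes["mid"], sizes["high"]) == (4, 3, 3)

    def test_tied_block_stable_order(self):
        """A tie spanning a boundary is split by stable input order —
        identical to the explicit stable-sort oracle."""
        v = np.array([5.0, 1.0, 5.0, 5.0, 2.0, 5.0])
        labels = assign_tertiles(v)
        order = np.argsort(v, kind="stable")
        oracle = np.empty(6, dtype=object)
        oracle[order[:2]], oracle[order[2:4]], oracle[order[4:]] = \
            "low", "mid", "high"
        assert list(labels) == list(oracle)
        assert list(labels) == list(assign_tertiles(v))  # deterministic

    def test_fewer_than_three_distinct_rejected(self):
        with pytest.raises(ValidationError):
            assign_tertiles(np.array([1.0, 1.0, 2.0, 2.0]))


class TestStandardize:
    def test_full_sample_z(self):
        df = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        out = standardize(df, ["x"])
        assert out["x_z"].tolist() == [-1.0, 0.0, 1.0]
        assert out["x"].tolist() == [2.0, 4.0, 6.0]  # original preserved

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        once = standardize(df, ["x"])
        twice = standardize(once.rename(columns={"x_z": "y"}), ["y"])
        assert np.allclose(twice["y_z"], once["x_z"], atol=1e-12)

    def test_within_stratum_means_zero(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
                           "g": [0, 0, 0, 1, 1, 1]})
        out = standardize(df, ["x"], scope="within_stratum", stratum_var="g")
        assert np.allclose(out.groupby("g")["x_z"].mean(), 0.0)
        assert out.attrs["standardization_scope"] == "within_stratum"

    def test_scopes_differ_with_unequal_strata(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 100.0, 200.0, 300.0],
                           "g": [0, 0, 0, 1, 1, 1]})
        full = standardize(df, ["x"])
        within = standardize(df, ["x"], scope="within_stratum",
                             stratum_var="g")
        assert not np.allclose(full["x_z"], within["x_z"])

    def test_zero_variance_named(self):
        df = pd.DataFrame({"flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValidationError, match="flat"):
            standardize(df, ["flat"])
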