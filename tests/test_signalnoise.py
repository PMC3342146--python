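"""Signal/noise decomposition and minimum-variance weighted averages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bpsignal as bp
from bpsignal.exceptions import (InsufficientDataError, SingularMatrixError,
                                 ValidationError)
from conftest import make_panel


def exact_cov_data(cov, n=60, rng_seed=0):
    """Construct an n x k sample whose sample covariance (ddof=1) is exactly cov."""
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    rng = np.random.default_rng(rng_seed)
    X = rng.normal(size=(n, k))
    X -= X.mean(axis=0)
    # whiten then color
    L = np.linalg.cholesky(np.cov(X, rowvar=False, ddof=1))
    Z = X @ np.linalg.inv(L).T
    return Z @ np.linalg.cholesky(cov).T


class TestDecomposition:
    def test_exact_compound_symmetry_case(self):
        """Off-diagonals 2, diagonals (5,3,4,6): signal 2, noise (3,1,2,4)."""
        cov = np.full((4, 4), 2.0)
        np.fill_diagonal(cov, [5.0, 3.0, 4.0, 6.0])
        signal, noise = bp.decompose_covariance(cov)
        assert signal == pytest.approx(2.0)
        np.testing.assert_allclose(noise, [3.0, 1.0, 2.0, 4.0])
        # same through the estimator on data with that exact sample covariance
        est = bp.SignalNoiseEstimator().fit(exact_cov_data(cov))
        assert est.signal_var_ == pytest.approx(2.0)
        np.testing.assert_allclose(est.noise_vars_, [3.0, 1.0, 2.0, 4.0], atol=1e-9)
        np.testing.assert_allclose(est.snr_, [2 / 3, 2.0, 1.0, 0.5], atol=1e-9)

    def test_duplicated_method_shares_noise(self):
        """A method equal to another has pairwise covariance = common variance,
        so the pair's noise estimates coincide."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        X[:, 2] = X[:, 0]
        est = bp.SignalNoiseEstimator().fit(X)
        var0 = np.var(X[:, 0], ddof=1)
        assert est.covariance_[0, 2] == pytest.approx(var0)
        assert est.noise_vars_[0] == pytest.approx(est.noise_vars_[2])

    def test_generator_truth_recovery(self):
        """Estimates track the configured signal and noise variances."""
        cfg = bp.GeneratorConfig(n_subjects=4000, beta={}, signal_resid_var=50.0,
                                 noise_vars=(150.0, 30.0, 40.0, 100.0), seed=31)
        cohort = bp.generate_cohort(cfg)
        panel = bp.adjust_pretreatment(bp.compute_responses(cohort, "atenolol", "systolic"))
        dec = bp.estimate_signal_noise(panel)
        assert abs(dec.signal_var - 50.0) < 3.0
        np.testing.assert_array_less(np.abs(dec.noise_vars - np.array(cfg.noise_vars)),
                                     [15, 8, 9, 13])
        # decomposition identity holds exactly
        np.testing.assert_allclose(dec.noise_vars + dec.signal_var,
                                   np.diag(dec.cov_matrix), atol=1e-10)

    def test_negative_noise_is_flagged_not_clipped(self):
        # unequal factor loadings: method 1 loads weakly, so its total variance
        # (0.74) falls below the mean pairwise covariance (2.8)
        a = np.array([1.0, 0.4, 1.0, 1.0])
        cov = 4.0 * np.outer(a, a) + np.diag([2.0, 0.1, 2.0, 2.0])
        panel = make_panel(exact_cov_data(cov))
        panel.adjusted = panel.raw
        dec = bp.estimate_signal_noise(panel)
        assert dec.noise_vars[1] < 0
        assert "home" in dec.negative_noise
        assert np.isnan(dec.snr[1])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InsufficientDataError):
            bp.SignalNoiseEstimator().fit(np.zeros((4, 4)) + np.eye(4))

    def test_non_finite_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        X[3, 2] = np.nan
        with pytest.raises(ValidationError):
            bp.SignalNoiseEstimator().fit(X)

    def test_scaling_equivariance(self):
        """Scaling responses by c scales signal and noise by c^2."""
        X = np.random.default_rng(2).normal(size=(40, 4))
        a = bp.SignalNoiseEstimator().fit(X)
        b = bp.SignalNoiseEstimator().fit(3.0 * X)
        assert b.signal_var_ == pytest.approx(9.0 * a.signal_var_)
        np.testing.assert_allclose(b.noise_vars_, 9.0 * a.noise_vars_, atol=1e-9)

    def test_column_shift_invariance(self):
        """Adding a method-specific constant leaves the decomposition unchanged."""
        X = np.random.default_rng(3).normal(size=(40, 4))
        shifted = X + np.array([5.0, -2.0, 0.0, 11.0])
        a = bp.SignalNoiseEstimator().fit(X)
        b = bp.SignalNoiseEstimator().fit(shifted)
        assert b.signal_var_ == pytest.approx(a.signal_var_)
        np.testing.assert_allclose(b.noise_vars_, a.noise_vars_, atol=1e-9)


class TestMinVarianceWeights:
    def test_compound_symmetric_gives_equal_weights(self):
        cov = 50.0 * np.ones((4, 4)) + np.diag([30.0] * 4)
        spec = bp.min_variance_weights(cov, bp.METHODS, 50.0)
        np.testing.assert_allclose(spec.weights, 0.25, atol=1e-12)

    def test_two_method_worked_case(self):
        """Sigma = [[2,1],[1,4]] (signal 1, noises 1 and 3): weights (3/4, 1/4)."""
        cov = np.array([[2.0, 1.0], [1.0, 4.0]])
        spec = bp.min_variance_weights(cov, [0, 1], 1.0, methods=("a", "b"))
        np.testing.assert_allclose(spec.weights, [0.75, 0.25], atol=1e-12)
        assert spec.combined_var == pytest.approx(1.75)
        assert spec.combined_noise == pytest.approx(0.75)
        assert spec.combined_snr == pytest.approx(4.0 / 3.0)
        # grid-search oracle over the weight simplex
        w = np.linspace(0.0, 1.0, 100_001)
        variances = (w ** 2 * 2.0 + 2 * w * (1 - w) * 1.0 + (1 - w) ** 2 * 4.0)
        assert variances.min() == pytest.approx(spec.combined_var, abs=1e-6)
        assert w[variances.argmin()] == pytest.approx(spec.weights[0], abs=1e-4)

    def test_singleton_subset(self):
        cov = np.diag([2.0, 3.0, 4.0, 5.0])
        spec = bp.min_variance_weights(cov, ["home"], 1.0)
        np.testing.assert_allclose(spec.weights, [1.0])
        assert spec.combined_var == pytest.approx(3.0)

    def test_singular_subset_named(self):
        cov = np.ones((4, 4))
        with pytest.raises(SingularMatrixError) as err:
            bp.min_variance_weights(cov, ["office", "home"], 1.0)
        assert "office" in str(err.value)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.1, 100.0), min_size=4, max_size=4),
           st.floats(0.1, 50.0))
    def test_precision_weights_for_uncorrelated_noise(self, noises, signal):
        """For Sigma = s J + diag(d), the min-variance weights are 1/d normalized."""
        d = np.asarray(noises)
        cov = signal * np.ones((4, 4)) + np.diag(d)
        spec = bp.min_variance_weights(cov, bp.METHODS, signal)
        np.testing.assert_allclose(spec.weights, (1 / d) / (1 / d).sum(), atol=1e-8)
        # combination never worse than the best single method...
        assert spec.combined_var <= d.min() + signal + 1e-9
        # ...and its SNR dominates every single-method SNR (sum property)
        assert spec.combined_snr >= (signal / d).max() - 1e-9
        assert spec.combined_snr == pytest.approx((signal / d).sum(), rel=1e-8)

    def test_combined_snr_dominates_on_generator_replicates(self):
        """Estimated min-variance weights beat each single method's SNR."""
        for seed in range(20):
            cfg = bp.default_config(n_subjects=500, seed=800 + seed)
            cohort = bp.generate_cohort(cfg)
            panel = bp.adjust_pretreatment(
                bp.compute_responses(cohort, "atenolol", "systolic"))
            dec = bp.estimate_signal_noise(panel)
            if dec.negative_noise:
                continue
            spec = bp.min_variance_weights(dec.cov_matrix, bp.METHODS, dec.signal_var)
            assert spec.combined_snr >= np.nanmax(dec.snr) - 1e-9


class TestWeightedAverage:
    def test_unit_weight_returns_that_column(self, atenolol_systolic_5000):
        _, _, panel, _ = atenolol_systolic_5000
        spec = bp.WeightedAverageSpec(methods=("office",), weights=np.array([1.0]),
                                      combined_var=0.0, combined_noise=0.0,
                                      combined_snr=np.nan)
        out = bp.apply_weighted_average(panel, spec)
        np.testing.assert_allclose(out, panel.adjusted["office"].to_numpy())

    def test_equal_weights_on_identical_columns(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        X[:, 1] = X[:, 0]
        panel = make_panel(X, adjusted=X)
        spec = bp.WeightedAverageSpec(methods=("office", "home"),
                                      weights=np.array([0.5, 0.5]),
                                      combined_var=0.0, combined_noise=0.0,
                                      combined_snr=np.nan)
        np.testing.assert_allclose(bp.apply_weighted_average(panel, spec), X[:, 0])

    def test_subset_mismatch_rejected(self):
        panel = make_panel(np.zeros((6, 4)), adjusted=np.zeros((6, 4)))
        spec = bp.WeightedAverageSpec(methods=("office", "wrist"),
                                      weights=np.array([0.5, 0.5]),
                                      combined_var=0.0, combined_noise=0.0,
                                      combined_snr=np.nan)
        with pytest.raises(ValidationError):
            bp.apply_weighted_average(panel, spec)

    def test_combined_sample_variance_equals_quadratic_form(self, atenolol_systolic_5000):
        """var(Xw) = w' Sigma-hat w exactly, and tracks the population value."""
        cfg, _, panel, _ = atenolol_systolic_5000
        dec = bp.estimate_signal_noise(panel)
        spec = bp.min_variance_weights(dec.cov_matrix, bp.METHODS, dec.signal_var)
        out = bp.apply_weighted_average(panel, spec)
        assert np.var(out, ddof=1) == pytest.approx(spec.combined_var, rel=1e-10)
        truth = bp.response_covariance_truth(cfg, adjusted=True)
        pop = spec.weights @ truth @ spec.weights
        se = pop * np.sqrt(2.0 / panel.n_subjects)
        assert abs(spec.combined_var - pop) < 4 * se

    def test_combiner_estimator_api(self):
        from sklearn.base import clone
        X = exact_cov_data(50.0 * np.ones((4, 4)) + np.diag([30.0] * 4), n=80)
        comb = bp.MinimumVarianceCombiner(subset=("office", "home"))
        assert clone(comb).get_params()["subset"] == ("office", "home")
        out = comb.fit(X).transform(X)
        assert out.shape == (80, 1)
        np.testing.assert_allclose(comb.weights_.sum(), 1.0)
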