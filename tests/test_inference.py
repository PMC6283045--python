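"""Confidence intervals: information matrix oracles, classical t-interval
exactness, degrees-of-freedom identities, and interval orderings."""

import math

import numpy as np
import pytest
from scipy import stats

from ipdmeta.dataset import ModelSpec, build_design
from ipdmeta.exceptions import InferenceError, UsageError
from ipdmeta.fit import FitResult, fit
from ipdmeta.inference import (
    CIResult,
    ci_kenward_roger,
    ci_satterthwaite,
    ci_standard,
    corrected_cis,
    coverage_indicator,
    varcomp_information,
)
from ipdmeta.likelihood import marginal_loglik

from .conftest import make_balanced_dataset
from .oracles import dense_expected_information, pooled_t_interval


def _single_trial_dataset(n=40, seed=2):
    rng = np.random.default_rng(seed)
    return make_balanced_dataset(K=1, n=n, noise=rng.normal(0, 12.0, n))


def _dummy_fit(theta=-9.66, var=1.0, alpha=0.05):
    spec = ModelSpec()
    return FitResult(
        theta_hat=theta, var_theta=var, fixed_effects=np.array([theta]),
        fixed_names=["theta"], fixed_cov=np.array([[var]]), sigma2_hat=1.0,
        tau2_hat=0.0, tau_beta2_hat=None, loglik=0.0, converged=True,
        n_iter=1, runtime_seconds=0.0, spec=spec,
        varcomp=np.array([1.0, 0.0]), varcomp_names=["sigma2", "tau2"],
    )


class TestInformationMatrix:
    def test_single_trial_reml_matches_chi_square_variance(self):
        """For one balanced trial with a common effect, the REML variance
        of sigma2_hat is exactly 2 sigma^4 / (n - p)."""
        data = _single_trial_dataset(n=40)
        spec = ModelSpec(intercept_mode="stratified", treatment_mode="common",
                         estimation="REML")
        r = fit(data, spec)
        W = varcomp_information(r, r.design)
        expected = 2.0 * r.sigma2_hat**2 / (data.n_total - 2)
        assert W.shape == (1, 1)
        assert W[0, 0] == pytest.approx(expected, rel=1e-8)

    def test_symmetric_and_psd(self, base_dataset):
        for im in ("stratified", "random"):
            r = fit(base_dataset, ModelSpec(intercept_mode=im, estimation="REML"))
            W = varcomp_information(r, r.design)
            np.testing.assert_allclose(W, W.T, atol=1e-12)
            assert np.linalg.eigvalsh(W).min() >= -1e-10

    def test_matches_dense_information_oracle(self, small_dataset):
        """Low-rank expected information == dense-matrix evaluation."""
        for im in ("stratified", "random"):
            for est in ("ML", "REML"):
                spec = ModelSpec(intercept_mode=im, estimation=est)
                r = fit(small_dataset, spec)
                assert r.converged
                psi = np.maximum(r.varcomp, 1e-8)  # oracle needs V invertible
                r.varcomp = psi
                W = varcomp_information(r, r.design)
                info_dense = dense_expected_information(psi, small_dataset, spec)
                np.testing.assert_allclose(W, np.linalg.inv(info_dense),
                                           rtol=1e-6, atol=1e-10)

    def test_q1_inverse_fd_hessian_at_optimum(self):
        """For the single-component model the expected information at the
        REML optimum equals the curvature of the criterion, so W matches
        the inverse finite-difference Hessian to high accuracy."""
        data = _single_trial_dataset(n=30)
        spec = ModelSpec(intercept_mode="stratified", treatment_mode="common",
                         estimation="REML")
        r = fit(data, spec)
        d = r.design
        s2 = r.sigma2_hat
        h = 1e-3 * s2
        f = lambda v: marginal_loglik([v], d, "REML")[0]
        hess = (f(s2 + h) - 2 * f(s2) + f(s2 - h)) / h**2
        W = varcomp_information(r, d)
        assert W[0, 0] == pytest.approx(-1.0 / hess, rel=1e-3)


class TestStandardCI:
    def test_textbook_example(self):
        ci = ci_standard(_dummy_fit(theta=-9.66, var=1.0), alpha=0.05)
        assert round(ci.lower, 2) == -11.62
        assert round(ci.upper, 2) == -7.70
        assert ci.df == math.inf

    @pytest.mark.parametrize("alpha", [0.0, 1.0])
    def test_degenerate_alpha_rejected(self, alpha):
        with pytest.raises(InferenceError):
            ci_standard(_dummy_fit(), alpha=alpha)

    def test_width_identity(self):
        for var, alpha in [(1.0, 0.05), (4.2, 0.01), (0.3, 0.10)]:
            ci = ci_standard(_dummy_fit(var=var), alpha=alpha)
            expected = 2 * stats.norm.ppf(1 - alpha / 2) * math.sqrt(var)
            assert (ci.upper - ci.lower) == pytest.approx(expected, rel=1e-12)


class TestCorrectedCIs:
    def test_single_trial_equals_classical_pooled_t(self):
        """One balanced trial, common effect: both corrections reproduce
        the classical pooled two-sample t interval."""
        data = _single_trial_dataset(n=40)
        spec = ModelSpec(intercept_mode="stratified", treatment_mode="common",
                         estimation="REML")
        r = fit(data, spec)
        satt, kr = corrected_cis(r, r.design)
        y, t = data.y_final, data.treat
        lo, hi, df = pooled_t_interval(y[t == 1], y[t == 0])
        for ci in (satt, kr):
            assert ci.df == pytest.approx(df, abs=1e-6)
            assert ci.lower == pytest.approx(lo, abs=1e-6)
            assert ci.upper == pytest.approx(hi, abs=1e-6)
        assert kr.var_used == pytest.approx(r.var_theta, rel=1e-10)

    def test_kr_df_equals_satterthwaite_df(self, base_dataset):
        for im in ("stratified", "random"):
            r = fit(base_dataset, ModelSpec(intercept_mode=im, estimation="REML"))
            satt, kr = corrected_cis(r, r.design)
            assert abs(kr.df - satt.df) < 1e-6

    def test_satterthwaite_contains_standard(self, base_dataset):
        for im in ("stratified", "random"):
            r = fit(base_dataset, ModelSpec(intercept_mode=im, estimation="REML"))
            std = ci_standard(r)
            satt = ci_satterthwaite(r, r.design)
            assert satt.lower < std.lower and std.upper < satt.upper

    def test_kr_at_least_as_wide_as_satterthwaite_on_base_fixture(self, base_dataset):
        for im in ("stratified", "random"):
            r = fit(base_dataset, ModelSpec(intercept_mode=im, estimation="REML"))
            satt, kr = corrected_cis(r, r.design)
            assert (kr.upper - kr.lower) >= (satt.upper - satt.lower) - 1e-12

    def test_df_finite_and_bounded_on_base_fixture(self, base_dataset):
        r = fit(base_dataset, ModelSpec(intercept_mode="stratified",
                                        estimation="REML"))
        satt, _ = corrected_cis(r, r.design)
        assert 0 < satt.df < base_dataset.n_total

    def test_large_single_trial_corrections_converge_to_standard(self):
        """As n grows with K=1 the t quantile approaches z and all three
        intervals coincide to < 1% in width."""
        data = _single_trial_dataset(n=10_000, seed=4)
        r = fit(data, ModelSpec(intercept_mode="stratified",
                                treatment_mode="common", estimation="REML"))
        std = ci_standard(r)
        satt, kr = corrected_cis(r, r.design)
        w_std = std.upper - std.lower
        for ci in (satt, kr):
            assert abs((ci.upper - ci.lower) - w_std) / w_std < 0.01

    def test_ml_fit_gets_usage_error(self, base_dataset):
        r = fit(base_dataset, ModelSpec(estimation="ML"))
        with pytest.raises(UsageError):
            ci_satterthwaite(r, r.design)
        with pytest.raises(UsageError):
            ci_kenward_roger(r, r.design)


class TestCoverageIndicator:
    def test_decisions(self):
        ci = CIResult("standard", -11.62, -7.70, math.inf, 1.0, 0.05, -9.66)
        assert coverage_indicator(ci, -9.66) == 1
        assert coverage_indicator(CIResult("standard", -9.0, -7.0, math.inf,
                                           1.0, 0.05, -8.0), -9.66) == 0
        # closed interval: boundary counts as covered
        assert coverage_indicator(CIResult("standard", -9.66, -7.0, math.inf,
                                           1.0, 0.05, -8.0), -9.66) == 1
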