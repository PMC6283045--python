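"""Estimation: exact recovery, closed-form GLS, cross-implementation
oracles, boundary behaviour, and stationarity at the optimum."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from ipdmeta.dataset import ModelSpec
from ipdmeta.dgm import generate_dataset, load_scenario, replicate_rng
from ipdmeta.exceptions import ValidationError
from ipdmeta.fit import fit, fit_all_combinations
from ipdmeta.likelihood import marginal_loglik

from .conftest import make_balanced_dataset
from .oracles import weighted_mean_difference


class TestExactData:
    def test_noise_free_recovery_all_combinations(self, noise_free_dataset):
        """Y = 159.73 - 9.66 * treat exactly: every fit returns theta_hat
        = -9.66 with all variances on the zero boundary."""
        results = fit_all_combinations(noise_free_dataset)
        assert len(results) == 4
        for r in results:
            assert r.converged
            assert r.theta_hat == pytest.approx(-9.66, abs=1e-9)
            assert r.sigma2_hat == 0.0
            assert r.tau2_hat == 0.0

    def test_fan_out_order_and_spec_echo(self, base_dataset):
        results = fit_all_combinations(base_dataset)
        combos = [(r.spec.intercept_mode, r.spec.estimation) for r in results]
        assert combos == [
            ("stratified", "ML"),
            ("stratified", "REML"),
            ("random", "ML"),
            ("random", "REML"),
        ]
        for r in results:
            assert (r.tau2_hat is not None) == (r.spec.treatment_mode == "random")
            assert (r.tau_beta2_hat is not None) == (r.spec.intercept_mode == "random")


class TestClosedFormOracles:
    def test_common_effect_stratified_theta_is_weighted_mean_difference(self):
        """With a common effect and stratified intercepts, GLS reduces to
        the n_T n_C / n weighted average of per-trial mean differences."""
        cfg = load_scenario("B3")  # unequal trial sizes exercise the weights
        data, _ = generate_dataset(cfg, replicate_rng(17, "B3", "normal_random", 0))
        for est in ("ML", "REML"):
            r = fit(data, ModelSpec(intercept_mode="stratified",
                                    treatment_mode="common", estimation=est))
            assert r.converged
            assert r.theta_hat == pytest.approx(weighted_mean_difference(data),
                                                abs=1e-8)

    def test_cross_implementation_random_intercept(self, base_dataset):
        """Same model in statsmodels MixedLM (independent variance
        components): theta to 1e-5, tau2 to 1e-4 relative."""
        import statsmodels.formula.api as smf

        df = base_dataset.to_dataframe()
        df["one"] = 1.0
        vc = {"icept": "0 + one", "slope": "0 + treat"}
        for reml in (False, True):
            sm = smf.mixedlm("y_final ~ treat", df, groups="trial",
                             vc_formula=vc).fit(reml=reml, method="lbfgs",
                                                maxiter=5000, factr=10.0,
                                                pgtol=1e-10, maxfun=10000)
            ours = fit(base_dataset, ModelSpec(
                intercept_mode="random",
                estimation="REML" if reml else "ML",
            ))
            assert ours.converged
            assert ours.theta_hat == pytest.approx(sm.params["treat"], abs=1e-5)
            sm_tau2 = float(sm.vcomp[1])
            assert ours.tau2_hat == pytest.approx(sm_tau2, rel=1e-4, abs=1e-4)
            # and our optimum is at least as good under our own criterion
            d = ours.design
            sm_crit, _, _ = marginal_loglik(
                [sm.scale, sm_tau2, float(sm.vcomp[0])], d, ours.spec.estimation
            )
            assert ours.loglik >= sm_crit - 1e-6

    def test_cross_implementation_stratified_lme4(self, base_dataset, tmp_path):
        """lme4/lmerTest oracle for the stratified model, where
        statsmodels' optimizer is unreliable: tau2/sigma2 to 1e-4
        relative and Satterthwaite df to 1e-3."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the lme4 oracle")
        csv = tmp_path / "d.csv"
        base_dataset.to_dataframe().to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            d$trial <- factor(d$trial)
            m <- lmerTest::lmer(
              y_final ~ 0 + trial + treat + (0 + treat | trial), data = d,
              REML = TRUE)
            vc <- as.data.frame(VarCorr(m))
            s <- summary(m)$coefficients
            cat(fixef(m)["treat"], vc$vcov[1], vc$vcov[2], s["treat", "df"], "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        theta, tau2, sigma2, _df = map(float, out.stdout.split())

        ours = fit(base_dataset, ModelSpec(intercept_mode="stratified",
                                           estimation="REML"))
        assert ours.theta_hat == pytest.approx(theta, abs=1e-5)
        assert ours.tau2_hat == pytest.approx(tau2, rel=1e-4)
        assert ours.sigma2_hat == pytest.approx(sigma2, rel=1e-4)


class TestBoundaryAndBias:
    def test_ml_tau2_never_above_reml_in_median(self, base_run):
        """ML shrinks the between-trial variance harder than REML."""
        _, table = base_run
        std = table[(table.ci_method == "standard") & (table.converged == 1)]
        for model in ("stratified", "random"):
            med = {
                est: std[(std.model == model) & (std.estimation == est)]
                ["tau2_hat"].median()
                for est in ("ML", "REML")
            }
            assert med["ML"] <= med["REML"]

    def test_stratified_ml_shrinks_tau2_at_least_as_much_as_random_ml(self, base_run):
        """Per replicate, the stratified-intercept ML fit gives the
        smaller tau2 estimate in a clear majority of the first 100
        base-case replicates."""
        _, table = base_run
        ml = table[(table.ci_method == "standard") & (table.estimation == "ML")
                   & (table.rep_index < 100) & (table.converged == 1)]
        wide = ml.pivot(index="rep_index", columns="model", values="tau2_hat").dropna()
        assert (wide["stratified"] <= wide["random"] + 1e-12).mean() > 0.5

    def test_parameter_recovery_mean_theta(self, base_run):
        """Over >= 500 base-case replicates every model/estimation
        combination recovers theta = -9.66 within 3 Monte-Carlo SEs."""
        _, table = base_run
        std = table[(table.ci_method == "standard") & (table.converged == 1)]
        for (model, est), grp in std.groupby(["model", "estimation"]):
            th = grp["theta_hat"].to_numpy()
            assert len(th) >= 500
            mcse = th.std(ddof=1) / np.sqrt(len(th))
            assert abs(th.mean() - (-9.66)) < 3 * mcse


class TestStationarityAndErrors:
    def test_gradient_vanishes_at_interior_optimum(self, base_dataset):
        """Central-difference gradient of the criterion at the optimum
        has norm < 1e-4 over the interior (non-boundary) components."""
        for im in ("stratified", "random"):
            for est in ("ML", "REML"):
                r = fit(base_dataset, ModelSpec(intercept_mode=im, estimation=est))
                assert r.converged
                d = r.design
                psi = r.varcomp
                interior = [j for j in range(d.q) if psi[j] > 0]
                g = []
                for j in interior:
                    h = 1e-5 * max(1.0, psi[j])
                    e = np.eye(d.q)[j] * h
                    g.append(
                        (marginal_loglik(psi + e, d, est)[0]
                         - marginal_loglik(np.maximum(psi - e, 0), d, est)[0])
                        / (2 * h)
                    )
                assert np.linalg.norm(g) < 1e-4

    def test_random_effect_needs_two_trials(self):
        data = make_balanced_dataset(K=1, n=20)
        with pytest.raises(ValidationError):
            fit(data, ModelSpec(intercept_mode="stratified", treatment_mode="random"))

    def test_variance_snapping_is_exact_zero(self, base_run):
        """Boundary tau2 estimates are stored as exactly 0, never 1e-12
        dust."""
        _, table = base_run
        small = table[(table.tau2_hat < 1e-8) & table.tau2_hat.notna()]
        assert len(small) > 0
        assert (small.tau2_hat == 0.0).all()
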