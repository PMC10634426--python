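"""Estimation machinery: marginal likelihood, recovery limits, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logsumexp

from dapaer import (CohortSpec, FitOptions, ObservationTable,
                    RandomEffectSpec, StructuralParameters,
                    approximate_marginal_loglik, generate_cohort,
                    goodness_of_fit, visual_predictive_check)
from dapaer.diagnostics import simulate_from_fit
from dapaer.estimation import BasalInsulinStep, fit_sequential, fit_step


class TestMarginalLoglik:
    def test_zero_omega_single_obs_closed_form(self):
        # proportional error, y == pred: density of eps = 0
        ll = approximate_marginal_loglik(
            np.array([50.0]), lambda eta: np.array([50.0]),
            omega=0.0, error_model="proportional", magnitude=0.185)
        assert ll == pytest.approx(stats.norm.logpdf(50.0, 50.0, 0.185 * 50.0))

    def test_zero_omega_additive_matches_normal_density(self):
        y = np.array([8.5, 8.2, 8.9])
        pred = np.array([8.4, 8.4, 8.4])
        ll = approximate_marginal_loglik(
            y, lambda eta: pred, omega=0.0, error_model="constant",
            magnitude=0.061)
        assert ll == pytest.approx(stats.norm.logpdf(y, pred, 0.061).sum())

    def test_grid_integration_agrees_with_monte_carlo(self, rng):
        y = np.array([42.0, 44.5, 41.0])
        base = np.array([45.0, 45.0, 45.0])

        def predict(eta):
            return base * (1.0 - np.minimum(0.1 * np.exp(eta), 0.999) * 0.8)

        omega, b = 1.0, 0.18
        ll_grid = approximate_marginal_loglik(
            y, predict, omega=omega, error_model="proportional", magnitude=b)
        etas = rng.normal(0.0, omega, size=400_000)
        cond = np.empty(etas.size)
        for i, e in enumerate(etas):
            pred = predict(e)
            sd = b * pred
            cond[i] = np.sum(stats.norm.logpdf(y, pred, sd))
        ll_mc = logsumexp(cond) - np.log(etas.size)
        assert ll_grid == pytest.approx(ll_mc, abs=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            approximate_marginal_loglik(np.array([1.0]), lambda e: np.array([1.0]),
                                        0.5, "proportional", magnitude=0.0)
        with pytest.raises(ValueError):
            approximate_marginal_loglik(np.array([1.0]), lambda e: np.array([1.0]),
                                        0.5, "lognormal", magnitude=0.1)
        with pytest.raises(ValueError):
            approximate_marginal_loglik(np.array([]), lambda e: np.array([]),
                                        0.5, "constant", magnitude=0.1)


class TestFitting:
    def test_near_noise_free_data_recovers_truth(self):
        """Exact-fit limit: without IIV and with tiny residual noise, the
        three steps land on the generating parameters."""
        truth = StructuralParameters(b_ins=0.005, b_glu=0.005, a_hba1c=0.0025)
        spec = CohortSpec(arm_sizes={"placebo": 80, "5mg": 80, "10mg": 80})
        table, _ = generate_cohort(spec, truth, RandomEffectSpec.none(), seed=77)
        fit = fit_sequential(table, FitOptions(seed=0, n_starts=1,
                                               compute_se=False))
        est = fit.structural
        assert est.imax_ins == pytest.approx(truth.imax_ins, rel=0.10)
        assert est.iauc50_ins == pytest.approx(truth.iauc50_ins, rel=0.15)
        assert est.b_ins == pytest.approx(truth.b_ins, rel=0.10)
        assert est.keff == pytest.approx(truth.keff, rel=0.15)
        assert est.imax_glu == pytest.approx(truth.imax_glu, rel=0.10)
        assert est.b_glu == pytest.approx(truth.b_glu, rel=0.10)
        assert est.k2 == pytest.approx(truth.k2, rel=0.15)
        assert est.imax_hba1c == pytest.approx(truth.imax_hba1c, rel=0.15)
        assert est.a_hba1c == pytest.approx(truth.a_hba1c, rel=0.15)

    def test_likelihood_invariant_under_subject_permutation(self, small_cohort,
                                                            rng):
        table, _ = small_cohort
        theta = {"imax_ins": 0.0941, "iauc50_ins": 38.8,
                 "omega_imax_ins": 1.09, "b_ins": 0.185}
        ll = BasalInsulinStep(table).loglike(theta)
        shuffled = table.df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        ll_perm = BasalInsulinStep(ObservationTable(shuffled)).loglike(theta)
        assert ll_perm == pytest.approx(ll, abs=1e-8)

    def test_objective_worse_away_from_optimum(self, phase3_fit):
        from dapaer.estimation import GlucoseStep, HbA1cStep
        table, _, fit = phase3_fit
        models = {
            1: BasalInsulinStep(table),
            2: GlucoseStep(table, driver_mode="ebe", step1=fit.steps[1]),
            3: HbA1cStep(table, driver_mode="ebe", step1=fit.steps[1],
                         step2=fit.steps[2]),
        }
        for step, model in models.items():
            theta_hat = dict(fit.steps[step].params)
            ll_hat = model.loglike(theta_hat)
            for name in theta_hat:
                for factor in (0.5, 1.5):
                    theta = dict(theta_hat)
                    theta[name] = theta_hat[name] * factor
                    assert model.loglike(theta) < ll_hat, \
                        f"step {step}: {name} x{factor} not worse"

    def test_fit_step_dispatch_and_validation(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ValueError):
            fit_step(4, table)
        with pytest.raises(ValueError):
            fit_step(2, table, driver_mode="oracle")
        r1 = fit_step(1, table, options=FitOptions(n_starts=1, compute_se=False,
                                                   maxfev=300))
        assert r1.step == 1 and np.isfinite(r1.llf)
        assert set(r1.params) == {"imax_ins", "iauc50_ins", "omega_imax_ins",
                                  "b_ins"}

    def test_rse_definition(self, small_cohort):
        table, _ = small_cohort
        r1 = fit_step(1, table, options=FitOptions(n_starts=1, maxfev=600))
        for k, se in r1.se.items():
            if np.isfinite(se):
                assert r1.rse_percent[k] == pytest.approx(
                    100 * se / abs(r1.params[k]))

    def test_removing_direct_effect_underpredicts_treatment_response(
            self, small_fit):
        """With the glucose-independent drug term removed, active-arm HbA1c
        is systematically overpredicted (response underpredicted)."""
        table, fit = small_fit
        p = fit.structural.replace(imax_hba1c=0.0)
        hb = table.subset("hba1c")
        hb = hb[(hb["arm"] == "10mg") & (hb["time_wk"] == 24.0)]
        g = (1 + p.keff * 24.0) * (1 - p.imax_ins * hb["auc"] /
                                   (p.iauc50_ins + hb["auc"])) ** (-p.k1) * \
            (1 - p.imax_glu * hb["auc"] / (p.iauc50_glu + hb["auc"]))
        pred_no_direct = hb["hba1c0"] * (1 + p.k2 * (g - 1))
        obs_change = (hb["value"] - hb["hba1c0"]).mean()
        pred_change = (pred_no_direct - hb["hba1c0"]).mean()
        assert obs_change < pred_change - 0.1


class TestDiagnostics:
    def test_gof_residual_coverage_for_well_specified_fit(self, small_fit):
        table, fit = small_fit
        gof = goodness_of_fit(table, fit)
        frac = (gof["pairs"]["resid_norm"].abs() < 1.96).mean()
        assert 0.90 <= frac <= 0.99
        assert {"obs_type", "time_wk", "mean_resid", "lo95", "hi95"} <= \
            set(gof["binned"].columns)

    def test_vpc_calibrated_on_self_simulated_data(self, small_fit):
        table, fit = small_fit
        rng = np.random.default_rng(9)
        df = table.df[table.df["obs_type"].isin(
            ("basal_insulin", "cgm_glucose", "hba1c"))].reset_index(drop=True)
        df = df.assign(value=simulate_from_fit(table, fit, rng))
        selfsim = ObservationTable(df)
        vpc = visual_predictive_check(selfsim, fit, n_sim=80, seed=3)
        med = vpc[vpc["percentile"] == 50.0]
        assert med["in_band"].mean() >= 0.7

    def test_vpc_flags_shifted_data(self, small_fit):
        table, fit = small_fit
        df = table.df.copy()
        df["value"] = df["value"] * 1.2
        vpc = visual_predictive_check(ObservationTable(df), fit, n_sim=40, seed=3)
        med = vpc[vpc["percentile"] == 50.0]
        assert med["in_band"].mean() <= 0.3

    def test_vpc_requires_two_simulations(self, small_fit):
        table, fit = small_fit
        with pytest.raises(ValueError):
            visual_predictive_check(table, fit, n_sim=1)
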