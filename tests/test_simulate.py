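"""Population simulation: sampling identities, seed contract, summaries."""

import numpy as np
import pandas as pd
import pytest

from dapaer import (Arm, RandomEffect, RandomEffectSpec, StructuralParameters,
                    TrialDesign, apply_residual_error, basal_insulin_ratio,
                    design_preset, glucose_ratio, hba1c_level,
                    sample_subject_parameters, simulate_population,
                    summarize_replicates)


class TestSampleSubjectParameters:
    def test_zero_omega_returns_population_values(self, params, rng):
        spec = RandomEffectSpec(effects={"imax_ins": RandomEffect(0.0)})
        draws = sample_subject_parameters(params, spec, rng, n=50)
        for name, value in params.to_dict().items():
            assert np.all(draws[name] == value)

    def test_lognormal_median_is_population_value(self, params, rng):
        draws = sample_subject_parameters(params, RandomEffectSpec(), rng, n=10 ** 5)
        med = np.median(draws["imax_ins"])
        # MC error of the median at n=1e5 with omega=1.09 is ~1%
        assert med == pytest.approx(0.0941, rel=0.03)

    def test_lognormal_mean_identity(self, params, rng):
        draws = sample_subject_parameters(params, RandomEffectSpec(), rng, n=10 ** 5)
        expected = 0.165 * np.exp(0.739 ** 2 / 2)
        assert draws["k2"].mean() == pytest.approx(expected, rel=0.02)

    def test_normal_family_additive(self, params, rng):
        draws = sample_subject_parameters(params, RandomEffectSpec(), rng, n=10 ** 5)
        assert draws["keff"].mean() == pytest.approx(0.0015, abs=1e-4)
        assert draws["keff"].std() == pytest.approx(0.003, rel=0.02)

    def test_lognormal_on_nonpositive_population_value_rejected(self, rng):
        p = StructuralParameters(keff=0.0)
        spec = RandomEffectSpec(effects={"keff": RandomEffect(0.5, "lognormal")})
        with pytest.raises(ValueError):
            sample_subject_parameters(p, spec, rng, n=10)

    def test_fraction_draws_stay_below_one(self, params, rng):
        draws = sample_subject_parameters(params, RandomEffectSpec(), rng, n=10 ** 5)
        assert draws["imax_ins"].max() < 1.0


class TestResidualError:
    def test_proportional_error_cv_identity(self, params, rng):
        y = apply_residual_error(np.full(10 ** 5, 180.0), "cgm_glucose", params, rng)
        assert y.std() / y.mean() == pytest.approx(0.162, rel=0.02)

    def test_constant_error_sd_identity(self, params, rng):
        y = apply_residual_error(np.full(10 ** 5, 8.48), "hba1c", params, rng)
        assert y.std() == pytest.approx(0.061, rel=0.02)
        assert y.mean() == pytest.approx(8.48, abs=0.002)

    def test_unknown_obs_type_rejected(self, params, rng):
        with pytest.raises(ValueError):
            apply_residual_error(np.ones(3), "weight", params, rng)

    def test_values_floored_positive(self, params, rng):
        y = apply_residual_error(np.full(10 ** 4, 0.01), "cgm_glucose", params, rng)
        assert np.all(y > 0)


def _tiny_design(**kw):
    base = dict(arms=(Arm("placebo", 0.0, 0.0), Arm("10mg", 10.0, 594.3)),
                n_per_arm=20,
                schedule={"basal_insulin": (0.0, 12.0, 24.0),
                          "cgm_glucose": (0.0, 12.0, 24.0),
                          "hba1c": (0.0, 12.0, 24.0)})
    base.update(kw)
    return TrialDesign(**base)


class TestSimulatePopulation:
    def test_seed_contract_bit_identical(self, params):
        a = simulate_population(_tiny_design(), params, seed=99)
        b = simulate_population(_tiny_design(), params, seed=99)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_zero_omega_noise_free_equals_closed_form(self, params):
        tab = simulate_population(_tiny_design(), params,
                                  re_spec=RandomEffectSpec.none(),
                                  seed=0, noise=False)
        active = tab.df[(tab.df["arm"] == "10mg") & (tab.df["time_wk"] == 24.0)]
        r = basal_insulin_ratio(594.3, params)
        g = glucose_ratio(r, 594.3, 24.0, params)
        ins = active[active["obs_type"] == "basal_insulin"]
        np.testing.assert_allclose(ins["value"], ins["ins0"] * r, rtol=1e-12)
        glu = active[active["obs_type"] == "cgm_glucose"]
        np.testing.assert_allclose(glu["value"], glu["glu0"] * g, rtol=1e-12)
        hb = active[active["obs_type"] == "hba1c"]
        np.testing.assert_allclose(
            hb["value"], hba1c_level(g, 594.3, hb["hba1c0"], params), rtol=1e-12)

    def test_baseline_visit_is_predose(self, params):
        tab = simulate_population(_tiny_design(), params, seed=0, noise=False)
        base = tab.df[tab.df["time_wk"] == 0.0]
        for obs_type, col in (("basal_insulin", "ins0"), ("cgm_glucose", "glu0"),
                              ("hba1c", "hba1c0")):
            sub = base[base["obs_type"] == obs_type]
            np.testing.assert_allclose(sub["value"], sub[col], rtol=1e-12)

    def test_placebo_without_iiv_or_noise_identical_trajectories(self, params):
        design = _tiny_design(arms=(Arm("placebo", 0.0, 0.0),))
        tab = simulate_population(design, params,
                                  re_spec=RandomEffectSpec.none(),
                                  seed=3, noise=False)
        glu = tab.df[tab.df["obs_type"] == "cgm_glucose"]
        ratios = glu["value"] / glu["glu0"]
        for _, grp in glu.assign(ratio=ratios).groupby("time_wk"):
            assert grp["ratio"].nunique() == 1

    def test_active_arm_median_insulin_ratio_matches_structural_value(self, params):
        design = _tiny_design(n_per_arm=500)
        tab = simulate_population(design, params, seed=7, noise=False)
        ins = tab.df[(tab.df["arm"] == "10mg") & (tab.df["time_wk"] == 24.0)
                     & (tab.df["obs_type"] == "basal_insulin")]
        ratio = (ins["value"] / ins["ins0"]).to_numpy()
        assert np.median(ratio) == pytest.approx(0.91167, abs=0.01)
        assert ratio.std() > 0.02  # omega-driven spread

    def test_design_validation(self):
        with pytest.raises(ValueError):
            _tiny_design(n_per_arm=0)
        with pytest.raises(ValueError):
            _tiny_design(schedule={"cgm_glucose": (-1.0,)})
        with pytest.raises(ValueError):
            simulate_population(_tiny_design(schedule={"hemoglobin": (0.0,)}))

    def test_preset_schedules(self):
        ph3 = design_preset("phase3_24wk")
        assert ph3.schedule["hba1c"] == (0.0, 4.0, 8.0, 12.0, 18.0, 24.0)
        assert ph3.schedule["cgm_glucose"] == (0.0, 12.0, 24.0)
        ph2 = design_preset("phase2_inpatient")
        assert "hba1c" not in ph2.schedule
        assert max(ph2.schedule["cgm_glucose"]) == 1.0  # one inpatient week
        with pytest.raises(ValueError):
            design_preset("phase4")


class TestSummarizeReplicates:
    def test_percentile_oracle(self):
        s = summarize_replicates(np.arange(1.0, 101.0))
        assert s["mean"] == pytest.approx(50.5)
        assert s["lo95"] == pytest.approx(3.475)
        assert s["hi95"] == pytest.approx(97.525)

    def test_identical_replicates_zero_width(self):
        s = summarize_replicates([2.0] * 10)
        assert s["lo95"] == s["hi95"] == s["mean"] == 2.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_replicates([])
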