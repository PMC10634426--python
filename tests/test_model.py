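"""Structural-model arithmetic against hand-evaluated oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dapaer import (StructuralParameters, SubjectBaseline, basal_insulin_ratio,
                    emax_fraction, glucose_ratio, hba1c_level,
                    predict_trajectory)


class TestEmaxFraction:
    @pytest.mark.parametrize("auc,imax,iauc50,expected", [
        (0.0, 0.0941, 38.8, 0.0),
        (38.8, 0.0941, 38.8, 0.0941 / 2),                  # exact half-maximum
        (594.3, 0.0941, 38.8, 0.0941 * 594.3 / 633.1),     # hand arithmetic
    ])
    def test_values(self, auc, imax, iauc50, expected):
        assert emax_fraction(auc, imax, iauc50) == pytest.approx(expected, rel=1e-12)

    def test_half_maximum_exact_to_machine_precision(self):
        for imax, i50 in [(0.0941, 38.8), (0.15, 67.4), (0.0421, 67.4)]:
            assert emax_fraction(i50, imax, i50) == imax / 2

    @pytest.mark.parametrize("bad", [
        dict(auc=-1.0, imax=0.1, iauc50=10.0),
        dict(auc=1.0, imax=0.1, iauc50=0.0),
        dict(auc=1.0, imax=1.0, iauc50=10.0),
    ])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            emax_fraction(bad["auc"], bad["imax"], bad["iauc50"])

    @given(auc=st.floats(0, 1e5), imax=st.floats(0.01, 0.99),
           iauc50=st.floats(0.1, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, auc, imax, iauc50):
        f = emax_fraction(auc, imax, iauc50)
        assert 0.0 <= f < imax
        assert emax_fraction(auc * 2 + 1, imax, iauc50) >= f


class TestChainedSubmodels:
    def test_insulin_ratio_values(self, params):
        assert basal_insulin_ratio(0.0, params) == 1.0
        assert basal_insulin_ratio(38.8, params) == pytest.approx(1 - 0.0941 / 2)
        assert basal_insulin_ratio(594.3, params) == pytest.approx(
            1 - 0.0941 * 594.3 / 633.1, rel=1e-12)

    def test_insulin_ratio_saturates(self, params):
        assert basal_insulin_ratio(1e12, params) == pytest.approx(
            1 - params.imax_ins, rel=1e-6)

    def test_glucose_ratio_identity_and_drift(self, params):
        assert glucose_ratio(1.0, 0.0, 0.0, params) == 1.0
        assert glucose_ratio(1.0, 0.0, 24.0, params) == pytest.approx(
            1 + 0.0015 * 24, rel=1e-12)

    def test_halving_insulin_raises_glucose_about_5pct(self, params):
        # closed form 0.5**(-k1) - 1 with k1 = 0.0674
        rel = glucose_ratio(0.5, 0.0, 0.0, params) - 1.0
        assert rel == pytest.approx(0.5 ** -0.0674 - 1.0, rel=1e-12)
        assert 0.04 < rel < 0.06

    def test_glucose_ratio_decreasing_in_insulin_ratio(self, params):
        assert params.k1 > 0
        g = [glucose_ratio(r, 0.0, 0.0, params) for r in (0.5, 0.7, 1.0)]
        assert g[0] > g[1] > g[2]

    def test_glucose_ratio_monotone_in_exposure(self, params):
        g = [glucose_ratio(1.0, a, 12.0, params) for a in (0, 50, 300, 600)]
        assert all(x > y for x, y in zip(g, g[1:]))

    def test_glucose_ratio_domain(self, params):
        with pytest.raises(ValueError):
            glucose_ratio(0.0, 0.0, 0.0, params)
        with pytest.raises(ValueError):
            glucose_ratio(1.0, 0.0, -1.0, params)

    def test_hba1c_values(self, params):
        assert hba1c_level(1.0, 0.0, 8.48, params) == 8.48
        # placebo drift: 8.48 * (1 + 0.165*0.036)
        assert hba1c_level(1.036, 0.0, 8.48, params) == pytest.approx(
            8.48 * (1 + 0.165 * 0.036), rel=1e-12)
        # mixed case by direct arithmetic
        expected = 8.48 * (1 + 0.165 * (0.9 - 1)) * (1 - 0.0421 * 594.3 / 661.7)
        assert hba1c_level(0.9, 594.3, 8.48, params) == pytest.approx(
            expected, rel=1e-12)

    def test_hba1c_domain(self, params):
        with pytest.raises(ValueError):
            hba1c_level(0.0, 0.0, 8.0, params)
        with pytest.raises(ValueError):
            hba1c_level(1.0, 0.0, -8.0, params)

    def test_direct_effect_nesting(self, params):
        """Disabling the glucose-independent drug term raises HbA1c for
        any positive exposure (the decomposition is well-defined)."""
        for auc in (10.0, 100.0, 594.3):
            with_direct = hba1c_level(0.95, auc, 8.48, params)
            without = hba1c_level(0.95, auc, 8.48, params, include_direct=False)
            assert with_direct < without


class TestPredictTrajectory:
    def test_placebo_identity_at_baseline(self, params):
        b = SubjectBaseline(ins0=40, glu0=180, hba1c0=8.4)
        out = predict_trajectory(params, 0.0, b, [0.0])
        assert out["insulin_ratio"][0] == 1.0
        assert out["glucose"][0] == b.glu0
        assert out["hba1c"][0] == b.hba1c0

    def test_placebo_glucose_strictly_increasing(self, params):
        b = SubjectBaseline(ins0=40, glu0=180, hba1c0=8.4)
        out = predict_trajectory(params, 0.0, b, [0, 12, 24])
        assert np.all(np.diff(out["glucose"]) > 0)

    def test_treatment_lowers_hba1c_by_week_24(self, params):
        b = SubjectBaseline(ins0=40, glu0=180, hba1c0=8.4)
        out = predict_trajectory(params, 594.3, b, [0, 24])
        # the on-treatment prediction sits below the pre-dose baseline at
        # both times (the drug effect is instantaneous and sustained)
        assert out["hba1c"][1] < b.hba1c0
        assert out["hba1c"][0] < b.hba1c0

    def test_unsorted_times_rejected(self, params):
        b = SubjectBaseline(ins0=40, glu0=180, hba1c0=8.4)
        with pytest.raises(ValueError):
            predict_trajectory(params, 0.0, b, [12, 0])


class TestParameterContainer:
    def test_defaults_are_the_published_estimates(self):
        p = StructuralParameters()
        assert (p.imax_ins, p.iauc50_ins, p.k1, p.keff) == \
            (0.0941, 38.8, 0.0674, 0.0015)
        assert (p.imax_glu, p.iauc50_glu, p.k2, p.imax_hba1c) == \
            (0.15, 67.4, 0.165, 0.0421)
        assert (p.b_ins, p.b_glu, p.a_hba1c) == (0.185, 0.162, 0.061)

    def test_direct_iauc50_is_tied_to_glucose(self):
        p = StructuralParameters(iauc50_glu=100.0)
        assert p.iauc50_hba1c == 100.0

    @pytest.mark.parametrize("kw", [dict(imax_ins=1.0), dict(imax_glu=-0.1),
                                    dict(iauc50_glu=0.0), dict(b_ins=0.0)])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            StructuralParameters(**kw)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            StructuralParameters.from_dict({"imax": 0.1})

    @pytest.mark.parametrize("kw", [dict(ins0=0), dict(hba1c0=3.0),
                                    dict(hba1c0=16.0)])
    def test_baseline_validation(self, kw):
        base = dict(ins0=40, glu0=180, hba1c0=8.4)
        base.update(kw)
        with pytest.raises(ValueError):
            SubjectBaseline(**base)
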