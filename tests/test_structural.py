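"""Compartmental model evaluators: closed forms, ODE oracle, invariants."""

import numpy as np
import pytest

from txapk.data import DoseEvent
from txapk.structural import (TABLE_SPECS, CovariateRelation, StructuralParams,
                              StructuralSpec, predict_profile,
                              terminal_half_life, typical_value)

SPEC_2D = StructuralSpec(2, "first_order", "first_order", "none")
TYPICAL = StructuralParams(CL=0.1382, V1=9.25, Q=0.32, V2=9.49, p_urine=0.54)
BOLUS = [DoseEvent(subject="x", time=0.0, amount=1000.0, infusion_duration=1.0)]
SAMPLE_TIMES = np.array([15.0, 30.0, 60.0, 120.0, 180.0, 360.0])


class TestSpecs:
    def test_catalogue_constructible(self):
        assert len(TABLE_SPECS) == 10
        assert len({s.label() for s in TABLE_SPECS}) == 10

    def test_param_names_of_selected_model(self):
        assert SPEC_2D.param_names() == ["CL", "V1", "Q", "V2", "p_urine"]

    def test_invalid_combinations(self):
        with pytest.raises(ValueError):
            StructuralSpec(1, "first_order", "none", "first_order")  # elim_b needs 2 cmt
        with pytest.raises(ValueError):
            StructuralSpec(2, "michaelis_menten", "first_order", "none")

    def test_param_invariants(self):
        with pytest.raises(ValueError):
            StructuralParams(CL=0.1, V1=10, Q=0.1, V2=5, p_urine=1.5).validate(SPEC_2D)
        with pytest.raises(ValueError):
            StructuralParams(CL=np.nan, V1=10, Q=0.1, V2=5, p_urine=0.5).validate(SPEC_2D)
        assert TYPICAL.k_urine == pytest.approx(0.54 * 0.1382 / 9.25)


class TestPrediction:
    def test_zero_dose_zero_profile(self):
        prof = predict_profile(SPEC_2D, TYPICAL, [], SAMPLE_TIMES)
        assert np.all(prof.plasma == 0) and np.all(prof.urine_cumulative_amount == 0)

    def test_closed_form_matches_ode(self):
        cf = predict_profile(SPEC_2D, TYPICAL, BOLUS, SAMPLE_TIMES, method="closed_form")
        od = predict_profile(SPEC_2D, TYPICAL, BOLUS, SAMPLE_TIMES, method="ode",
                             rtol=1e-10)
        assert np.allclose(cf.plasma, od.plasma, rtol=1e-6)
        assert np.allclose(cf.urine_cumulative_amount, od.urine_cumulative_amount,
                           rtol=1e-6)

    def test_peripheral_elimination_matches_ode(self):
        spec = StructuralSpec(2, "first_order", "none", "first_order")
        params = StructuralParams(CL=0.1, V1=9.0, Q=0.3, V2=9.0, CLB=0.05)
        cf = predict_profile(spec, params, BOLUS, SAMPLE_TIMES, method="closed_form")
        od = predict_profile(spec, params, BOLUS, SAMPLE_TIMES, method="ode", rtol=1e-10)
        assert np.allclose(cf.plasma, od.plasma, rtol=1e-6)

    def test_three_compartment_matches_ode(self):
        spec = StructuralSpec(3, "first_order", "none", "none")
        params = StructuralParams(CL=0.12, V1=8.0, Q=0.3, V2=9.0, Q2=0.1, V3=20.0)
        cf = predict_profile(spec, params, BOLUS, SAMPLE_TIMES, method="closed_form")
        od = predict_profile(spec, params, BOLUS, SAMPLE_TIMES, method="ode", rtol=1e-10)
        assert np.allclose(cf.plasma, od.plasma, rtol=1e-6)

    def test_superposition_of_doses(self):
        rescue = DoseEvent(subject="x", time=87.0, amount=1000.0, infusion_duration=1.0)
        both = predict_profile(SPEC_2D, TYPICAL, BOLUS + [rescue], SAMPLE_TIMES)
        one = predict_profile(SPEC_2D, TYPICAL, BOLUS, SAMPLE_TIMES)
        two = predict_profile(SPEC_2D, TYPICAL, [rescue], SAMPLE_TIMES)
        assert np.allclose(both.plasma, one.plasma + two.plasma, rtol=1e-8)
        assert np.allclose(both.urine_cumulative_amount,
                           one.urine_cumulative_amount + two.urine_cumulative_amount,
                           rtol=1e-8)

    def test_mass_conservation_full_urinary(self):
        params = StructuralParams(CL=0.1382, V1=9.25, Q=0.32, V2=9.49, p_urine=1.0)
        t_half = terminal_half_life(params, SPEC_2D)
        t_inf = np.array([50.0 * t_half])
        prof = predict_profile(SPEC_2D, params, BOLUS, t_inf)
        assert prof.urine_cumulative_amount[-1] == pytest.approx(1000.0, rel=1e-3)

    def test_urinary_fraction_equals_p_urine(self):
        t_half = terminal_half_life(TYPICAL, SPEC_2D)
        prof = predict_profile(SPEC_2D, TYPICAL, BOLUS, np.array([50.0 * t_half]))
        assert prof.urine_cumulative_amount[-1] / 1000.0 == pytest.approx(0.54, rel=1e-3)

    def test_urine_cumulative_monotone(self):
        ts = np.linspace(1.0, 720.0, 200)
        prof = predict_profile(SPEC_2D, TYPICAL, BOLUS, ts)
        assert np.all(np.diff(prof.urine_cumulative_amount) >= -1e-9)
        assert np.all(prof.plasma >= 0)

    def test_michaelis_menten_first_order_limit(self):
        # Vmax/Km fixed at CL as Km grows: saturable -> linear urinary route
        lin = StructuralParams(CL=0.14, V1=10.0, Q=0.3, V2=9.0)
        spec_lin = StructuralSpec(2, "first_order", "none", "none")
        spec_mm = StructuralSpec(2, "michaelis_menten", "none", "none")
        ref = predict_profile(spec_lin, lin, BOLUS, SAMPLE_TIMES)
        km = 1e5
        mm = StructuralParams(Vmax=0.14 * km, Km=km, V1=10.0, Q=0.3, V2=9.0)
        got = predict_profile(spec_mm, mm, BOLUS, SAMPLE_TIMES, rtol=1e-8)
        assert np.allclose(got.plasma, ref.plasma, rtol=1e-3)


class TestHalfLife:
    def test_one_compartment_closed_form(self):
        spec = StructuralSpec(1, "first_order", "none", "none")
        params = StructuralParams(CL=0.1, V1=10.0)
        assert terminal_half_life(params, spec) == pytest.approx(np.log(2) / 0.01)

    def test_reference_half_life_rounds_to_1_8_h(self):
        t = terminal_half_life(TYPICAL, SPEC_2D) / 60.0
        assert round(t, 1) == 1.8

    def test_q_to_zero_converges_to_one_compartment(self):
        spec1 = StructuralSpec(1, "first_order", "none", "none")
        ref = terminal_half_life(StructuralParams(CL=0.1382, V1=9.25), spec1)
        p = StructuralParams(CL=0.1382, V1=9.25, Q=1e-9, V2=9.49, p_urine=0.54)
        assert terminal_half_life(p, SPEC_2D) == pytest.approx(ref, rel=1e-4)

    def test_saturable_unsupported(self):
        spec = StructuralSpec(2, "michaelis_menten", "none", "none")
        with pytest.raises(ValueError):
            terminal_half_life(StructuralParams(Vmax=1, Km=10, V1=10, Q=0.3, V2=9), spec)


class TestTypicalValue:
    REL_CL = CovariateRelation("CL", "ECLCR_bef", "linear")
    REL_V1 = CovariateRelation("V1", "BWBEF", "power", ref=70.0)

    def test_final_equation_clearance(self):
        p = typical_value({"CL": 0.077}, [(self.REL_CL, 0.0039)],
                          {"ECLCR_bef": 150.0})
        assert p.CL == pytest.approx(0.1382, abs=5e-4)
        assert round(p.CL, 2) == 0.14

    def test_null_effect_returns_theta(self):
        p = typical_value({"CL": 0.077}, [(self.REL_CL, 0.0)], {"ECLCR_bef": 150.0})
        assert p.CL == pytest.approx(0.077)

    def test_reference_weight_returns_theta(self):
        p = typical_value({"V1": 9.25}, [(self.REL_V1, 1.41)], {"BWBEF": 70.0})
        assert p.V1 == pytest.approx(9.25)

    def test_missing_reference_covariate(self):
        with pytest.raises(KeyError):
            typical_value({"CL": 0.077}, [(self.REL_CL, 0.0039)], {})


class TestPropertyInvariants:
    """Hypothesis-drawn structural parameters: the linear-model invariants
    hold across the physiological parameter space, not just at the
    reference values."""

    from hypothesis import given, settings, strategies as st

    params_strategy = st.builds(
        StructuralParams,
        CL=st.floats(0.02, 0.5),
        V1=st.floats(2.0, 40.0),
        Q=st.floats(0.01, 1.0),
        V2=st.floats(2.0, 40.0),
        p_urine=st.floats(0.05, 0.99),
    )

    @given(params=params_strategy, t_rescue=st.floats(10.0, 300.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_superposition_everywhere(self, params, t_rescue):
        d1 = DoseEvent(subject="x", time=0.0, amount=1000.0)
        d2 = DoseEvent(subject="x", time=t_rescue, amount=500.0)
        ts = np.array([5.0, 30.0, 90.0, 200.0, 360.0])
        both = predict_profile(SPEC_2D, params, [d1, d2], ts)
        sep = [predict_profile(SPEC_2D, params, [d], ts) for d in (d1, d2)]
        assert np.allclose(both.plasma, sep[0].plasma + sep[1].plasma,
                           rtol=1e-8, atol=1e-12)

    @given(params=params_strategy)
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_urinary_mass_balance_everywhere(self, params):
        dose = [DoseEvent(subject="x", time=0.0, amount=1000.0)]
        t_half = terminal_half_life(params, SPEC_2D)
        prof = predict_profile(SPEC_2D, params, dose,
                               np.array([min(50.0 * t_half, 5e5)]))
        frac = prof.urine_cumulative_amount[-1] / 1000.0
        assert frac == pytest.approx(params.p_urine, rel=2e-3)
        assert 0.0 <= frac <= 1.0 + 1e-9
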