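import numpy as np
import pytest

from hepaflow.curves import SampledCurve, shift
from hepaflow.kinetics import (
    DegenerateParametersError,
    NewModelParams,
    OneTissueParams,
    RijzewijkParams,
    TaniguchiParams,
    UnstableRecursionWarning,
    blend_blood,
    blood_input,
    derive_quantities,
    simulate_1tcm,
    simulate_new_model,
    simulate_pet,
    simulate_pv_compartment,
    simulate_rijzewijk,
    simulate_taniguchi,
)

from .oracles import (
    at_integer_seconds,
    fine_grid,
    gamma_aif_fine,
    measured_curve_fine,
    oracle_1tcm,
    oracle_new_model,
    oracle_rijzewijk,
    oracle_taniguchi,
    pv_compartment_fine,
    rel_l2,
)


class TestOneTissue:
    def test_zero_flow_gives_zero_tissue(self, aif):
        out = simulate_1tcm(OneTissueParams(f=0.0, k=1.0), aif)
        assert np.all(out.values == 0)

    def test_zero_washout_constant_input_grows_linearly(self):
        c = 600.0
        aif = SampledCurve(np.full(100, c))
        out = simulate_1tcm(OneTissueParams(f=1.2, k=0.0, dt1=0), aif)
        # with k = 0 each step adds f_s * aif(i-1); aif(0) = 0 so the sum
        # lags one sample behind the pure ramp
        i = np.arange(1, 101)
        expected = (1.2 / 60.0) * c * (i - 1)
        assert np.allclose(out.values, expected)

    def test_matches_fine_convolution_oracle(self, aif):
        params = OneTissueParams(f=1.2, k=1.4, V_B=0.0, dt1=10)
        t_fine = fine_grid()
        oracle = at_integer_seconds(oracle_1tcm(params, gamma_aif_fine(t_fine), t_fine))
        got = simulate_1tcm(params, aif).values
        assert rel_l2(got, oracle) < 0.02

    def test_unstable_per_step_rate_warns_but_runs(self, aif):
        with pytest.warns(UnstableRecursionWarning):
            simulate_1tcm(OneTissueParams(f=1.0, k=61.0), aif)


class TestPortalCompartment:
    def test_constant_input_has_unit_dc_gain(self):
        aif = SampledCurve(np.full(2000, 5.0))
        out = simulate_pv_compartment(1.25, 0, aif)
        assert out.values[-1] == pytest.approx(5.0, rel=1e-6)

    def test_finite_impulse_mass_is_preserved(self):
        # f_p = 6/min -> time constant 10 s; 2000 s leaves a < 0.1% tail
        values = np.zeros(2000)
        values[4:10] = 100.0
        out = simulate_pv_compartment(6.0, 0, SampledCurve(values))
        assert out.values.sum() == pytest.approx(values.sum(), rel=0.01)

    def test_very_fast_dispersion_approaches_pure_shift(self, aif):
        out = simulate_pv_compartment(60.0, 4, aif)  # per-second rate = 1
        expected = shift(aif, 5).values  # 4 s delay + the recursion's 1-sample lag
        assert np.allclose(out.values, expected)

    def test_matches_fine_oracle(self, aif):
        t_fine = fine_grid()
        oracle = at_integer_seconds(
            pv_compartment_fine(gamma_aif_fine(t_fine), 1.25, 5, t_fine)
        )
        got = simulate_pv_compartment(1.25, 5, aif).values
        assert rel_l2(got, oracle) < 0.02

    def test_nonpositive_rate_rejected(self, aif):
        with pytest.raises(ValueError):
            simulate_pv_compartment(0.0, 0, aif)


class TestDualInputNesting:
    """The dual-input models must collapse onto the 1TCM exactly."""

    def test_taniguchi_without_shunting_is_double_delayed_1tcm(self, aif):
        p = TaniguchiParams(f_A=0.4, f_p=1.2, E=0.0, k=1.5, dt1=8, dt2=5)
        c_t, _ = simulate_taniguchi(p, aif)
        ref = simulate_1tcm(OneTissueParams(f=0.4, k=1.5, dt1=13), aif)
        assert np.array_equal(c_t.values, ref.values)

    def test_taniguchi_full_shunting_no_dt2_input_composition(self, aif):
        p = TaniguchiParams(f_A=0.4, f_p=1.2, E=1.0, k=1.5, dt1=8, dt2=0)
        c_t, c_pv = simulate_taniguchi(p, aif)
        # rebuild the liver input by hand and rerun the washout recursion
        from hepaflow.kinetics import _decay_recursion, _delayed_input

        u = (0.4 / 60.0) * _delayed_input(aif.values, 8)
        u += (1.2 / 60.0) * _delayed_input(c_pv.values, 0)
        assert np.allclose(c_t.values, _decay_recursion(u, 1.5 / 60.0))

    def test_rijzewijk_zero_delay_equals_taniguchi_zero_delays(self, aif):
        pr = RijzewijkParams(f_A=0.3, f_p=1.1, E=0.8, k=1.4, dt1=0)
        pt = TaniguchiParams(f_A=0.3, f_p=1.1, E=0.8, k=1.4, dt1=0, dt2=0)
        c_r, _ = simulate_rijzewijk(pr, aif)
        c_t, _ = simulate_taniguchi(pt, aif)
        assert np.array_equal(c_r.values, c_t.values)

    def test_rijzewijk_without_shunting_is_undelayed_1tcm(self, aif):
        p = RijzewijkParams(f_A=0.5, f_p=1.0, E=0.0, k=1.2, dt1=20)
        c_t, _ = simulate_rijzewijk(p, aif)
        ref = simulate_1tcm(OneTissueParams(f=0.5, k=1.2, dt1=0), aif)
        assert np.array_equal(c_t.values, ref.values)

    def test_new_model_without_portal_flow_is_1tcm(self, aif):
        pv = simulate_pv_compartment(1.25, 5, aif)
        p = NewModelParams(f_A=0.6, f_P=0.0, k=1.3, dt1=12, dt2=30)
        got = simulate_new_model(p, aif, pv)
        ref = simulate_1tcm(OneTissueParams(f=0.6, k=1.3, dt1=12), aif)
        assert np.array_equal(got.values, ref.values)

    def test_new_model_with_identical_inputs_merges_flows(self, aif):
        p = NewModelParams(f_A=0.4, f_P=0.8, k=1.5, dt1=9, dt2=9)
        got = simulate_new_model(p, aif, aif)
        ref = simulate_1tcm(OneTissueParams(f=1.2, k=1.5, dt1=9), aif)
        assert np.allclose(got.values, ref.values)


class TestFineGridAgreement:
    """Each recursion tracks the continuous system within 2% relative L2."""

    def test_all_models_against_fine_oracles(self, aif, rng):
        t_fine = fine_grid()
        aif_fine = gamma_aif_fine(t_fine)
        pv_meas = simulate_pv_compartment(1.25, 5, aif)
        pv_meas_fine = measured_curve_fine(pv_meas.values, t_fine)
        for _ in range(5):
            f = rng.uniform(0.1, 3.0)
            k = rng.uniform(0.1, 3.0)
            fa = rng.uniform(0.1, 1.0)
            fp = rng.uniform(0.5, 2.5)
            E = rng.uniform(0.5, 1.0)
            d1 = int(rng.integers(0, 41))
            d2 = int(rng.integers(0, 21))

            p1 = OneTissueParams(f=f, k=k, dt1=d1)
            got = simulate_1tcm(p1, aif).values
            assert rel_l2(got, at_integer_seconds(oracle_1tcm(p1, aif_fine, t_fine))) < 0.02

            pt = TaniguchiParams(f_A=fa, f_p=fp, E=E, k=k, dt1=d1, dt2=d2)
            got, _ = simulate_taniguchi(pt, aif)
            ref, _ = oracle_taniguchi(pt, aif_fine, t_fine)
            assert rel_l2(got.values, at_integer_seconds(ref)) < 0.02

            pr = RijzewijkParams(f_A=fa, f_p=fp, E=E, k=k, dt1=d1)
            got, _ = simulate_rijzewijk(pr, aif)
            ref, _ = oracle_rijzewijk(pr, aif_fine, t_fine)
            assert rel_l2(got.values, at_integer_seconds(ref)) < 0.02

            pn = NewModelParams(f_A=fa, f_P=fp, k=k, dt1=d1, dt2=d2)
            got = simulate_new_model(pn, aif, pv_meas).values
            ref = oracle_new_model(pn, aif_fine, pv_meas_fine, t_fine)
            assert rel_l2(got, at_integer_seconds(ref)) < 0.02


class TestLinearityAndPositivity:
    def test_scaling_the_input_scales_every_output(self, aif):
        alpha = 3.7
        scaled = SampledCurve(alpha * aif.values)
        p = NewModelParams(f_A=0.3, f_P=0.9, k=1.6, V_B=0.1, dt1=18, dt2=23)
        pv = simulate_pv_compartment(1.25, 5, aif)
        pv_scaled = simulate_pv_compartment(1.25, 5, scaled)
        assert np.allclose(pv_scaled.values, alpha * pv.values)
        got = simulate_pet(p, scaled, pv_scaled)
        ref = simulate_pet(p, aif, pv)
        assert np.allclose(got.values, alpha * ref.values)

    def test_nonnegative_inputs_give_nonnegative_curves(self, aif):
        pt = TaniguchiParams(f_A=0.4, f_p=1.2, E=0.9, k=2.9, V_B=0.2, dt1=10, dt2=8)
        c_t, c_pv = simulate_taniguchi(pt, aif)
        assert np.all(c_t.values >= 0) and np.all(c_pv.values >= 0)


class TestBloodBlend:
    def test_vb_zero_returns_tissue(self, aif):
        c_t = simulate_1tcm(OneTissueParams(f=1.0, k=1.0), aif)
        out = blend_blood(c_t, aif, 0.0)
        assert np.array_equal(out.values, c_t.values)

    def test_vb_one_returns_blood(self, aif):
        c_t = simulate_1tcm(OneTissueParams(f=1.0, k=1.0), aif)
        out = blend_blood(c_t, aif, 1.0)
        assert np.array_equal(out.values, aif.values)

    def test_equal_flow_weights_give_plain_mean(self):
        c_a = SampledCurve(np.full(50, 2.0))
        c_pv = SampledCurve(np.full(50, 4.0))
        p = NewModelParams(f_A=0.5, f_P=0.5, k=1.0, V_B=0.1)
        blood = blood_input(p, c_a, c_pv)
        assert np.allclose(blood.values, 3.0)
        c_t = SampledCurve(np.full(50, 10.0))
        out = blend_blood(c_t, blood, 0.1)
        assert np.allclose(out.values, 0.9 * 10.0 + 0.3)

    def test_zero_total_flow_is_degenerate(self, aif):
        p = NewModelParams(f_A=0.0, f_P=0.0, k=1.0)
        with pytest.raises(DegenerateParametersError):
            blood_input(p, aif, aif)


class TestDerivedQuantities:
    def test_cohort_mean_arterial_plus_portal_flow(self):
        d = derive_quantities(NewModelParams(f_A=0.299, f_P=0.930, k=1.603))
        assert d.f_total == pytest.approx(1.229)

    def test_equal_flows_give_half_portal_fraction(self):
        d = derive_quantities(NewModelParams(f_A=0.7, f_P=0.7, k=1.0))
        assert d.portal_fraction == pytest.approx(0.5)

    def test_partition_coefficient_is_flow_over_washout(self):
        d = derive_quantities(NewModelParams(f_A=0.4, f_P=0.8, k=1.6))
        assert d.V_T == pytest.approx(0.75)

    def test_shunted_portal_flow_for_dispersed_variants(self):
        p = TaniguchiParams(f_A=0.2, f_p=1.2, E=0.5, k=1.0)
        d = derive_quantities(p)
        assert d.f_total == pytest.approx(0.2 + 0.6)
        assert d.portal_fraction == pytest.approx(0.6 / 0.8)

    def test_1tcm_has_no_portal_fraction(self):
        d = derive_quantities(OneTissueParams(f=0.6, k=0.6))
        assert d.portal_fraction is None
        assert d.f_total == pytest.approx(0.6)

    def test_zero_washout_has_no_partition_coefficient(self):
        with pytest.raises(DegenerateParametersError):
            derive_quantities(OneTissueParams(f=1.0, k=0.0))
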