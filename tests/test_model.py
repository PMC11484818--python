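"""Core pump-leak model: electrochemistry, fluxes, integration, steady state."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dfgaba import (
    IonState,
    ModelParams,
    PhysicalConstants,
    balanced_initial_state,
    gabaa_reversal,
    membrane_voltage,
    nernst_potential,
    reversal_potentials,
    simulate,
    steady_state,
    step,
    transmembrane_fluxes,
    volume_derivative,
)
from dfgaba.model import IntegrationError
from dfgaba.params import ParameterError

# high-precision reference values for the default ionic gradients
E_CL_DEFAULT = -81.05588
E_HCO3_DEFAULT = -31.05266
E_GABAA_DEFAULT = -72.80612


class TestNernst:
    def test_equal_concentrations_zero(self):
        assert nernst_potential(110.0, 110.0, -1) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "c_in, c_out, expected",
        [(5.3, 110.0, E_CL_DEFAULT), (9.7, 31.0, E_HCO3_DEFAULT)],
    )
    def test_default_anion_gradients(self, c_in, c_out, expected):
        assert nernst_potential(c_in, c_out, -1) == pytest.approx(expected, abs=1e-4)

    def test_cation_sign_convention(self):
        # K+ gradient: more K inside than out -> negative reversal
        assert nernst_potential(122.6, 3.5, +1) < -80

    def test_nonpositive_concentration_names_species(self):
        with pytest.raises(ParameterError, match="intracellular"):
            nernst_potential(0.0, 110.0, -1)
        with pytest.raises(ParameterError, match="valence"):
            nernst_potential(1.0, 1.0, 0)


class TestGabaaReversal:
    def test_unity_gradients(self):
        assert gabaa_reversal(110, 110, 31, 31) == pytest.approx(0.0)

    def test_proportional_gradients_collapse_to_nernst(self):
        # both ions share the same in/out ratio -> E_GABAA equals E_Cl
        e = gabaa_reversal(11.0, 110.0, 3.1, 31.0)
        assert e == pytest.approx(nernst_potential(11.0, 110.0, -1), abs=1e-9)

    def test_default_value(self):
        assert gabaa_reversal(5.3, 110.0, 9.7, 31.0) == pytest.approx(
            E_GABAA_DEFAULT, abs=1e-4
        )

    @given(
        cl_i=st.floats(0.5, 60.0),
        hco3_i=st.floats(1.0, 30.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_weighted_reversal_between_ionic_reversals(self, cl_i, hco3_i):
        e_cl = nernst_potential(cl_i, 110.0, -1)
        e_hco3 = nernst_potential(hco3_i, 31.0, -1)
        e_g = gabaa_reversal(cl_i, 110.0, hco3_i, 31.0)
        lo, hi = sorted((e_cl, e_hco3))
        if abs(hi - lo) > 1e-9:
            assert lo < e_g < hi


class TestMembraneVoltage:
    def test_electroneutral_interior_is_zero(self, params):
        state = IonState(Na_i=10, K_i=10, Cl_i=10, HCO3_i=10, X_i=0,
                         Vm=0, w=params.volume_pl)
        assert membrane_voltage(state, params) == pytest.approx(0.0)

    def test_linearity_in_net_charge(self, params):
        s1 = IonState(Na_i=10, K_i=10, Cl_i=10, HCO3_i=9.99, X_i=0,
                      Vm=0, w=params.volume_pl)
        s2 = IonState(Na_i=10, K_i=10, Cl_i=10, HCO3_i=9.98, X_i=0,
                      Vm=0, w=params.volume_pl)
        assert membrane_voltage(s2, params) == pytest.approx(
            2 * membrane_voltage(s1, params)
        )

    def test_resting_state_matches_printed_vm(self, params, resting_state):
        assert membrane_voltage(resting_state, params) == pytest.approx(-67.2, abs=1.5)


class TestFluxes:
    def test_all_zero_configuration(self, params, resting_state):
        p = params.with_overrides(g_Na=0, g_K=0, g_Cl=0, g_HCO3=0, g_KCC2=0, P=0)
        flux = transmembrane_fluxes(resting_state, p)
        for name in ("Na", "K", "Cl", "HCO3", "X"):
            assert getattr(flux, name) == pytest.approx(0.0, abs=1e-30)
        assert flux.total_current == pytest.approx(0.0, abs=1e-30)

    def test_pump_rate_cubic_in_sodium_gradient(self, params, resting_state):
        state = IonState(**{**resting_state.to_dict(), "Na_i": 15.0})
        flux = transmembrane_fluxes(state, params)
        assert flux.pump_current_density == pytest.approx(1.10706e-4, rel=1e-4)

    def test_kcc2_flux_vanishes_when_gradients_match(self, params):
        # choose Cl_i so that E_Cl = E_K exactly
        k_i, k_o = 122.6, params.K_o
        cl_i = params.Cl_o * k_o / k_i
        state = IonState(Na_i=15, K_i=k_i, Cl_i=cl_i, HCO3_i=9.7, X_i=144.4,
                         Vm=-67.2, w=params.volume_pl)
        flux = transmembrane_fluxes(state, params)
        assert flux.kcc2_current_density == pytest.approx(0.0, abs=1e-12)

    def test_x_never_crosses_membrane(self, params, resting_state):
        flux = transmembrane_fluxes(resting_state, params, g_gabaa_now_nS=10.0)
        assert flux.X == 0.0


class TestVolume:
    def test_default_state_is_osmotically_balanced(self, params, resting_state):
        # both sides sum to 297 mM at the published defaults
        assert volume_derivative(resting_state, params) == pytest.approx(0.0, abs=1e-6)

    def test_hypertonic_interior_swells(self, params, resting_state):
        swollen = IonState(**{**resting_state.to_dict(), "K_i": resting_state.K_i + 10})
        assert volume_derivative(swollen, params) > 0

    def test_zero_permeability_freezes_volume(self, params, resting_state):
        p = params.with_overrides(pw=0.0)
        swollen = IonState(**{**resting_state.to_dict(), "K_i": resting_state.K_i + 10})
        assert volume_derivative(swollen, p) == 0.0


class TestStep:
    def test_zero_flux_leaves_state_unchanged(self, params, resting_state):
        p = params.with_overrides(g_Na=0, g_K=0, g_Cl=0, g_HCO3=0, g_KCC2=0,
                                  P=0, pw=0)
        # silence the carbonate reaction at its equilibrium point
        eq = 1e3 * p.h2co3_i_molar / (p.Kr * p.h_i) * 1e3
        state = IonState(**{**resting_state.to_dict(), "HCO3_i": eq})
        new = step(state, p, dt=0.01)
        assert new.t == pytest.approx(state.t + 0.01)
        for name in ("Na_i", "K_i", "Cl_i", "HCO3_i", "w"):
            assert getattr(new, name) == pytest.approx(getattr(state, name), rel=1e-9)

    def test_two_half_steps_agree_with_one_full_step(self, params, resting_state):
        dt = 0.004
        full = step(resting_state, params, dt)
        half = step(step(resting_state, params, dt / 2), params, dt / 2)
        for name in ("Na_i", "K_i", "Cl_i", "HCO3_i", "Vm", "w"):
            assert getattr(half, name) == pytest.approx(getattr(full, name), rel=1e-8)

    def test_rejects_nonpositive_dt(self, params, resting_state):
        with pytest.raises(ParameterError):
            step(resting_state, params, dt=0.0)

    def test_rk4_reference_matches_implicit_integrator(self, params, resting_state):
        """Fixed-step explicit and adaptive implicit schemes agree."""
        state = IonState(**{**resting_state.to_dict(), "Cl_i": resting_state.Cl_i + 1.0,
                            "K_i": resting_state.K_i + 1.0})
        s = state
        for _ in range(500):
            s = step(s, params, dt=0.01)
        res = simulate(params, duration=5.0, initial_state=state, dt_out=1.0)
        fin = res.final_state()
        for name in ("Na_i", "K_i", "Cl_i", "HCO3_i", "Vm"):
            assert getattr(s, name) == pytest.approx(getattr(fin, name), rel=1e-6)


class TestSteadyState:
    def test_matches_published_defaults(self, resting_state):
        assert resting_state.Cl_i == pytest.approx(5.3, abs=0.3)
        assert resting_state.K_i == pytest.approx(122.6, abs=1.5)
        assert resting_state.HCO3_i == pytest.approx(9.7, abs=0.1)
        assert resting_state.Vm == pytest.approx(-67.2, abs=1.5)

    def test_osmotic_balance_at_steady_state(self, params, resting_state):
        assert abs(resting_state.osmolarity - 297.0) < 1e-3

    def test_kcc2_removal_raises_chloride(self, params, resting_state):
        blocked = steady_state(params.with_overrides(g_KCC2=0.0))
        assert blocked.Cl_i > resting_state.Cl_i + 1.0

    def test_chloride_monotone_in_kcc2_conductance(self, params):
        cl = [steady_state(params.with_overrides(g_KCC2=g)).Cl_i for g in (0, 5, 10, 20)]
        assert all(a > b for a, b in zip(cl, cl[1:]))

    def test_voltage_clamped_single_species_obeys_nernst(self, params):
        """With a 10^4-fold capacitance and only a Cl- leak (pump, other
        leaks and the carbonate reaction silenced), chloride relaxes to its
        Nernst equilibrium at the nearly frozen membrane potential."""
        p = params.with_overrides(g_Na=0, g_K=0, g_HCO3=0, g_KCC2=0, P=0,
                                  pw=0, Kf=1e-9, Kr=1e-9, Cm=2e-2)
        state0 = balanced_initial_state(p)
        res = simulate(p, duration=60000.0, initial_state=state0, dt_out=500.0)
        fin = res.final_state()
        expected = p.Cl_o * np.exp(fin.Vm / 26.7267)
        assert fin.Cl_i == pytest.approx(expected, rel=1e-3)


class TestSimulate:
    def test_empty_protocol_from_steady_state_is_flat(self, params, resting_state):
        # mM-precision state round-tripping perturbs the net charge by
        # ~1e-6 mM, which the membrane re-equilibrates as a <0.1 mV blip
        res = simulate(params, duration=600.0, initial_state=resting_state)
        assert np.ptp(res.Vm) < 0.1
        assert np.ptp(res.Vm[len(res.t) // 2 :]) < 1e-3
        assert np.ptp(res.Cl_i) < 0.005
        assert np.all(np.diff(res.t) > 0)

    def test_charge_bookkeeping_consistency(self, params, resting_state):
        """Vm recomputed from concentrations equals the trajectory's Vm."""
        res = simulate(params, duration=60.0, initial_state=resting_state)
        i = len(res.t) // 2
        assert membrane_voltage(res.state_at(i), params) == pytest.approx(
            res.Vm[i], rel=1e-9
        )

    def test_determinism(self, params, resting_state):
        r1 = simulate(params, duration=30.0, initial_state=resting_state)
        r2 = simulate(params, duration=30.0, initial_state=resting_state)
        assert np.array_equal(r1.Vm, r2.Vm)
        assert np.array_equal(r1.Cl_i, r2.Cl_i)

    def test_long_run_drift_below_half_percent(self, params):
        res = simulate(params, duration=3600.0, initial_state=None, dt_out=10.0)
        for name in ("Na_i", "K_i", "Cl_i", "HCO3_i"):
            arr = getattr(res, name)
            assert abs(arr[-1] - arr[0]) / arr[0] < 0.005
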