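"""Three-compartment patient model: mass balances, equilibria, limits."""

import numpy as np
import pytest
from dataclasses import replace

from dialybind.binding import SpeciesVector
from dialybind.params import DrugParams, PatientParams
from dialybind.patient import (
    ExternalExchange,
    PatientState,
    initialize_equilibrated,
    patient_rhs,
    simulate_patient_only,
    total_drug_mass,
)
from dialybind.presets import carbamazepine, phenytoin


def _unbound_tracer(lambda_free=None):
    return DrugParams.from_affinity(
        "tracer", 200.0, "none", 0.0, t_half_total=60.0,
        therapeutic_range=(1.0, 10.0), lambda_free=lambda_free,
    )


class TestInitialization:
    def test_phenytoin_prehd_bound_fraction(self, patient):
        st = initialize_equilibrated(70.0, patient, phenytoin())
        assert st.plasma.frac_bound_T == pytest.approx(0.86, abs=0.01)

    def test_carbamazepine_prehd_bound_fraction(self, patient):
        st = initialize_equilibrated(35.0, patient, carbamazepine())
        assert st.plasma.frac_bound_T == pytest.approx(0.73, abs=0.01)

    def test_zero_drug_gives_all_free_albumin(self, patient):
        st = initialize_equilibrated(0.0, patient, phenytoin())
        assert st.plasma.P_free == patient.albumin_plasma
        assert st.interstitial.P_free == patient.albumin_interstitial
        assert st.plasma.total_T == 0.0 and st.intracellular_T == 0.0

    def test_free_concentration_uniform_across_pools(self, patient):
        st = initialize_equilibrated(70.0, patient, phenytoin())
        assert st.interstitial.T_free == pytest.approx(st.plasma.T_free, rel=1e-12)
        assert st.intracellular_T == pytest.approx(st.plasma.T_free, rel=1e-12)

    def test_requested_plasma_total_is_honoured(self, patient):
        st = initialize_equilibrated(70.0, patient, phenytoin())
        assert st.plasma.total_T * phenytoin().molecular_weight / 1000 == pytest.approx(70.0, rel=1e-10)


class TestRhsStructure:
    def test_global_equilibrium_is_stationary(self, patient):
        drug = phenytoin().with_lambda(0.0)
        st = initialize_equilibrated(70.0, patient, drug)
        dy = patient_rhs(st, None, patient, drug).as_array()
        assert np.abs(dy).max() < 1e-8

    def test_protein_species_have_no_intercompartment_exchange(self, patient):
        # perturb only the PT gradient between plasma and interstitium; with
        # reactions suppressed the complex concentration must not move
        drug = _unbound_tracer(0.0)
        pl = np.array([0.0, 0.0, 0.0, 10.0, 0.0])
        is_ = np.array([0.0, 0.0, 0.0, 2.0, 0.0])
        st = PatientState(
            plasma=SpeciesVector.from_array(pl),
            interstitial=SpeciesVector.from_array(is_),
            intracellular_T=0.0,
            intracellular_D=0.0,
        )
        dy = patient_rhs(st, None, patient, drug)
        assert dy.plasma.PT == 0.0 and dy.interstitial.PT == 0.0

    def test_exchange_term_applies_to_all_species(self, patient):
        drug = phenytoin().with_lambda(0.0)
        st = initialize_equilibrated(70.0, patient, drug)
        c_out = st.plasma.as_array() * 0.9
        dy = patient_rhs(st, ExternalExchange(Q_pl=162.5, C_out=c_out), patient, drug)
        # equilibrated otherwise, so the derivative is purely the exchange term
        expected = 162.5 * (c_out - st.plasma.as_array()) / patient.v_pl_ml
        np.testing.assert_allclose(dy.plasma.as_array(), expected, rtol=1e-6, atol=1e-12)

    def test_total_mass_derivative_is_elimination_only(self, patient):
        drug = phenytoin().with_lambda(0.01)
        st = initialize_equilibrated(70.0, patient, drug)
        dy = patient_rhs(st, None, patient, drug)
        d_mass = (
            patient.v_pl_ml * (dy.plasma.T_free + dy.plasma.PT)
            + patient.v_is_ml * (dy.interstitial.T_free + dy.interstitial.PT)
            + patient.v_ic_ml * dy.intracellular_T
        )
        assert d_mass == pytest.approx(-0.01 * st.plasma.T_free * patient.v_pl_ml, rel=1e-9)


class TestSimulation:
    def test_mass_conserved_without_elimination(self, patient):
        drug = phenytoin().with_lambda(0.0)
        st0 = initialize_equilibrated(70.0, patient, drug)
        # start away from equilibrium to exercise the exchange terms
        st0 = PatientState(
            plasma=st0.plasma,
            interstitial=st0.interstitial,
            intracellular_T=0.0,
            intracellular_D=0.0,
        )
        _, st1, _ = simulate_patient_only(st0, 600.0, patient, drug)
        m0 = total_drug_mass(st0.as_array(), patient)
        m1 = total_drug_mass(st1.as_array(), patient)
        assert m1[0] == pytest.approx(m0[0], rel=1e-8)

    def test_albumin_totals_constant_per_pool(self, patient):
        drug = phenytoin().with_lambda(0.01)
        st0 = initialize_equilibrated(70.0, patient, drug)
        _, st1, _ = simulate_patient_only(st0, 600.0, patient, drug)
        assert st1.plasma.total_P == pytest.approx(patient.albumin_plasma, rel=1e-9)
        assert st1.interstitial.total_P == pytest.approx(patient.albumin_interstitial, rel=1e-9)

    def test_plasma_total_decreases_monotonically_with_elimination(self, patient):
        drug = phenytoin().with_lambda(0.012)
        st0 = initialize_equilibrated(70.0, patient, drug)
        frame, _, _ = simulate_patient_only(st0, 300.0, patient, drug)
        diffs = np.diff(frame["plasma_total_T_mgL"].to_numpy())
        assert (diffs < 0).all()

    def test_fast_exchange_unbound_limit_is_monoexponential(self):
        # with K_ip, K_ic scaled far up, the three pools collapse into one of
        # combined volume and decay at rate λ·V_pl/V_total
        fast = PatientParams(K_ip=120000.0, K_ic=10000.0)
        lam = 0.02
        drug = _unbound_tracer(lam)
        st0 = initialize_equilibrated(10.0, fast, drug)
        frame, _, _ = simulate_patient_only(st0, 400.0, fast, drug)
        v_tot = fast.V_pl + fast.V_is + fast.V_ic
        expected = 10.0 * np.exp(-lam * fast.V_pl / v_tot * frame["time_min"].to_numpy())
        np.testing.assert_allclose(
            frame["plasma_total_T_mgL"].to_numpy(), expected, rtol=5e-3
        )

    def test_negative_initial_concentration_rejected(self, patient):
        with pytest.raises(ValueError):
            initialize_equilibrated(-1.0, patient, phenytoin())
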