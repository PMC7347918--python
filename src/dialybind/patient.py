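"""Three-compartment patient model.

Plasma and interstitium each hold all five binding species; the intracellular
pool holds free drug only (no intracellular albumin).  Free solutes exchange
between plasma and interstitium (coefficient K_ip) and between interstitium
and cells (K_ic); protein and complexes stay inside their extracellular pool.
Endogenous elimination is first-order on *free plasma* drug only, with rate
``lambda_free`` per drug.  Compartment volumes are constant (no ultrafiltration
from the patient; infused diluent is removed along the dialyzer instead).

State vector layout (concentrations, µM; amounts, nmol):

    y[0:5]   plasma    (T, D, P, PT, PD)
    y[5:10]  interstitial (same order)
    y[10]    intracellular free T
    y[11]    intracellular free D
    y[12]    cumulative endogenously eliminated T, nmol
    y[13]    cumulative endogenously eliminated D, nmol
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import binding
from .binding import BindingKinetics, SpeciesVector, reaction_rates
from .params import DrugParams, PatientParams, uM_to_mgL

__all__ = [
    "PatientState",
    "ExternalExchange",
    "N_PATIENT",
    "patient_rhs",
    "patient_rates",
    "initialize_equilibrated",
    "simulate_patient_only",
    "total_drug_mass",
]

N_PATIENT = 14
PL = slice(0, 5)
IS = slice(5, 10)
IC_T, IC_D = 10, 11
CUM_T, CUM_D = 12, 13

_FREE = np.array([1.0, 1.0, 0.0, 0.0, 0.0])  # (1 − ∅_C): free drugs exchange/eliminate


@dataclass(frozen=True)
class PatientState:
    """Structured view of the 14-element patient state vector."""

    plasma: SpeciesVector
    interstitial: SpeciesVector
    intracellular_T: float
    intracellular_D: float
    eliminated_T_nmol: float = 0.0
    eliminated_D_nmol: float = 0.0

    def as_array(self) -> np.ndarray:
        y = np.empty(N_PATIENT)
        y[PL] = self.plasma.as_array()
        y[IS] = self.interstitial.as_array()
        y[IC_T] = self.intracellular_T
        y[IC_D] = self.intracellular_D
        y[CUM_T] = self.eliminated_T_nmol
        y[CUM_D] = self.eliminated_D_nmol
        return y

    @classmethod
    def from_array(cls, y) -> "PatientState":
        return cls(
            plasma=SpeciesVector.from_array(y[PL]),
            interstitial=SpeciesVector.from_array(y[IS]),
            intracellular_T=float(y[IC_T]),
            intracellular_D=float(y[IC_D]),
            eliminated_T_nmol=float(y[CUM_T]),
            eliminated_D_nmol=float(y[CUM_D]),
        )


@dataclass(frozen=True)
class ExternalExchange:
    """Extracorporeal exchange seen by the plasma pool.

    When active, plasma loses ``Q_pl · C_pl`` and regains ``Q_pl · C_out``
    (post-dialyzer return) for every species, free and protein-bound alike.
    """

    Q_pl: float
    C_out: np.ndarray  # (5,) µM
    active: bool = True


def _lambda_vec(toxic: DrugParams, competitor: Optional[DrugParams]) -> np.ndarray:
    lam = np.zeros(5)
    lam[binding.T] = toxic.lambda_free or 0.0
    if competitor is not None:
        lam[binding.D] = competitor.lambda_free or 0.0
    return lam


def patient_rates(
    y: np.ndarray,
    patient: PatientParams,
    kin: BindingKinetics,
    lam: np.ndarray,
) -> np.ndarray:
    """Time derivative of the patient state without extracorporeal exchange."""
    pl = y[PL]
    is_ = y[IS]
    dy = np.empty(N_PATIENT)

    v_pl, v_is, v_ic = patient.v_pl_ml, patient.v_is_ml, patient.v_ic_ml
    kip, kic = patient.K_ip, patient.K_ic

    r_pl = reaction_rates(pl, kin)
    r_is = reaction_rates(is_, kin)

    ic5 = np.zeros(5)
    ic5[binding.T] = y[IC_T]
    ic5[binding.D] = y[IC_D]

    dy[PL] = _FREE * kip * (is_ - pl) / v_pl + r_pl - _FREE * lam * pl
    dy[IS] = (-_FREE * kip * (is_ - pl) + _FREE * kic * (ic5 - is_)) / v_is + r_is
    dy[IC_T] = -kic * (y[IC_T] - is_[binding.T]) / v_ic
    dy[IC_D] = -kic * (y[IC_D] - is_[binding.D]) / v_ic
    dy[CUM_T] = lam[binding.T] * pl[binding.T] * v_pl
    dy[CUM_D] = lam[binding.D] * pl[binding.D] * v_pl
    return dy


def patient_rhs(
    state: PatientState,
    exchange: Optional[ExternalExchange],
    patient: PatientParams,
    toxic: DrugParams,
    competitor: Optional[DrugParams] = None,
) -> PatientState:
    """Right-hand side of the patient mass balances, returned in state form."""
    y = state.as_array()
    kin = BindingKinetics.from_drugs(toxic, competitor)
    dy = patient_rates(y, patient, kin, _lambda_vec(toxic, competitor))
    if exchange is not None and exchange.active:
        dy[PL] += exchange.Q_pl * (np.asarray(exchange.C_out) - y[PL]) / patient.v_pl_ml
    return PatientState.from_array(dy)


def initialize_equilibrated(
    total_plasma_toxic_mgL: float,
    patient: PatientParams,
    toxic: DrugParams,
    competitor: Optional[DrugParams] = None,
    total_plasma_competitor_mgL: float = 0.0,
) -> PatientState:
    """Patient state at peak concentration, fully equilibrated.

    Free drug concentrations are equal across the three pools; plasma and
    interstitium are each at binding equilibrium with their own albumin; the
    plasma *total* equals the requested serum concentration.
    """
    if total_plasma_toxic_mgL < 0 or total_plasma_competitor_mgL < 0:
        raise ValueError("initial concentrations must be non-negative")
    t_tot = 1000.0 * total_plasma_toxic_mgL / toxic.molecular_weight
    d_tot = (
        1000.0 * total_plasma_competitor_mgL / competitor.molecular_weight
        if competitor is not None and total_plasma_competitor_mgL > 0
        else 0.0
    )
    k_d = competitor.K_A if competitor is not None else 0.0
    pl = binding.equilibrate_competitive(t_tot, d_tot, patient.albumin_plasma, toxic.K_A, k_d)

    # interstitium: same free concentrations, own albumin at equilibrium
    kt = toxic.K_A * 1e-6
    kd = k_d * 1e-6
    p_free_is = patient.albumin_interstitial / (1.0 + kt * pl.T_free + kd * pl.D_free)
    is_ = SpeciesVector(
        T_free=pl.T_free,
        D_free=pl.D_free,
        P_free=p_free_is,
        PT=kt * pl.T_free * p_free_is,
        PD=kd * pl.D_free * p_free_is,
    )
    return PatientState(
        plasma=pl,
        interstitial=is_,
        intracellular_T=pl.T_free,
        intracellular_D=pl.D_free,
    )


def total_drug_mass(y: np.ndarray, patient: PatientParams) -> tuple[float, float, float]:
    """Total (T, D, albumin) amounts in the patient, nmol, excluding cumulatives."""
    v = np.array([patient.v_pl_ml, patient.v_is_ml])
    pools = np.stack([y[PL], y[IS]])  # (2, 5)
    t = float(v @ (pools[:, binding.T] + pools[:, binding.PT]) + patient.v_ic_ml * y[IC_T])
    d = float(v @ (pools[:, binding.D] + pools[:, binding.PD]) + patient.v_ic_ml * y[IC_D])
    alb = float(v @ (pools[:, binding.P] + pools[:, binding.PT] + pools[:, binding.PD]))
    return t, d, alb


def _timecourse_frame(
    t: np.ndarray, ys: np.ndarray, patient: PatientParams, toxic: DrugParams,
    competitor: Optional[DrugParams],
) -> pd.DataFrame:
    cols = {
        "time_min": t,
        "plasma_total_T_uM": ys[binding.T] + ys[binding.PT],
        "plasma_free_T_uM": ys[binding.T],
        "interstitial_free_T_uM": ys[5 + binding.T],
        "intracellular_T_uM": ys[IC_T],
        "eliminated_T_nmol": ys[CUM_T],
    }
    cols["plasma_total_T_mgL"] = uM_to_mgL(cols["plasma_total_T_uM"], toxic.molecular_weight)
    cols["plasma_free_T_mgL"] = uM_to_mgL(cols["plasma_free_T_uM"], toxic.molecular_weight)
    if competitor is not None:
        cols["plasma_total_D_uM"] = ys[binding.D] + ys[binding.PD]
        cols["plasma_free_D_uM"] = ys[binding.D]
        cols["plasma_total_D_mgL"] = uM_to_mgL(cols["plasma_total_D_uM"], competitor.molecular_weight)
        cols["eliminated_D_nmol"] = ys[CUM_D]
    return pd.DataFrame(cols)


def simulate_patient_only(
    state0: PatientState,
    duration: float,
    patient: PatientParams,
    toxic: DrugParams,
    competitor: Optional[DrugParams] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    events=None,
    sample_min: float = 1.0,
):
    """Integrate the patient alone (no dialysis) for ``duration`` minutes.

    Returns ``(timecourse DataFrame, final PatientState, OdeResult)``.  The
    binding kinetics (k_on·P ≈ 6.5e4 min⁻¹) make the system stiff; BDF with
    tight tolerances keeps states non-negative without clipping.
    """
    kin = BindingKinetics.from_drugs(toxic, competitor)
    lam = _lambda_vec(toxic, competitor)

    def rhs(t, y):
        return patient_rates(y, patient, kin, lam)

    n = max(2, int(np.floor(duration / sample_min)) + 1)
    t_eval = np.linspace(0.0, duration, n)
    sol = solve_ivp(
        rhs,
        (0.0, duration),
        state0.as_array(),
        method="BDF",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        events=events,
        dense_output=events is not None,
    )
    if not sol.success:
        raise RuntimeError(f"patient ODE solver failed: {sol.message}")
    if sol.y.size and sol.y[:12].min() < -1e-6:
        raise ArithmeticError(
            f"negative concentration {sol.y[:12].min():.3e} µM in patient simulation"
        )
    y_end = sol.y[:, -1] if sol.y.size else state0.as_array()
    frame = _timecourse_frame(sol.t, sol.y, patient, toxic, competitor)
    return frame, PatientState.from_array(y_end), sol
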