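"""Closed-loop hemodialysis session simulator.

Couples the three-compartment patient, the arterial tube segment (with
optional competitor infusion) and the counter-current dialyzer into one
stiff ODE system solved by BDF with a sparse finite-difference Jacobian.
Plasma leaves the patient at Q_pl, is mixed with the infusate, traverses the
tube and the dialyzer blood side, and the dialyzer outlet stream returns to
the patient plasma pool.  The infused diluent volume is ultrafiltered along
the fiber, so the patient's compartment volumes stay constant.

Cumulative bookkeeping states (dialysate outflow per species, endogenous
elimination, infused competitor) make total solute a *linear invariant* of
the right-hand side, which BDF preserves to solver precision — the basis of
the per-run mass audit.

State vector (length 12 + 5·n_tube + 10·n_dz + 8):

    [0:12]      patient (plasma 5, interstitial 5, intracellular T, D)
    [12:12+5nt] tube cells (5 species per cell, cell-major)
    then per dialyzer cell: 5 plasma species, 5 dialysate species
    tail: removed-to-dialysate per species (5, nmol),
          eliminated T, eliminated D (nmol), infused D (nmol)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from . import binding
from .binding import BindingKinetics, N_SPECIES
from .extracorporeal import (
    DEFAULT_N_DZ,
    DEFAULT_N_TUBE,
    FlowProfile,
    dialyzer_rhs,
    tube_inlet_mixing,
    tube_rhs,
)
from .params import Scenario, raise_if_invalid, uM_to_mgL
from .patient import (
    N_PATIENT,
    PatientState,
    _lambda_vec,
    initialize_equilibrated,
    patient_rates,
    simulate_patient_only,
    total_drug_mass,
)

__all__ = [
    "SessionRun",
    "SessionResult",
    "SessionAuditError",
    "simulate_session",
    "rebound_trajectory",
    "find_min_duration",
    "sweep_competitor_half_life",
    "sweep_toxicity",
    "mass_audit",
]

_N_TAIL = 8  # removed[5], elim_T, elim_D, infused_D


class SessionAuditError(ArithmeticError):
    """A conservation or free-concentration invariant failed during a run."""


@dataclass(frozen=True)
class SessionRun:
    """Outcome of one fixed-duration session plus its rebound follow-up."""

    scenario: Scenario
    duration: float                     # min
    timecourse: pd.DataFrame
    rebound: pd.DataFrame
    end_state: PatientState
    end_total_mgL: float                # total plasma toxin at session end
    rebound_peak_mgL: float             # max total plasma toxin after HD
    removed_dialysate_mg: dict          # per drug name, mg in spent dialysate
    eliminated_endogenous_mg: dict      # per drug name, mg
    circuit_holdup_mg: dict             # per drug name, mg left in the circuit
    mass_residual: float                # worst relative mass-balance residual
    max_free_ratio: float               # max free plasma toxin / its t=0 value


@dataclass(frozen=True)
class SessionResult:
    """Result of the minimal-duration search."""

    run: SessionRun
    min_duration: Optional[float]       # min; None if censored at max_duration
    censored: bool

    @property
    def timecourse(self) -> pd.DataFrame:
        return self.run.timecourse

    @property
    def rebound_peak_mgL(self) -> float:
        return self.run.rebound_peak_mgL

    @property
    def mass_residual(self) -> float:
        return self.run.mass_residual


def _state_size(n_tube: int, n_dz: int) -> int:
    return 12 + 5 * n_tube + 10 * n_dz + _N_TAIL


class _SessionContext:
    """Precomputed arrays and index bookkeeping for the coupled RHS."""

    def __init__(self, scenario: Scenario, duration: float, n_tube: int, n_dz: int):
        self.scenario = scenario
        self.n_tube = n_tube
        self.n_dz = n_dz
        patient = scenario.patient
        sess = scenario.session
        self.kin = BindingKinetics.from_drugs(scenario.toxic, scenario.competitor)
        self.lam = _lambda_vec(scenario.toxic, scenario.competitor)
        self.Q_pl = sess.q_plasma(patient.hematocrit)
        inf = sess.infusion
        self.Q_D = inf.rate_for_duration(duration) if inf is not None else 0.0
        self.c_inf = inf.concentration_uM if inf is not None else 0.0
        self.flows = FlowProfile.build(self.Q_pl, self.Q_D, sess.Q_dialysate, n_dz)
        self.tube_params = scenario.tube
        self.dz = scenario.dialyzer
        self.v_pl = patient.v_pl_ml
        # index helpers
        self.i_tube = 12
        self.i_dz = 12 + 5 * n_tube
        self.i_tail = self.i_dz + 10 * n_dz
        self.n = self.i_tail + _N_TAIL
        self._dz_shape = (n_dz, 2, N_SPECIES)

    def unpack(self, y: np.ndarray):
        tube = y[self.i_tube : self.i_dz].reshape(self.n_tube, N_SPECIES).T
        dz = y[self.i_dz : self.i_tail].reshape(self._dz_shape)
        c_p = dz[:, 0, :].T  # (5, n_dz)
        c_d = dz[:, 1, :].T
        return tube, c_p, c_d

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        sc = self.scenario
        patient = sc.patient
        dy = np.empty_like(y)

        tube, c_p, c_d = self.unpack(y)
        pl = y[0:5]

        # patient without extracorporeal exchange
        dy[:N_PATIENT - 2] = patient_rates(
            np.concatenate([y[:12], [0.0, 0.0]]), patient, self.kin, self.lam
        )[: N_PATIENT - 2]

        # tube: inlet mixing then upwind advection + reaction
        inlet = tube_inlet_mixing(pl, self.Q_pl, self.Q_D, self.c_inf)
        d_tube = tube_rhs(tube, inlet, self.flows.Q_tube, self.tube_params, self.kin)

        # dialyzer, fed by the tube outlet
        d_cp, d_cd = dialyzer_rhs(c_p, c_d, tube[:, -1], self.flows, self.dz, self.kin)

        # plasma return from the dialyzer outlet closes the loop
        c_out = c_p[:, -1]
        dy[0:5] += self.Q_pl * (c_out - pl) / self.v_pl

        dy[self.i_tube : self.i_dz] = d_tube.T.ravel()
        ddz = np.empty(self._dz_shape)
        ddz[:, 0, :] = d_cp.T
        ddz[:, 1, :] = d_cd.T
        dy[self.i_dz : self.i_tail] = ddz.ravel()

        # bookkeeping: spent-dialysate outflow, elimination, infusion
        tail = self.i_tail
        dy[tail : tail + 5] = self.flows.q_d[0] * c_d[:, 0]
        dy[tail + 5] = self.lam[binding.T] * pl[binding.T] * self.v_pl
        dy[tail + 6] = self.lam[binding.D] * pl[binding.D] * self.v_pl
        dy[tail + 7] = self.Q_D * self.c_inf
        return dy

    def sparsity(self) -> lil_matrix:
        """Jacobian sparsity pattern for grouped finite differences."""
        n = self.n
        s = lil_matrix((n, n), dtype=np.int8)
        blk = np.ones((5, 5), dtype=np.int8)
        # patient: plasma/interstitial/intracellular mutual coupling
        s[0:12, 0:12] = 1
        # plasma gains from dialyzer outlet plasma cell
        last_p = self.i_dz + 10 * (self.n_dz - 1)
        s[0:5, last_p : last_p + 5] = 1
        # tube cells
        for j in range(self.n_tube):
            b = self.i_tube + 5 * j
            s[b : b + 5, b : b + 5] = blk
            if j == 0:
                s[b : b + 5, 0:5] = blk  # inlet mixing from patient plasma
            else:
                s[b : b + 5, b - 5 : b] = blk
        # dialyzer cells: 10-block self-coupling, plasma upstream, dialysate upstream
        for i in range(self.n_dz):
            b = self.i_dz + 10 * i
            s[b : b + 10, b : b + 10] = 1
            if i == 0:
                tlast = self.i_tube + 5 * (self.n_tube - 1)
                s[b : b + 5, tlast : tlast + 5] = blk
            else:
                s[b : b + 5, b - 10 : b - 5] = blk
            if i < self.n_dz - 1:
                s[b + 5 : b + 10, b + 15 : b + 20] = blk
        # cumulative rows
        tail = self.i_tail
        first_d = self.i_dz + 5
        s[tail : tail + 5, first_d : first_d + 5] = blk  # dialysate cell 0 outflow
        s[tail + 5, binding.T] = 1
        s[tail + 6, binding.D] = 1
        return s


def _totals_everywhere(ctx: _SessionContext, y: np.ndarray) -> tuple[float, float, float]:
    """Total T, D and albumin amounts (nmol) in patient plus circuit."""
    sc = ctx.scenario
    t_pat, d_pat, p_pat = total_drug_mass(
        np.concatenate([y[:12], [0.0, 0.0]]), sc.patient
    )
    tube, c_p, c_d = ctx.unpack(y)
    v_t = ctx.tube_params.volume_ml / ctx.n_tube
    v_p = ctx.dz.plasma_volume_ml / ctx.n_dz
    v_d = ctx.dz.dialysate_volume_ml / ctx.n_dz

    def field_tot(idx_free, idx_bound):
        return (
            v_t * (tube[idx_free].sum() + tube[idx_bound].sum())
            + v_p * (c_p[idx_free].sum() + c_p[idx_bound].sum())
            + v_d * (c_d[idx_free].sum() + c_d[idx_bound].sum())
        )

    t_tot = t_pat + field_tot(binding.T, binding.PT)
    d_tot = d_pat + field_tot(binding.D, binding.PD)
    p_tot = p_pat + sum(
        v * (f[binding.P].sum() + f[binding.PT].sum() + f[binding.PD].sum())
        for v, f in ((v_t, tube), (v_p, c_p), (v_d, c_d))
    )
    return t_tot, d_tot, p_tot


def _circuit_holdup(ctx, y) -> tuple[float, float]:
    t_all, d_all, _ = _totals_everywhere(ctx, y)
    t_pat, d_pat, _ = total_drug_mass(np.concatenate([y[:12], [0.0, 0.0]]), ctx.scenario.patient)
    return t_all - t_pat, d_all - d_pat


def mass_audit(ctx: _SessionContext, y0: np.ndarray, y_end: np.ndarray) -> float:
    """Worst relative mass-balance residual over toxin, competitor and albumin."""
    tail = ctx.i_tail
    t0, d0, p0 = _totals_everywhere(ctx, y0)
    t1, d1, p1 = _totals_everywhere(ctx, y_end)
    rem = y_end[tail : tail + 5]
    rem_t = rem[binding.T] + rem[binding.PT]
    rem_d = rem[binding.D] + rem[binding.PD]
    rem_p = rem[binding.P] + rem[binding.PT] + rem[binding.PD]
    infused = y_end[tail + 7]

    res_t = abs(t0 - (t1 + rem_t + y_end[tail + 5])) / max(t0, 1e-300)
    res_p = abs(p0 - (p1 + rem_p)) / max(p0, 1e-300)
    residuals = [res_t, res_p]
    d_in = d0 + infused
    if d_in > 0:
        residuals.append(abs(d_in - (d1 + rem_d + y_end[tail + 6])) / d_in)
    return max(residuals)


def _nmol_to_mg(nmol: float, mw: float) -> float:
    return nmol * mw * 1e-6


def _session_frame(ctx: _SessionContext, t: np.ndarray, ys: np.ndarray) -> pd.DataFrame:
    sc = ctx.scenario
    mw_t = sc.toxic.molecular_weight
    tail = ctx.i_tail
    cols = {
        "time_min": t,
        "plasma_total_T_uM": ys[binding.T] + ys[binding.PT],
        "plasma_free_T_uM": ys[binding.T],
        "interstitial_free_T_uM": ys[5 + binding.T],
        "intracellular_T_uM": ys[10],
        "removed_T_mg": _nmol_to_mg(ys[tail + binding.T] + ys[tail + binding.PT], mw_t),
        "eliminated_T_mg": _nmol_to_mg(ys[tail + 5], mw_t),
    }
    cols["plasma_total_T_mgL"] = uM_to_mgL(cols["plasma_total_T_uM"], mw_t)
    cols["plasma_free_T_mgL"] = uM_to_mgL(cols["plasma_free_T_uM"], mw_t)
    comp = sc.competitor
    if comp is not None:
        mw_d = comp.molecular_weight
        cols["plasma_total_D_uM"] = ys[binding.D] + ys[binding.PD]
        cols["plasma_free_D_uM"] = ys[binding.D]
        cols["plasma_total_D_mgL"] = uM_to_mgL(cols["plasma_total_D_uM"], mw_d)
        cols["removed_D_mg"] = _nmol_to_mg(ys[tail + binding.D] + ys[tail + binding.PD], mw_d)
        cols["eliminated_D_mg"] = _nmol_to_mg(ys[tail + 6], mw_d)
        cols["infused_D_mg"] = _nmol_to_mg(ys[tail + 7], mw_d)
    return pd.DataFrame(cols)


def simulate_session(
    scenario: Scenario,
    duration: float,
    n_tube: int = DEFAULT_N_TUBE,
    n_dz: int = DEFAULT_N_DZ,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    rebound: bool = True,
    validate: bool = True,
) -> SessionRun:
    """Run one HD session of ``duration`` minutes and its rebound follow-up.

    The extracorporeal fields start empty (the circuit is primed with
    drug-free fluid); the patient starts equilibrated at the scenario's
    initial toxin concentration.  Raises :class:`SessionAuditError` if the
    mass audit exceeds 1e−6 or, when a competitor is infused, if free plasma
    toxin rises above its initial value.
    """
    if validate:
        raise_if_invalid(scenario, require_lambda=True)
    if duration <= 0:
        raise ValueError("duration must be positive")
    ctx = _SessionContext(scenario, duration, n_tube, n_dz)

    y0 = np.zeros(ctx.n)
    y0[:12] = initialize_equilibrated(
        scenario.initial_toxic_mgL, scenario.patient, scenario.toxic, scenario.competitor
    ).as_array()[:12]

    t_eval = np.linspace(0.0, duration, int(round(duration)) + 1)
    sol = solve_ivp(
        ctx.rhs,
        (0.0, duration),
        y0,
        method="BDF",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        jac_sparsity=ctx.sparsity(),
    )
    if not sol.success:
        raise RuntimeError(f"session ODE solver failed: {sol.message}")
    conc = sol.y[: ctx.i_tail]
    if conc.min() < -1e-6:
        raise SessionAuditError(
            f"negative concentration {conc.min():.3e} µM in session fields"
        )

    y_end = sol.y[:, -1]
    residual = mass_audit(ctx, y0, y_end)
    if residual > 1e-6:
        raise SessionAuditError(f"mass audit residual {residual:.3e} exceeds 1e-6")

    free0 = y0[binding.T]
    max_free_ratio = float(sol.y[binding.T].max() / free0) if free0 > 0 else 0.0
    if scenario.session.infusion is not None and max_free_ratio > 1.0 + 1e-6:
        raise SessionAuditError(
            f"free plasma toxin rose to {max_free_ratio:.6f}× its initial value "
            "during competitor infusion"
        )

    frame = _session_frame(ctx, sol.t, sol.y)
    end_patient = PatientState.from_array(np.concatenate([y_end[:12], [0.0, 0.0]]))
    end_total = uM_to_mgL(
        y_end[binding.T] + y_end[binding.PT], scenario.toxic.molecular_weight
    )

    if rebound:
        reb_frame, reb_peak = rebound_trajectory(
            end_patient, scenario.session.rebound_horizon, scenario.patient,
            scenario.toxic, scenario.competitor,
        )
    else:
        reb_frame, reb_peak = pd.DataFrame(), end_total

    tail = ctx.i_tail
    mw_t = scenario.toxic.molecular_weight
    holdup_t, holdup_d = _circuit_holdup(ctx, y_end)
    removed = {
        scenario.toxic.name: _nmol_to_mg(y_end[tail + binding.T] + y_end[tail + binding.PT], mw_t)
    }
    eliminated = {scenario.toxic.name: _nmol_to_mg(y_end[tail + 5], mw_t)}
    holdup = {scenario.toxic.name: _nmol_to_mg(holdup_t, mw_t)}
    comp = scenario.competitor
    if comp is not None:
        mw_d = comp.molecular_weight
        removed[comp.name] = _nmol_to_mg(
            y_end[tail + binding.D] + y_end[tail + binding.PD], mw_d
        )
        eliminated[comp.name] = _nmol_to_mg(y_end[tail + 6], mw_d)
        holdup[comp.name] = _nmol_to_mg(holdup_d, mw_d)

    return SessionRun(
        scenario=scenario,
        duration=duration,
        timecourse=frame,
        rebound=reb_frame,
        end_state=end_patient,
        end_total_mgL=float(end_total),
        rebound_peak_mgL=float(reb_peak),
        removed_dialysate_mg=removed,
        eliminated_endogenous_mg=eliminated,
        circuit_holdup_mg=holdup,
        mass_residual=float(residual),
        max_free_ratio=max_free_ratio,
    )


def rebound_trajectory(
    end_state: PatientState,
    horizon: float,
    patient,
    toxic,
    competitor=None,
) -> tuple[pd.DataFrame, float]:
    """Post-dialytic redistribution: patient-only follow-up after the session.

    Returns the trajectory and the maximum total plasma toxin concentration
    (mg/L) reached over the horizon; drug returning from the interstitial and
    intracellular pools can transiently raise plasma levels (rebound).
    """
    frame, _, _ = simulate_patient_only(end_state, horizon, patient, toxic, competitor)
    return frame, float(frame["plasma_total_T_mgL"].max())


def _feasible(run: SessionRun, mtc: float, tol: float = 1e-9) -> bool:
    return run.end_total_mgL <= mtc + tol and run.rebound_peak_mgL <= mtc + tol


def find_min_duration(
    scenario: Scenario,
    step: float = 5.0,
    n_tube: int = DEFAULT_N_TUBE,
    n_dz: int = DEFAULT_N_DZ,
    rtol: float = 1e-6,
    lower: Optional[float] = None,
    upper: Optional[float] = None,
) -> SessionResult:
    """Smallest session duration (on a ``step``-minute grid) that detoxifies.

    A duration is acceptable when both the end-of-session and the post-
    dialytic rebound peak total plasma concentrations are at or below the
    toxin's maximum therapeutic concentration.  Acceptability is monotone in
    duration (longer sessions remove more drug and deliver the same total
    competitor dose), so a bisection on the grid is exact.  If even
    ``max_duration`` fails, the result is censored rather than an error.
    """
    raise_if_invalid(scenario, require_lambda=True)
    mtc = scenario.toxic.therapeutic_range[1]
    max_dur = upper if upper is not None else scenario.session.max_duration

    runs: dict[int, SessionRun] = {}

    def run_at(k: int) -> SessionRun:
        if k not in runs:
            runs[k] = simulate_session(
                scenario, k * step, n_tube=n_tube, n_dz=n_dz, rtol=rtol, validate=False
            )
        return runs[k]

    k_hi = int(math.floor(max_dur / step))
    if k_hi < 1:
        raise ValueError("max_duration shorter than one step")
    if not _feasible(run_at(k_hi), mtc):
        return SessionResult(run=run_at(k_hi), min_duration=None, censored=True)
    k_lo = 0  # sentinel: duration 0 is never acceptable for a toxic start
    if lower is not None:
        k = int(math.floor(lower / step))
        if 1 <= k < k_hi and not _feasible(run_at(k), mtc):
            k_lo = k
    while k_hi - k_lo > 1:
        k_mid = (k_hi + k_lo) // 2
        if _feasible(run_at(k_mid), mtc):
            k_hi = k_mid
        else:
            k_lo = k_mid
    return SessionResult(run=run_at(k_hi), min_duration=k_hi * step, censored=False)


def sweep_competitor_half_life(
    scenario: Scenario,
    half_lives_min: list[float],
    step: float = 5.0,
    n_tube: int = DEFAULT_N_TUBE,
    n_dz: int = DEFAULT_N_DZ,
    rtol: float = 1e-6,
) -> pd.DataFrame:
    """Minimal HD duration as a function of the competitor's half-life.

    Binding affinity and dose stay fixed; the free elimination rate is
    recalibrated for every half-life.  Longer-lived competitors persist in
    the patient and keep displacing toxin between passes, so the minimal
    duration is non-increasing and plateaus once the half-life exceeds the
    session length scale.
    """
    from .calibration import calibrate_free_half_life

    if scenario.session.infusion is None:
        raise ValueError("scenario has no competitor infusion to sweep")
    rows = []
    prev_min: Optional[float] = None
    for hl in half_lives_min:
        comp = scenario.session.infusion.drug.with_half_life(hl)
        lam, t_free = calibrate_free_half_life(comp, scenario.patient)
        comp = comp.with_lambda(lam)
        sc = replace(
            scenario,
            session=replace(
                scenario.session, infusion=replace(scenario.session.infusion, drug=comp)
            ),
        )
        res = find_min_duration(sc, step=step, n_tube=n_tube, n_dz=n_dz, rtol=rtol,
                                upper=prev_min)
        if res.censored:
            res = find_min_duration(sc, step=step, n_tube=n_tube, n_dz=n_dz, rtol=rtol)
        rows.append(
            {
                "competitor_half_life_min": hl,
                "t_half_free_min": t_free,
                "min_duration_min": res.min_duration,
                "rebound_peak_mgL": res.rebound_peak_mgL,
            }
        )
        if res.min_duration is not None:
            prev_min = res.min_duration
    return pd.DataFrame(rows)


def sweep_toxicity(
    scenario: Scenario,
    initial_concs_mgL: list[float],
    duration: float,
    n_tube: int = DEFAULT_N_TUBE,
    n_dz: int = DEFAULT_N_DZ,
    rtol: float = 1e-6,
) -> pd.DataFrame:
    """End-of-session and rebound-peak concentrations across toxicity levels.

    The session duration and the competitor dose are held fixed; only the
    initial toxin concentration varies.
    """
    rows = []
    for c0 in initial_concs_mgL:
        sc = replace(scenario, initial_toxic_mgL=c0)
        run = simulate_session(sc, duration, n_tube=n_tube, n_dz=n_dz, rtol=rtol)
        rows.append(
            {
                "initial_mgL": c0,
                "end_total_mgL": run.end_total_mgL,
                "rebound_peak_mgL": run.rebound_peak_mgL,
                "removed_mg": run.removed_dialysate_mg[scenario.toxic.name],
            }
        )
    return pd.DataFrame(rows)
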