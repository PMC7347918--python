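"""Free-drug half-life calibration.

Published half-lives refer to *total* serum concentration, but in the model
only free plasma drug is metabolised/excreted (rate ``lambda_free``).  For a
protein-bound drug the free pool is small, so ``lambda_free`` must be much
larger than ``ln 2 / t_half_total``.  We pin it down by requiring that, in
the three-compartment patient model started from an equilibrated peak, the
total plasma concentration first crosses half its peak exactly at the
conventional half-life.  The crossing time is a strictly decreasing function
of ``lambda_free``, so the root is unique.
"""

from __future__ import annotations

import math
from typing import Optional

from scipy.optimize import brentq

from . import binding
from .params import DrugParams, PatientParams
from .patient import initialize_equilibrated, simulate_patient_only

__all__ = [
    "calibrate_free_half_life",
    "conventional_half_life_check",
    "calibrate_scenario",
]


class CalibrationError(RuntimeError):
    pass


def _crossing_time(
    lam: float,
    drug: DrugParams,
    patient: PatientParams,
    peak_mgL: float,
    horizon: float,
    rtol: float,
) -> float:
    """First time total plasma concentration reaches half the peak; inf if never."""
    probe = drug.with_lambda(lam)
    state0 = initialize_equilibrated(peak_mgL, patient, probe)
    half_total_uM = 0.5 * (state0.plasma.T_free + state0.plasma.PT)

    def crossed(t, y):
        return y[binding.T] + y[binding.PT] - half_total_uM

    crossed.terminal = True
    crossed.direction = -1.0

    _, _, sol = simulate_patient_only(
        state0, horizon, patient, probe, rtol=rtol, atol=1e-10,
        events=crossed, sample_min=horizon / 50.0,
    )
    if sol.t_events[0].size == 0:
        return math.inf
    return float(sol.t_events[0][0])


def calibrate_free_half_life(
    drug: DrugParams,
    patient: PatientParams,
    peak_conc_mgL: Optional[float] = None,
    rtol: float = 1e-8,
    lam_rtol: float = 1e-6,
) -> tuple[float, float]:
    """Return ``(lambda_free [1/min], t_half_free [min])`` for one drug.

    ``peak_conc_mgL`` defaults to the drug's stored calibration peak (for the
    toxins, the intoxication concentration the scenario starts from).
    Calibration is run for the drug alone, without a competitor.
    """
    if drug.t_half_total <= 0:
        raise CalibrationError(f"{drug.name}: t_half_total must be positive")
    peak = peak_conc_mgL if peak_conc_mgL is not None else drug.calibration_peak_mgL
    if peak is None or peak <= 0:
        raise CalibrationError(f"{drug.name}: no calibration peak concentration given")

    target = drug.t_half_total
    horizon = 5.0 * target

    def g(lam: float) -> float:
        tc = _crossing_time(lam, drug, patient, peak, horizon, rtol)
        return (tc - target) if math.isfinite(tc) else horizon

    # λ = ln2/t_half applied to the (small) free plasma pool is always too slow
    lam_lo = math.log(2.0) / target
    g_lo = g(lam_lo)
    if g_lo <= 0:  # pragma: no cover - would mean faster-than-definition decay
        raise CalibrationError(f"{drug.name}: lower bracket λ={lam_lo:.3e} already too fast")
    lam_hi = lam_lo
    for _ in range(40):
        lam_hi *= 4.0
        if g(lam_hi) < 0:
            break
    else:  # pragma: no cover
        raise CalibrationError(
            f"{drug.name}: no sign change in λ ∈ [{lam_lo:.3e}, {lam_hi:.3e}] 1/min"
        )
    lam = brentq(g, lam_hi / 4.0, lam_hi, rtol=lam_rtol, xtol=1e-300)
    return float(lam), math.log(2.0) / float(lam)


def conventional_half_life_check(
    drug: DrugParams,
    patient: PatientParams,
    peak_conc_mgL: Optional[float] = None,
    rtol: float = 1e-8,
) -> float:
    """Forward check: observed half-concentration time (min) with the stored λ."""
    if drug.lambda_free is None or drug.lambda_free <= 0:
        raise CalibrationError(f"{drug.name}: lambda_free not set (or zero); nothing to check")
    peak = peak_conc_mgL if peak_conc_mgL is not None else drug.calibration_peak_mgL
    if peak is None or peak <= 0:
        raise CalibrationError(f"{drug.name}: no peak concentration given")
    horizon = 5.0 * drug.t_half_total
    tc = _crossing_time(drug.lambda_free, drug, patient, peak, horizon, rtol)
    if not math.isfinite(tc):
        raise CalibrationError(
            f"{drug.name}: total plasma concentration never halved within {horizon:g} min"
        )
    return tc


def calibrate_scenario(scenario, rtol: float = 1e-8):
    """Return a copy of ``scenario`` with calibrated λ for toxin and competitor."""
    from dataclasses import replace

    lam_t, _ = calibrate_free_half_life(scenario.toxic, scenario.patient, rtol=rtol)
    toxic = scenario.toxic.with_lambda(lam_t)
    session = scenario.session
    if session.infusion is not None:
        lam_d, _ = calibrate_free_half_life(session.infusion.drug, scenario.patient, rtol=rtol)
        session = replace(
            session, infusion=replace(session.infusion, drug=session.infusion.drug.with_lambda(lam_d))
        )
    return replace(scenario, toxic=toxic, session=session)
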