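"""Competitive single-site albumin binding.

Two drugs T (toxin) and D (displacer/competitor) bind the same Sudlow site
on albumin P:

    P + T <-> PT   (K_T = k_on,T / k_off,T)
    P + D <-> PD   (K_D = k_on,D / k_off,D)

This module provides the mass-action rate laws used by every spatial and
compartmental mass balance, the algebraic equilibrium solvers (single ligand:
quadratic; two ligands: monotone scalar root in free albumin), and affinity
estimation from a therapeutic binding fraction.

Species are indexed ``T, D, P, PT, PD`` (free toxin, free competitor, free
albumin, complexes); concentrations are µM, affinities M⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .params import DrugParams

__all__ = [
    "T",
    "D",
    "P",
    "PT",
    "PD",
    "N_SPECIES",
    "SPECIES",
    "SpeciesVector",
    "BindingKinetics",
    "binding_rates",
    "reaction_rates",
    "equilibrate_single",
    "equilibrate_competitive",
    "affinity_from_binding",
]

T, D, P, PT, PD = range(5)
N_SPECIES = 5
SPECIES = ("T", "D", "P", "PT", "PD")

#: conversion of a rate/affinity constant per molar to per micromolar
_PER_M_TO_PER_UM = 1.0e-6


@dataclass(frozen=True)
class SpeciesVector:
    """Concentrations of the five binding species in one well-mixed pool (µM)."""

    T_free: float
    D_free: float
    P_free: float
    PT: float
    PD: float

    def as_array(self) -> np.ndarray:
        return np.array([self.T_free, self.D_free, self.P_free, self.PT, self.PD])

    @classmethod
    def from_array(cls, a) -> "SpeciesVector":
        return cls(float(a[T]), float(a[D]), float(a[P]), float(a[PT]), float(a[PD]))

    @property
    def total_T(self) -> float:
        return self.T_free + self.PT

    @property
    def total_D(self) -> float:
        return self.D_free + self.PD

    @property
    def total_P(self) -> float:
        return self.P_free + self.PT + self.PD

    @property
    def frac_bound_T(self) -> float:
        tot = self.total_T
        return self.PT / tot if tot > 0 else 0.0

    @property
    def frac_bound_D(self) -> float:
        tot = self.total_D
        return self.PD / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class BindingKinetics:
    """Rate constants of the two binding reactions in µM units (k_on in µM⁻¹min⁻¹)."""

    kon_T: float
    koff_T: float
    kon_D: float
    koff_D: float

    @classmethod
    def from_drugs(cls, toxic: DrugParams, competitor: Optional[DrugParams]) -> "BindingKinetics":
        return cls(
            kon_T=toxic.k_on * _PER_M_TO_PER_UM,
            koff_T=toxic.k_off,
            kon_D=(competitor.k_on * _PER_M_TO_PER_UM) if competitor else 0.0,
            koff_D=competitor.k_off if competitor else 0.0,
        )


def reaction_rates(conc: np.ndarray, kin: BindingKinetics) -> np.ndarray:
    """Net production rate of each species (µM/min) from the two reactions.

    ``conc`` has species on the leading axis and any trailing shape (a single
    pool, or a spatial grid); the result has the same shape.
    """
    assoc_T = kin.kon_T * conc[P] * conc[T] - kin.koff_T * conc[PT]
    assoc_D = kin.kon_D * conc[P] * conc[D] - kin.koff_D * conc[PD]
    out = np.empty_like(conc)
    out[T] = -assoc_T
    out[D] = -assoc_D
    out[P] = -(assoc_T + assoc_D)
    out[PT] = assoc_T
    out[PD] = assoc_D
    return out


def binding_rates(
    s: SpeciesVector, toxic: DrugParams, competitor: Optional[DrugParams] = None
) -> SpeciesVector:
    """Mass-action net rates (µM/min) for one pool; pure function of the state."""
    kin = BindingKinetics.from_drugs(toxic, competitor)
    return SpeciesVector.from_array(reaction_rates(s.as_array(), kin))


def equilibrate_single(T_tot: float, P_tot: float, K_A: float) -> SpeciesVector:
    """Single-ligand binding equilibrium (no competitor).

    Solves ``T_free · (1 + K_A · P_free) = T_tot`` with ``P_free = P_tot − PT``,
    a quadratic in the bound concentration, taking the physical root.
    """
    if T_tot < 0 or P_tot < 0 or K_A < 0:
        raise ValueError("equilibrate_single: inputs must be non-negative")
    ka = K_A * _PER_M_TO_PER_UM  # µM⁻¹
    if ka == 0.0 or T_tot == 0.0 or P_tot == 0.0:
        return SpeciesVector(T_tot, 0.0, P_tot, 0.0, 0.0)
    # ka·b² − (ka(T+P)+1)·b + ka·T·P = 0 ; smaller root is physical
    bcoef = ka * (T_tot + P_tot) + 1.0
    disc = bcoef * bcoef - 4.0 * ka * ka * T_tot * P_tot
    if disc < 0:  # impossible for valid inputs; guard against rounding
        disc = 0.0
    # numerically stable smaller root: 2c / (−b − sqrt(disc)) form
    bound = 2.0 * ka * T_tot * P_tot / (bcoef + np.sqrt(disc))
    s = SpeciesVector(T_tot - bound, 0.0, P_tot - bound, bound, 0.0)
    _check_equilibrium_residual(s, 0.0, K_A, 0.0, T_tot, 0.0, P_tot)
    return s


def equilibrate_competitive(
    T_tot: float, D_tot: float, P_tot: float, K_T: float, K_D: float
) -> SpeciesVector:
    """Simultaneous two-ligand equilibrium on a shared site.

    Reduces to a monotone scalar equation in free albumin ``p``::

        f(p) = p · (1 + K_T·T_tot/(1+K_T·p) + K_D·D_tot/(1+K_D·p)) − P_tot

    bracketed on ``[0, P_tot]``; the complexes follow algebraically.
    """
    if min(T_tot, D_tot, P_tot, K_T, K_D) < 0:
        raise ValueError("equilibrate_competitive: inputs must be non-negative")
    if D_tot == 0.0 or K_D == 0.0:
        s = equilibrate_single(T_tot, P_tot, K_T)
        return SpeciesVector(s.T_free, D_tot, s.P_free, s.PT, 0.0)
    if T_tot == 0.0 or K_T == 0.0:
        s = equilibrate_single(D_tot, P_tot, K_D)
        return SpeciesVector(T_tot, s.T_free, s.P_free, 0.0, s.PT)
    if P_tot == 0.0:
        return SpeciesVector(T_tot, D_tot, 0.0, 0.0, 0.0)

    kt = K_T * _PER_M_TO_PER_UM
    kd = K_D * _PER_M_TO_PER_UM

    def f(p: float) -> float:
        return p * (1.0 + kt * T_tot / (1.0 + kt * p) + kd * D_tot / (1.0 + kd * p)) - P_tot

    try:
        p_free = brentq(f, 0.0, P_tot, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    except Exception as exc:  # pragma: no cover - monotone bracket cannot fail
        raise ArithmeticError(
            f"albumin root bracketing failed for T_tot={T_tot}, D_tot={D_tot}, "
            f"P_tot={P_tot}, K_T={K_T}, K_D={K_D}"
        ) from exc
    t_free = T_tot / (1.0 + kt * p_free)
    d_free = D_tot / (1.0 + kd * p_free)
    s = SpeciesVector(t_free, d_free, p_free, kt * p_free * t_free, kd * p_free * d_free)
    _check_equilibrium_residual(s, D_tot, K_T, K_D, T_tot, D_tot, P_tot)
    return s


def _check_equilibrium_residual(
    s: SpeciesVector, _d, K_T, K_D, T_tot, D_tot, P_tot, rtol: float = 1e-8
) -> None:
    scale = max(T_tot, D_tot, P_tot, 1e-300)
    res = max(
        abs(s.total_T - T_tot),
        abs(s.total_D - D_tot),
        abs(s.total_P - P_tot),
    )
    if res > rtol * scale:
        raise ArithmeticError(f"equilibrium residual {res:.3e} exceeds {rtol:.0e}·{scale:.3e}")


def affinity_from_binding(
    C_tot_mgL: float, frac_bound: float, P_tot_uM: float, molecular_weight: float
) -> float:
    """Association constant K_A (M⁻¹) from a measured therapeutic binding fraction.

    Given a total drug concentration with a known bound fraction in the
    presence of albumin ``P_tot``, invert the single-site isotherm:
    ``K_A = bound / (free · P_free)`` with ``P_free = P_tot − bound``.
    """
    if not (0.0 < frac_bound < 1.0):
        raise ValueError(f"frac_bound must lie strictly in (0, 1), got {frac_bound}")
    if C_tot_mgL <= 0 or P_tot_uM <= 0 or molecular_weight <= 0:
        raise ValueError("concentrations and molecular weight must be positive")
    c_tot = 1000.0 * C_tot_mgL / molecular_weight  # µM
    bound = frac_bound * c_tot
    free = c_tot - bound
    p_free = P_tot_uM - bound
    if p_free <= 0:
        raise ValueError(
            f"bound drug ({bound:.1f} µM) exceeds available albumin ({P_tot_uM:.1f} µM)"
        )
    return bound / (free * p_free * _PER_M_TO_PER_UM)
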