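"""Parameter containers, unit bridges, and scenario validation.

Internal unit system
--------------------
time in minutes, flows in mL/min, concentrations in µM (µmol/L, i.e. nmol/mL
when paired with volumes in mL), lengths in cm, cross-sections in cm².
Compartment volumes are stored in litres (the clinically quoted unit) and
converted where mass balances need mL.  Drug amounts in mass balances are
carried in nmol; I/O additionally reports mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "DrugParams",
    "PatientParams",
    "DialyzerParams",
    "TubeParams",
    "InfusionSpec",
    "SessionParams",
    "Scenario",
    "ScenarioError",
    "mgL_to_uM",
    "uM_to_mgL",
    "validate_scenario",
    "raise_if_invalid",
]

SUDLOW_I = "sudlow-1"
SUDLOW_II = "sudlow-2"
_BINDING_SITES = (SUDLOW_I, SUDLOW_II, "none")


class ScenarioError(ValueError):
    """Raised when a scenario fails validation; carries the full violation list."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid scenario:\n  " + "\n  ".join(self.violations))


def mgL_to_uM(conc_mgL: float, molecular_weight: float) -> float:
    """Convert a mass concentration (mg/L) to µM for a given molar mass (g/mol)."""
    if molecular_weight <= 0:
        raise ValueError(f"molecular weight must be positive, got {molecular_weight}")
    return 1000.0 * conc_mgL / molecular_weight


def uM_to_mgL(conc_uM: float, molecular_weight: float) -> float:
    """Inverse of :func:`mgL_to_uM`."""
    if molecular_weight <= 0:
        raise ValueError(f"molecular weight must be positive, got {molecular_weight}")
    return conc_uM * molecular_weight / 1000.0


@dataclass(frozen=True)
class DrugParams:
    """One drug's albumin-binding, elimination and therapeutic-range parameters.

    ``K_A`` is the association equilibrium constant (M⁻¹) of the single
    Sudlow-site binding reaction; ``k_on``/``k_off`` its mass-action rate
    constants with ``k_off = k_on / K_A``.  ``t_half_total`` is the
    conventional half-life defined on *total* serum concentration;
    ``lambda_free`` is the first-order elimination rate applied to free
    plasma drug that reproduces it in the three-compartment model
    (``None`` until calibrated).
    """

    name: str
    molecular_weight: float            # g/mol
    binding_site: str                  # "sudlow-1" | "sudlow-2" | "none"
    K_A: float                         # 1/M
    k_on: float                        # 1/(M·min)
    k_off: float                       # 1/min
    t_half_total: float                # min
    therapeutic_range: tuple[float, float]  # (min, max) total serum conc, mg/L
    lambda_free: Optional[float] = None     # 1/min, free-drug elimination rate
    calibration_peak_mgL: Optional[float] = None  # peak used for calibration

    @classmethod
    def from_affinity(
        cls,
        name: str,
        molecular_weight: float,
        binding_site: str,
        K_A: float,
        t_half_total: float,
        therapeutic_range: tuple[float, float],
        k_on: float = 1.0e8,
        lambda_free: Optional[float] = None,
        calibration_peak_mgL: Optional[float] = None,
    ) -> "DrugParams":
        """Build a drug from its affinity; ``k_off`` follows from K_A = k_on/k_off.

        ``K_A = 0`` denotes an unbound tracer and zeroes both rate constants.
        """
        if K_A == 0.0:
            k_on_eff, k_off = 0.0, 0.0
        else:
            k_on_eff, k_off = k_on, k_on / K_A
        return cls(
            name=name,
            molecular_weight=molecular_weight,
            binding_site=binding_site,
            K_A=K_A,
            k_on=k_on_eff,
            k_off=k_off,
            t_half_total=t_half_total,
            therapeutic_range=tuple(therapeutic_range),
            lambda_free=lambda_free,
            calibration_peak_mgL=calibration_peak_mgL,
        )

    def with_lambda(self, lambda_free: float) -> "DrugParams":
        return replace(self, lambda_free=lambda_free)

    def with_half_life(self, t_half_total: float) -> "DrugParams":
        """New drug with a different conventional half-life (λ reset to None)."""
        return replace(self, t_half_total=t_half_total, lambda_free=None)


@dataclass(frozen=True)
class PatientParams:
    """Three-compartment patient: volumes, albumin levels, transfer coefficients."""

    V_pl: float = 3.5            # plasma volume, L
    V_is: float = 14.0           # interstitial volume, L
    V_ic: float = 28.0           # intracellular volume, L
    hematocrit: float = 0.35     # fraction
    albumin_plasma: float = 650.0        # µM
    albumin_interstitial: float = 260.0  # µM (~40% of plasma, typical interstitial level)
    K_ip: float = 1200.0         # plasma<->interstitial free-solute MTC, mL/min
    K_ic: float = 100.0          # interstitial<->intracellular MTC, mL/min

    @property
    def v_pl_ml(self) -> float:
        return self.V_pl * 1000.0

    @property
    def v_is_ml(self) -> float:
        return self.V_is * 1000.0

    @property
    def v_ic_ml(self) -> float:
        return self.V_ic * 1000.0


def _default_fiber_count(membrane_area_m2: float, diameter_cm: float, length_cm: float) -> int:
    import math

    return round(membrane_area_m2 * 1.0e4 / (math.pi * diameter_cm * length_cm))


@dataclass(frozen=True)
class DialyzerParams:
    """Hollow-fiber dialyzer transport and geometry parameters.

    Diffusive transport is governed entirely by ``KoA_free`` (protein-bound
    species do not diffuse across the membrane); geometry only sets residence
    volumes.  Defaults emulate a 1.8 m² high-flux dialyzer with 200 µm inner
    fiber diameter and 23 cm effective length.
    """

    KoA_free: float = 800.0        # mL/min, free solutes
    sigma_free: float = 0.0        # reflection coefficient, free solutes
    sigma_protein: float = 0.999   # reflection coefficient, protein species
    membrane_area: float = 1.8     # m²
    fiber_inner_diameter: float = 0.02   # cm
    fiber_length: float = 23.0     # cm
    n_fibers: int = _default_fiber_count(1.8, 0.02, 23.0)
    area_dialysate_ratio: float = 2.0  # dialysate cross-section per fiber / lumen

    @property
    def area_lumen(self) -> float:
        """Inner cross-section of one fiber lumen, cm²."""
        import math

        return math.pi * (self.fiber_inner_diameter / 2.0) ** 2

    @property
    def area_dialysate(self) -> float:
        """Interstitial (dialysate-side) cross-section per fiber, cm²."""
        return self.area_dialysate_ratio * self.area_lumen

    @property
    def plasma_volume_ml(self) -> float:
        """Total blood-side priming volume N·A·L (cm³ = mL)."""
        return self.n_fibers * self.area_lumen * self.fiber_length

    @property
    def dialysate_volume_ml(self) -> float:
        return self.n_fibers * self.area_dialysate * self.fiber_length


@dataclass(frozen=True)
class TubeParams:
    """Arterial tube segment between the infusion port and the dialyzer inlet."""

    length: float = 150.0          # cm
    inner_diameter: float = 0.4    # cm

    @property
    def area(self) -> float:
        import math

        return math.pi * (self.inner_diameter / 2.0) ** 2

    @property
    def volume_ml(self) -> float:
        return self.area * self.length


@dataclass(frozen=True)
class InfusionSpec:
    """Constant-rate extracorporeal infusion of the binding competitor.

    The full ``dose`` dissolved in ``diluent_volume`` is delivered over the
    session; the infusion rate is therefore ``diluent_volume / duration``
    unless ``rate`` pins it explicitly.
    """

    drug: DrugParams
    dose: float                  # mg
    diluent_volume: float        # mL
    rate: Optional[float] = None  # mL/min; None -> diluent_volume / session duration

    @property
    def concentration_uM(self) -> float:
        """Infusate concentration, µM (= dose / MW / volume)."""
        return self.dose / self.drug.molecular_weight / self.diluent_volume * 1.0e6

    def rate_for_duration(self, duration_min: float) -> float:
        if self.rate is not None:
            return self.rate
        return self.diluent_volume / duration_min


@dataclass(frozen=True)
class SessionParams:
    """Prescription of one hemodialysis session."""

    Q_blood: float = 250.0        # mL/min
    Q_dialysate: float = 500.0    # mL/min (fresh dialysate inlet, Q_di)
    infusion: Optional[InfusionSpec] = None
    max_duration: float = 720.0   # min, cap for the minimal-duration search
    rebound_horizon: float = 720.0  # min of post-dialytic follow-up

    def q_plasma(self, hematocrit: float) -> float:
        """Plasma flow entering the extracorporeal circuit, mL/min."""
        return self.Q_blood * (1.0 - hematocrit)


@dataclass(frozen=True)
class Scenario:
    """A complete intoxication + treatment scenario."""

    name: str
    patient: PatientParams
    toxic: DrugParams
    dialyzer: DialyzerParams
    tube: TubeParams
    session: SessionParams
    initial_toxic_mgL: float

    @property
    def competitor(self) -> Optional[DrugParams]:
        return self.session.infusion.drug if self.session.infusion else None


# ---------------------------------------------------------------------------
# validation


def _check_drug(d: DrugParams, path: str, out: list[str], require_lambda: bool = False) -> None:
    if d.molecular_weight <= 0:
        out.append(f"{path}.molecular_weight: must be positive, got {d.molecular_weight}")
    if d.binding_site not in _BINDING_SITES:
        out.append(f"{path}.binding_site: unknown site {d.binding_site!r}")
    if d.K_A < 0:
        out.append(f"{path}.K_A: must be non-negative, got {d.K_A}")
    if d.K_A > 0:
        if d.k_on <= 0:
            out.append(f"{path}.k_on: must be positive, got {d.k_on}")
        if d.k_off <= 0:
            out.append(f"{path}.k_off: must be positive, got {d.k_off}")
        elif d.k_on > 0 and abs(d.k_off - d.k_on / d.K_A) > 1e-12 * abs(d.k_off):
            out.append(
                f"{path}.k_off / {path}.K_A: inconsistent with k_off = k_on/K_A "
                f"(k_off={d.k_off}, k_on/K_A={d.k_on / d.K_A})"
            )
    if d.t_half_total <= 0:
        out.append(f"{path}.t_half_total: must be positive, got {d.t_half_total}")
    lo, hi = d.therapeutic_range
    if not (0 <= lo < hi):
        out.append(f"{path}.therapeutic_range: need 0 <= min < max, got {d.therapeutic_range}")
    if d.lambda_free is not None and d.lambda_free < 0:
        out.append(f"{path}.lambda_free: must be non-negative, got {d.lambda_free}")
    if require_lambda and d.lambda_free is None:
        out.append(f"{path}.lambda_free: required (run calibration first)")


def validate_scenario(scenario: Scenario, require_lambda: bool = False) -> list[str]:
    """Check every declared invariant; return all violations with field paths.

    An empty list means the scenario is valid.  Violations are aggregated,
    never first-failure-only.
    """
    v: list[str] = []
    p = scenario.patient
    for fname in ("V_pl", "V_is", "V_ic"):
        val = getattr(p, fname)
        if val <= 0:
            v.append(f"patient.{fname}: must be positive, got {val}")
    if not (0.0 < p.hematocrit < 1.0):
        v.append(f"patient.hematocrit: must lie in (0, 1), got {p.hematocrit}")
    if p.albumin_plasma <= 0:
        v.append(f"patient.albumin_plasma: must be positive, got {p.albumin_plasma}")
    if p.albumin_interstitial < 0:
        v.append(f"patient.albumin_interstitial: must be non-negative, got {p.albumin_interstitial}")
    if not (p.K_ip > p.K_ic > 0):
        v.append(
            f"patient.K_ip/patient.K_ic: need K_ip > K_ic > 0 (capillary endothelium more "
            f"permeable than cell walls), got K_ip={p.K_ip}, K_ic={p.K_ic}"
        )

    _check_drug(scenario.toxic, "toxic", v, require_lambda=require_lambda)
    if scenario.toxic.K_A == 0 and scenario.session.infusion is not None:
        v.append("toxic.K_A: unbound toxin cannot be displaced; remove the infusion")

    dz = scenario.dialyzer
    if dz.KoA_free <= 0:
        v.append(f"dialyzer.KoA_free: must be positive, got {dz.KoA_free}")
    if not (0.0 <= dz.sigma_free < 1.0):
        v.append(f"dialyzer.sigma_free: must lie in [0, 1), got {dz.sigma_free}")
    if not (0.0 < dz.sigma_protein <= 1.0):
        v.append(f"dialyzer.sigma_protein: must lie in (0, 1], got {dz.sigma_protein}")
    if dz.membrane_area <= 0:
        v.append(f"dialyzer.membrane_area: must be positive, got {dz.membrane_area}")
    if dz.n_fibers <= 0:
        v.append(f"dialyzer.n_fibers: must be positive, got {dz.n_fibers}")
    for fname in ("fiber_inner_diameter", "fiber_length", "area_dialysate_ratio"):
        val = getattr(dz, fname)
        if val <= 0:
            v.append(f"dialyzer.{fname}: must be positive, got {val}")

    tube = scenario.tube
    if tube.length <= 0:
        v.append(f"tube.length: must be positive, got {tube.length}")
    if tube.inner_diameter <= 0:
        v.append(f"tube.inner_diameter: must be positive, got {tube.inner_diameter}")

    s = scenario.session
    if s.Q_blood <= 0:
        v.append(f"session.Q_blood: must be positive, got {s.Q_blood}")
    if s.Q_dialysate <= 0:
        v.append(f"session.Q_dialysate: must be positive, got {s.Q_dialysate}")
    if s.max_duration <= 0:
        v.append(f"session.max_duration: must be positive, got {s.max_duration}")
    if s.rebound_horizon <= 0:
        v.append(f"session.rebound_horizon: must be positive, got {s.rebound_horizon}")
    if s.infusion is not None:
        inf = s.infusion
        _check_drug(inf.drug, "session.infusion.drug", v, require_lambda=require_lambda)
        if inf.dose <= 0:
            v.append(f"session.infusion.dose: must be positive, got {inf.dose}")
        if inf.diluent_volume <= 0:
            v.append(f"session.infusion.diluent_volume: must be positive, got {inf.diluent_volume}")
        if inf.rate is not None and inf.rate <= 0:
            v.append(f"session.infusion.rate: must be positive, got {inf.rate}")
        if inf.drug.binding_site != scenario.toxic.binding_site:
            v.append(
                "session.infusion.drug.binding_site: competitor must share the toxin's "
                f"albumin site ({scenario.toxic.binding_site}), got {inf.drug.binding_site}"
            )
        expected = inf.dose / inf.drug.molecular_weight / inf.diluent_volume * 1.0e6
        if abs(inf.concentration_uM - expected) > 1e-9 * expected:
            v.append("session.infusion: concentration inconsistent with dose and volume")

    if scenario.initial_toxic_mgL < 0:
        v.append(f"initial_toxic_mgL: must be non-negative, got {scenario.initial_toxic_mgL}")
    return v


def raise_if_invalid(scenario: Scenario, require_lambda: bool = False) -> Scenario:
    violations = validate_scenario(scenario, require_lambda=require_lambda)
    if violations:
        raise ScenarioError(violations)
    return scenario
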