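"""Reference drugs and the two canonical intoxication scenarios.

Molecular weights are standard reference values (g/mol).  Toxin affinities
are recomputed from their therapeutic binding fractions (20 mg/L phenytoin
90% bound, 12 mg/L carbamazepine 75% bound, at 650 µM albumin) rather than
taken as the rounded printed constants; competitor affinities are literature
constants.  The association rate constant is 1e8 M⁻¹min⁻¹ for every drug,
with the dissociation rate following from K_A.
"""

from __future__ import annotations

from .binding import affinity_from_binding
from .params import (
    SUDLOW_I,
    SUDLOW_II,
    DialyzerParams,
    DrugParams,
    InfusionSpec,
    PatientParams,
    Scenario,
    SessionParams,
    TubeParams,
)

__all__ = [
    "MW_PHENYTOIN",
    "MW_CARBAMAZEPINE",
    "MW_ASPIRIN",
    "MW_IBUPROFEN",
    "MW_ALBUMIN",
    "ALBUMIN_PLASMA_UM",
    "phenytoin",
    "carbamazepine",
    "aspirin",
    "ibuprofen",
    "scenario_phenytoin_aspirin",
    "scenario_carbamazepine_ibuprofen",
    "get_scenario",
    "SCENARIOS",
]

MW_PHENYTOIN = 252.27
MW_CARBAMAZEPINE = 236.27
MW_ASPIRIN = 180.16
MW_IBUPROFEN = 206.28
MW_ALBUMIN = 66438.0

#: plasma albumin of the reference patient (4.3 g/dL, quoted as 650 µM)
ALBUMIN_PLASMA_UM = 650.0


def phenytoin() -> DrugParams:
    """Sudlow-I anticonvulsant; therapeutic 10–20 mg/L, 90% bound at 20 mg/L."""
    k_a = affinity_from_binding(20.0, 0.90, ALBUMIN_PLASMA_UM, MW_PHENYTOIN)
    return DrugParams.from_affinity(
        "phenytoin", MW_PHENYTOIN, SUDLOW_I, k_a,
        t_half_total=35.0 * 60.0, therapeutic_range=(10.0, 20.0),
        calibration_peak_mgL=70.0,
    )


def carbamazepine() -> DrugParams:
    """Sudlow-II anticonvulsant; therapeutic 4–12 mg/L, 75% bound at 12 mg/L."""
    k_a = affinity_from_binding(12.0, 0.75, ALBUMIN_PLASMA_UM, MW_CARBAMAZEPINE)
    return DrugParams.from_affinity(
        "carbamazepine", MW_CARBAMAZEPINE, SUDLOW_II, k_a,
        t_half_total=25.0 * 60.0, therapeutic_range=(4.0, 12.0),
        calibration_peak_mgL=35.0,
    )


def aspirin() -> DrugParams:
    """Sudlow-I binding competitor; modelled as the parent drug, t½ = 20 min."""
    return DrugParams.from_affinity(
        "aspirin", MW_ASPIRIN, SUDLOW_I, 1.90e5,
        t_half_total=20.0, therapeutic_range=(20.0, 100.0),
        calibration_peak_mgL=20.0,
    )


def ibuprofen() -> DrugParams:
    """Sudlow-II binding competitor; t½ = 2 h."""
    return DrugParams.from_affinity(
        "ibuprofen", MW_IBUPROFEN, SUDLOW_II, 1.76e5,
        t_half_total=120.0, therapeutic_range=(10.0, 50.0),
        calibration_peak_mgL=50.0,
    )


def _base_patient() -> PatientParams:
    return PatientParams()


def scenario_phenytoin_aspirin(with_infusion: bool = True) -> Scenario:
    """70 mg/L phenytoin intoxication; 2000 mg aspirin in 500 mL saline."""
    infusion = (
        InfusionSpec(drug=aspirin(), dose=2000.0, diluent_volume=500.0)
        if with_infusion
        else None
    )
    return Scenario(
        name="phenytoin-aspirin" if with_infusion else "phenytoin-conventional",
        patient=_base_patient(),
        toxic=phenytoin(),
        dialyzer=DialyzerParams(),
        tube=TubeParams(),
        session=SessionParams(infusion=infusion),
        initial_toxic_mgL=70.0,
    )


def scenario_carbamazepine_ibuprofen(with_infusion: bool = True) -> Scenario:
    """35 mg/L carbamazepine intoxication; 800 mg ibuprofen in 200 mL saline."""
    infusion = (
        InfusionSpec(drug=ibuprofen(), dose=800.0, diluent_volume=200.0)
        if with_infusion
        else None
    )
    return Scenario(
        name="carbamazepine-ibuprofen" if with_infusion else "carbamazepine-conventional",
        patient=_base_patient(),
        toxic=carbamazepine(),
        dialyzer=DialyzerParams(),
        tube=TubeParams(),
        session=SessionParams(infusion=infusion),
        initial_toxic_mgL=35.0,
    )


SCENARIOS = {
    "phenytoin-aspirin": lambda: scenario_phenytoin_aspirin(True),
    "phenytoin-conventional": lambda: scenario_phenytoin_aspirin(False),
    "carbamazepine-ibuprofen": lambda: scenario_carbamazepine_ibuprofen(True),
    "carbamazepine-conventional": lambda: scenario_carbamazepine_ibuprofen(False),
}


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(SCENARIOS)}") from None
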