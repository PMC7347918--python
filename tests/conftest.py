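import pytest

from dialybind.params import PatientParams
from dialybind.presets import (
    aspirin,
    carbamazepine,
    ibuprofen,
    phenytoin,
    scenario_carbamazepine_ibuprofen,
    scenario_phenytoin_aspirin,
)


@pytest.fixture(scope="session")
def patient() -> PatientParams:
    return PatientParams()


@pytest.fixture(scope="session")
def drugs() -> dict:
    return {
        "phenytoin": phenytoin(),
        "carbamazepine": carbamazepine(),
        "aspirin": aspirin(),
        "ibuprofen": ibuprofen(),
    }


@pytest.fixture(scope="session")
def calibrated_drugs(patient) -> dict:
    """All four drugs with their free elimination rate calibrated once."""
    from dialybind.calibration import calibrate_free_half_life

    out = {}
    for d in (phenytoin(), carbamazepine(), aspirin(), ibuprofen()):
        lam, _ = calibrate_free_half_life(d, patient)
        out[d.name] = d.with_lambda(lam)
    return out


def _with_lambdas(scenario, calibrated):
    from dataclasses import replace

    toxic = calibrated[scenario.toxic.name]
    session = scenario.session
    if session.infusion is not None:
        session = replace(
            session,
            infusion=replace(session.infusion, drug=calibrated[session.infusion.drug.name]),
        )
    return replace(scenario, toxic=toxic, session=session)


@pytest.fixture(scope="session")
def scenario_a(calibrated_drugs):
    """Phenytoin 70 mg/L with 2000 mg aspirin infusion, calibrated."""
    return _with_lambdas(scenario_phenytoin_aspirin(True), calibrated_drugs)


@pytest.fixture(scope="session")
def scenario_a_conventional(calibrated_drugs):
    return _with_lambdas(scenario_phenytoin_aspirin(False), calibrated_drugs)


@pytest.fixture(scope="session")
def scenario_b(calibrated_drugs):
    """Carbamazepine 35 mg/L with 800 mg ibuprofen infusion, calibrated."""
    return _with_lambdas(scenario_carbamazepine_ibuprofen(True), calibrated_drugs)


@pytest.fixture(scope="session")
def scenario_b_conventional(calibrated_drugs):
    return _with_lambdas(scenario_carbamazepine_ibuprofen(False), calibrated_drugs)
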