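"""Scenario configuration files (TOML dialect) and time-course tables.

A scenario is one TOML file with sections ``[patient]``, ``[drug_toxic]``,
``[dialyzer]``, ``[tube]``, ``[session]`` and, when a competitor is infused,
``[session.infusion]`` / ``[session.infusion.drug]``.  Reading uses the
stdlib ``tomllib``; writing uses a small emitter restricted to the value
types a scenario needs, so any scenario survives a write/read round trip
field-for-field.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict
from pathlib import Path
from typing import Any

import pandas as pd

from .params import (
    DialyzerParams,
    DrugParams,
    InfusionSpec,
    PatientParams,
    Scenario,
    SessionParams,
    TubeParams,
)

__all__ = ["read_scenario", "write_scenario", "scenario_to_toml", "write_timecourse"]


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"unsupported TOML value {v!r}")


def _emit_table(name: str, table: dict[str, Any], out: list[str]) -> None:
    subtables = {k: v for k, v in table.items() if isinstance(v, dict)}
    scalars = {k: v for k, v in table.items() if not isinstance(v, dict) and v is not None}
    out.append(f"[{name}]")
    for k, v in scalars.items():
        out.append(f"{k} = {_toml_value(v)}")
    out.append("")
    for k, v in subtables.items():
        _emit_table(f"{name}.{k}", v, out)


def _drug_dict(d: DrugParams) -> dict[str, Any]:
    dd = asdict(d)
    dd["therapeutic_range"] = list(d.therapeutic_range)
    return dd


def scenario_to_toml(scenario: Scenario) -> str:
    out: list[str] = [f"name = {_toml_value(scenario.name)}",
                      f"initial_toxic_mgL = {_toml_value(scenario.initial_toxic_mgL)}", ""]
    _emit_table("patient", asdict(scenario.patient), out)
    _emit_table("drug_toxic", _drug_dict(scenario.toxic), out)
    _emit_table("dialyzer", asdict(scenario.dialyzer), out)
    _emit_table("tube", asdict(scenario.tube), out)
    sess = {
        "Q_blood": scenario.session.Q_blood,
        "Q_dialysate": scenario.session.Q_dialysate,
        "max_duration": scenario.session.max_duration,
        "rebound_horizon": scenario.session.rebound_horizon,
    }
    if scenario.session.infusion is not None:
        inf = scenario.session.infusion
        sess["infusion"] = {
            "dose": inf.dose,
            "diluent_volume": inf.diluent_volume,
            **({"rate": inf.rate} if inf.rate is not None else {}),
            "drug": _drug_dict(inf.drug),
        }
    _emit_table("session", sess, out)
    return "\n".join(out)


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    Path(path).write_text(scenario_to_toml(scenario))


def _drug_from_dict(d: dict[str, Any]) -> DrugParams:
    return DrugParams(
        name=d["name"],
        molecular_weight=d["molecular_weight"],
        binding_site=d["binding_site"],
        K_A=d["K_A"],
        k_on=d["k_on"],
        k_off=d["k_off"],
        t_half_total=d["t_half_total"],
        therapeutic_range=tuple(d["therapeutic_range"]),
        lambda_free=d.get("lambda_free"),
        calibration_peak_mgL=d.get("calibration_peak_mgL"),
    )


def read_scenario(path: str | Path) -> Scenario:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    sess = data["session"]
    infusion = None
    if "infusion" in sess:
        inf = sess["infusion"]
        infusion = InfusionSpec(
            drug=_drug_from_dict(inf["drug"]),
            dose=inf["dose"],
            diluent_volume=inf["diluent_volume"],
            rate=inf.get("rate"),
        )
    return Scenario(
        name=data["name"],
        patient=PatientParams(**data["patient"]),
        toxic=_drug_from_dict(data["drug_toxic"]),
        dialyzer=DialyzerParams(**data["dialyzer"]),
        tube=TubeParams(**data["tube"]),
        session=SessionParams(
            Q_blood=sess["Q_blood"],
            Q_dialysate=sess["Q_dialysate"],
            infusion=infusion,
            max_duration=sess["max_duration"],
            rebound_horizon=sess["rebound_horizon"],
        ),
        initial_toxic_mgL=data["initial_toxic_mgL"],
    )


def write_timecourse(frame: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a time-course table as delimited text with a header row."""
    frame.to_csv(path, sep=sep, index=False)
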