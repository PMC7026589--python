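"""Shipped presets: agents, cell models and landmark scenarios.

Chemical presets live in ``data/agents.yaml`` (structured text, one block
per agent).  The physical agents whose yields are fixed by the model's own
calibration (UV-C) or by the literature constant (gamma, 1000 SSBs/Gy) are
constructed here in code so they always agree with :mod:`hepacomet.model`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Mapping

import yaml

from .model import (
    AgentPreset,
    ConfigurationError,
    DamageScenario,
    Genotype,
    Inhibitors,
    MechanismClass,
    UV_YIELD_PER_JM2,
    GAMMA_SSB_PER_GY,
    ViabilityCurve,
)

__all__ = [
    "agent_preset",
    "list_agents",
    "screen_doses",
    "SCREEN_PANEL",
    "CellLine",
    "cell_line",
    "list_cell_lines",
    "make_scenario",
    "landmark_scenarios",
]


def _read_yaml(name: str) -> dict:
    with resources.files(__package__).joinpath("data", name).open("r") as fh:
        return yaml.safe_load(fh)


def _build_agents() -> Dict[str, AgentPreset]:
    agents: Dict[str, AgentPreset] = {}
    for name, block in _read_yaml("agents.yaml").items():
        via = block.get("viability", {})
        agents[name] = AgentPreset(
            name=name,
            mechanism_class=MechanismClass(block["mechanism"]),
            lesion_yield=float(block.get("lesion_yield", 0.0)),
            dose_unit=block.get("dose_unit", ""),
            activating_enzyme=block.get("activating_enzyme"),
            crosslink_yield=float(block.get("crosslink_yield", 0.0)),
            viability_curve=ViabilityCurve(
                d50=float(via.get("d50", float("inf"))),
                hill=float(via.get("hill", 1.0)),
            ),
        )
    # Physical agents with model-derived yields.
    agents["uv_c"] = AgentPreset(
        name="uv_c",
        mechanism_class=MechanismClass.BULKY_NER,
        lesion_yield=UV_YIELD_PER_JM2,
        dose_unit="J/m2",
    )
    agents["gamma"] = AgentPreset(
        name="gamma",
        mechanism_class=MechanismClass.DIRECT_SSB,
        lesion_yield=GAMMA_SSB_PER_GY,
        dose_unit="Gy",
    )
    return agents


_AGENTS = _build_agents()
_DOSES: Dict[str, List[float]] = {
    name: [float(d) for d in block.get("screen_doses", [])]
    for name, block in _read_yaml("agents.yaml").items()
}

#: The nine-compound reference screen panel, in report order.
SCREEN_PANEL: List[str] = [
    "etoposide",
    "dat_2_4",
    "cyclophosphamide",
    "pca",
    "ndma",
    "hydroquinone",
    "benzo_a_pyrene",
    "chloramphenicol",
    "cisplatin",
]


def agent_preset(name: str) -> AgentPreset:
    try:
        return _AGENTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown agent {name!r}; known agents: {sorted(_AGENTS)}"
        ) from None


def list_agents() -> List[str]:
    return sorted(_AGENTS)


def screen_doses(name: str) -> List[float]:
    doses = _DOSES.get(name)
    if not doses:
        raise ConfigurationError(f"no screen dose ladder for agent {name!r}")
    return list(doses)


@dataclass(frozen=True)
class CellLine:
    name: str
    cyp_scalars: Mapping[str, float]
    inhibitor_residuals: Mapping[str, float]
    description: str = ""


_CELL_LINES: Dict[str, CellLine] = {
    name: CellLine(
        name=name,
        cyp_scalars=dict(block.get("cyp_scalars", {})),
        inhibitor_residuals=dict(block.get("inhibitor_residuals", {})),
        description=block.get("description", ""),
    )
    for name, block in _read_yaml("cell_lines.yaml").items()
}


def cell_line(name: str) -> CellLine:
    try:
        return _CELL_LINES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown cell line {name!r}; known: {sorted(_CELL_LINES)}"
        ) from None


def list_cell_lines() -> List[str]:
    return sorted(_CELL_LINES)


def make_scenario(
    agent: str,
    dose: float,
    time_h: float = 1.0,
    cell_line_name: str = "HepaRG",
    genotype: Genotype | str = Genotype.WT,
    hu_arac: bool = False,
    ket: bool = False,
    anf: bool = False,
    vehicle: bool = False,
    label: str = "",
) -> DamageScenario:
    """Build a scenario with the cell line's metabolic scalars filled in."""
    line = cell_line(cell_line_name)
    return DamageScenario(
        agent=agent,
        dose=dose,
        time_h=time_h,
        genotype=Genotype(genotype),
        cyp_scalars=dict(line.cyp_scalars),
        inhibitors=Inhibitors(hu_arac=hu_arac, ket=ket, anf=anf),
        inhibitor_residuals=dict(line.inhibitor_residuals),
        label=label or f"{agent}@{dose}{'+HU/AraC' if hu_arac else ''}",
        vehicle=vehicle,
    )


def landmark_scenarios() -> Dict[str, DamageScenario]:
    """The shipped canonical conditions (see data/scenarios.yaml)."""
    out: Dict[str, DamageScenario] = {}
    for name, block in _read_yaml("scenarios.yaml").items():
        out[name] = make_scenario(
            agent=block["agent"],
            dose=float(block.get("dose", 0.0)),
            time_h=float(block.get("time_h", 1.0)),
            cell_line_name=block.get("cell_line", "HepaRG"),
            genotype=block.get("genotype", "WT"),
            hu_arac=bool(block.get("hu_arac", False)),
            ket=bool(block.get("ket", False)),
            anf=bool(block.get("anf", False)),
            vehicle=bool(block.get("vehicle", False)),
            label=name,
        )
    return out
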