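"""Scenario configuration parsing and result serialization.

Scenario files are JSON (canonical) or YAML (convenience).  Two equivalent
model specifications are accepted: an explicit atom list ::

    {"atoms": [{"p": 0.75, "xa": 3, "xb": 0},
               {"p": 0.25, "xa": 0, "xb": 3}],
     "regime": "systematic"}

or the two-state shorthand ::

    {"p": 0.75, "state1": [3, 0], "state2": [0, 3],
     "regime": "systematic"}

Optional blocks: ``intelligence`` ({"rho": ..., "cost": {"family": ...,
"kappa": ...}}) and ``simulation`` (policies, n0, generations, seed, mode,
conditioning).  Unknown keys are rejected with key-path diagnostics, and
``parse(serialize(x))`` round-trips exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .intelligence import CostRegionMap, IntelligenceSolveResult
from .optimize import RegionMap, SolveResult
from .scenarios import (
    CostFamily,
    CostModel,
    FecundityModel,
    OutcomeAtom,
    Regime,
    validate_model,
)
from .simulate import ReplicateSummary, SimulationConfig, Trajectory

__all__ = [
    "ScenarioConfig",
    "ConfigError",
    "read_scenario",
    "parse_scenario",
    "serialize_scenario",
    "write_results",
    "result_to_json",
]


class ConfigError(ValueError):
    """Schema violation in a scenario configuration, with key-path context."""


@dataclass(frozen=True)
class ScenarioConfig:
    model: FecundityModel
    intelligence: dict | None = None
    simulation: dict | None = None

    def simulation_config(self) -> SimulationConfig:
        if self.simulation is None:
            raise ConfigError("scenario has no 'simulation' block")
        sim = dict(self.simulation)
        return SimulationConfig(
            model=self.model,
            policies=sim.get("policies", [1.0]),
            n0=sim.get("n0", 10),
            generations=sim.get("generations", 25),
            seed=sim.get("seed", 0),
            mode=sim.get("mode", "sampled"),
            conditioning=sim.get("conditioning"),
        )

    def cost_model(self) -> CostModel:
        block = self.intelligence or {}
        cost = block.get("cost", {})
        return CostModel(
            CostFamily(cost.get("family", "linear")), float(cost.get("kappa", 0.0))
        )


_MODEL_KEYS = {"atoms", "p", "state1", "state2", "regime"}
_TOP_KEYS = _MODEL_KEYS | {"intelligence", "simulation"}
_SIM_KEYS = {"policies", "n0", "generations", "seed", "mode", "conditioning"}
_INTEL_KEYS = {"rho", "cost"}
_COST_KEYS = {"family", "kappa"}


def _reject_unknown(mapping: dict, allowed: set, path: str):
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown key {path}{key!r}")


def parse_scenario(data: dict) -> ScenarioConfig:
    """Validate and build a :class:`ScenarioConfig` from a plain mapping."""
    if not isinstance(data, dict):
        raise ConfigError("scenario must be a mapping at the top level")
    _reject_unknown(data, _TOP_KEYS, "")
    regime = data.get("regime", "systematic")
    try:
        regime = Regime.coerce(regime)
    except ValueError as exc:
        raise ConfigError(f"'regime': {exc}") from exc

    if "atoms" in data:
        if "state1" in data or "state2" in data:
            raise ConfigError("give either 'atoms' or the two-state shorthand")
        atoms = []
        for i, raw in enumerate(data["atoms"]):
            _reject_unknown(raw, {"p", "xa", "xb"}, f"atoms[{i}].")
            try:
                atoms.append(
                    OutcomeAtom(float(raw["p"]), float(raw["xa"]), float(raw["xb"]))
                )
            except KeyError as exc:
                raise ConfigError(f"atoms[{i}] missing key {exc}") from exc
        model = FecundityModel(atoms, regime)
    elif "state1" in data and "state2" in data:
        if "p" not in data:
            raise ConfigError("two-state shorthand requires 'p'")
        s1, s2 = data["state1"], data["state2"]
        for name, s in (("state1", s1), ("state2", s2)):
            if len(s) != 2:
                raise ConfigError(f"'{name}' must be a pair [x_a, x_b]")
        p = float(data["p"])
        model = FecundityModel(
            [
                OutcomeAtom(p, float(s1[0]), float(s1[1])),
                OutcomeAtom(1.0 - p, float(s2[0]), float(s2[1])),
            ],
            regime,
        )
    else:
        raise ConfigError("scenario must contain 'atoms' or 'state1'/'state2'")

    report = validate_model(model)
    if not report.ok:
        raise ConfigError("invalid model: " + "; ".join(report.violations))

    intelligence = data.get("intelligence")
    if intelligence is not None:
        _reject_unknown(intelligence, _INTEL_KEYS, "intelligence.")
        if "cost" in intelligence:
            _reject_unknown(intelligence["cost"], _COST_KEYS, "intelligence.cost.")
    simulation = data.get("simulation")
    if simulation is not None:
        _reject_unknown(simulation, _SIM_KEYS, "simulation.")
    return ScenarioConfig(model=model, intelligence=intelligence,
                          simulation=simulation)


def read_scenario(path: str | Path) -> ScenarioConfig:
    """Load a scenario from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return parse_scenario(data)


def serialize_scenario(config: ScenarioConfig) -> dict:
    """Inverse of :func:`parse_scenario` (atom-list form, exact round-trip)."""
    out: dict = {
        "atoms": [
            {"p": a.prob, "xa": a.x_a, "xb": a.x_b} for a in config.model.atoms
        ],
        "regime": config.model.regime.value,
    }
    if config.intelligence is not None:
        out["intelligence"] = config.intelligence
    if config.simulation is not None:
        out["simulation"] = config.simulation
    return out


def _round12(value):
    """Floats rendered at 12 significant digits; infinities as strings."""
    if isinstance(value, float):
        if math.isinf(value) or math.isnan(value):
            return str(value)
        return float(f"{value:.12g}")
    if isinstance(value, dict):
        return {k: _round12(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_round12(v) for v in value]
    return value


def result_to_json(result) -> str:
    """Serialize any solver/simulation result to deterministic JSON text."""
    if isinstance(result, (SolveResult, IntelligenceSolveResult)):
        payload = result.to_dict()
    elif isinstance(result, ReplicateSummary):
        payload = result.to_dict()
    elif isinstance(result, Trajectory):
        payload = {
            "mode": result.mode,
            "states": list(result.states) if result.states is not None else None,
            "extinct_at": list(result.extinct_at),
            "counts": [list(row) for row in result.counts],
        }
    elif isinstance(result, dict):
        payload = result
    else:
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")
    return json.dumps(_round12(payload), indent=2) + "\n"


def write_results(result, path: str | Path, format: str = "json") -> Path:
    """Write a result object to disk as JSON or CSV.

    Trajectories in CSV form mirror the generation-by-policy table layout
    (columns ``generation``, ``state``, then one integer column per policy);
    region maps are written long-format (one row per grid cell).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        path.write_text(result_to_json(result))
        return path
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    if isinstance(result, Trajectory):
        result.to_dataframe().to_csv(path, index=False)
    elif isinstance(result, (RegionMap, CostRegionMap)):
        result.to_dataframe().to_csv(path, index=False)
    else:
        raise TypeError(
            f"CSV output is not defined for {type(result).__name__}; use json"
        )
    return path
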