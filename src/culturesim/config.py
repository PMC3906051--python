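"""Simulation configuration: the single source of truth for all model parameters.

Every knob of the model is a field of :class:`SimulationConfig`, including the
parameters that the published experiments sweep (resource level, selection
differential, innovation/learning costs, interaction radius) and the
demographic/energetic constants that close the model (basic extraction rate,
skill cap, reproduction energetics, mortality, run length).  Configs load from
flat YAML or JSON files; unknown keys are rejected and missing keys take the
documented defaults, so a saved config always round-trips.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimulationConfig", "ConfigError", "load_config", "save_config",
           "FORAGE_MODES"]

# integer codes used by the jitted foraging kernels
FORAGE_MODES = {"needs_first": 0, "to_cap": 1, "to_requirement": 2}


class ConfigError(ValueError):
    """Raised when a configuration file or value set is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one simulation run.

    Units: energy and resources are measured in "resource units"; one time
    step is one year; skills are integer levels 1..``max_skill``.
    """

    # --- world ---
    grid_width: int = 10
    grid_height: int = 10
    n_resource_types: int = 10          # also the maximum trait-list length
    resource_level: float = 50.0        # units per resource type per square
    replenish_mode: str = "reset"       # stocks reset to resource_level each step

    # --- foraging / selection ---
    basic_rate: float = 7.0             # extraction rate of a trait at skill 1
    selection_differential: float = 0.1  # extra rate per one-unit skill increase
    max_skill: int = 10                 # skill cap per trait; gates invention
    energy_cap: float = 50.0            # maximum stored energy per individual
    step_requirement: float = 5.0       # minimum energy requirement per step
    forage_mode: str = "to_cap"         # or "needs_first" / "to_requirement"

    # --- culture ---
    copy_error_prob: float = 0.05       # P(copied value shifts by +-1)
    innovation_cost: float = 10.0       # energy cost of inventing a new trait
    learning_cost: float = 0.0          # energy cost per social learning event
    interaction_radius: int = 1         # 1 = within group, 2 = Moore neighbourhood

    # --- demography ---
    min_repro_age: int = 15             # years
    repro_energy_threshold: float = 20.0  # E_rep: minimum energy to reproduce
    birth_energy_transfer: float = 10.0   # energy each parent gives the newborn
    max_age: int = 60                   # death when age exceeds this
    fission_min_size: int = 10          # smaller pressured groups migrate instead
    pressure_fission_fraction: float = 0.5  # fraction unmet that triggers relocation

    # --- run control ---
    n_steps: int = 1000
    n_runs: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errs: list[str] = []
        if self.grid_width < 1 or self.grid_height < 1:
            errs.append(f"grid dimensions must be >= 1, got "
                        f"{self.grid_width}x{self.grid_height}")
        if self.n_resource_types < 1:
            errs.append("n_resource_types must be >= 1")
        if self.max_skill < 1:
            errs.append("max_skill must be >= 1")
        if not (0.0 <= self.copy_error_prob <= 1.0):
            errs.append(f"copy_error_prob must lie in [0, 1], got "
                        f"{self.copy_error_prob}")
        if self.interaction_radius not in (1, 2):
            errs.append(f"interaction_radius must be 1 (within-group) or 2 "
                        f"(Moore neighbourhood), got {self.interaction_radius}")
        for name in ("resource_level", "basic_rate", "energy_cap",
                     "step_requirement", "innovation_cost", "learning_cost",
                     "repro_energy_threshold", "birth_energy_transfer",
                     "selection_differential"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.resource_level <= self.step_requirement:
            errs.append("resource_level must exceed step_requirement for the "
                        "grid to be habitable")
        if self.forage_mode not in FORAGE_MODES:
            errs.append(f"forage_mode must be one of {sorted(FORAGE_MODES)}, "
                        f"got {self.forage_mode!r}")
        if self.replenish_mode != "reset":
            errs.append(f"replenish_mode 'reset' is the only implemented mode, "
                        f"got {self.replenish_mode!r}")
        if not (0.0 <= self.pressure_fission_fraction <= 1.0):
            errs.append("pressure_fission_fraction must lie in [0, 1]")
        if self.n_steps < 0 or self.n_runs < 1:
            errs.append("n_steps must be >= 0 and n_runs >= 1")
        if self.min_repro_age < 0 or self.max_age < 0 or self.fission_min_size < 1:
            errs.append("ages and fission_min_size must be non-negative")
        if errs:
            raise ConfigError("invalid configuration: " + "; ".join(errs))

    # --- (de)serialization -------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        """The fully resolved parameter set, defaults included."""
        return dataclasses.asdict(self)

    def replace(self, **overrides: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **overrides)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML or JSON configuration file and fill in defaults.

    Unknown keys are rejected; values violating a model invariant raise
    :class:`ConfigError` with a descriptive message.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must contain a mapping of parameter names "
                          f"to values, got {type(data).__name__}")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write the fully resolved config (defaults included) to YAML or JSON."""
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
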