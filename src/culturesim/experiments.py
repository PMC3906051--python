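"""Canned parameter sweeps reproducing the published experiments.

Three sweeps are defined.  ``table1``: four selection differentials x three
resource levels x two interaction regimes at innovation cost 10 and no
learning cost (24 cells).  ``fig1_learningcost``: the same grid with a
learning cost of 1 energy unit per learning event.  ``fig2_innovationcost``:
the table1 grid at innovation costs 10, 20 and 40 (72 cells).  Every cell is
run as ten independent replicates; replicate seeds are derived as
``base_seed + cell_index * n_runs + replicate`` with the cell index taken in
the canonical (unfiltered) sweep order, so any subset of cells is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import pandas as pd

from .config import SimulationConfig
from .engine import run

__all__ = ["Cell", "SWEEPS", "SELECTION_DIFFERENTIALS", "RESOURCE_LEVELS",
           "sweep_cells", "cell_config", "run_cell", "run_sweep"]

SELECTION_DIFFERENTIALS = (0.01, 0.1, 0.5, 1.0)
RESOURCE_LEVELS = (50.0, 100.0, 500.0)
REGIMES = {1: "isolated", 2: "interacting"}


@dataclass(frozen=True)
class Cell:
    """One parameter combination of a sweep."""
    selection_differential: float
    resource_level: float
    interaction_radius: int
    innovation_cost: float = 10.0
    learning_cost: float = 0.0

    @property
    def regime(self) -> str:
        return REGIMES[self.interaction_radius]


def _grid(innovation_costs=(10.0,), learning_cost=0.0) -> list[Cell]:
    return [Cell(d, lv, r, ic, learning_cost)
            for ic in innovation_costs
            for d in SELECTION_DIFFERENTIALS
            for lv in RESOURCE_LEVELS
            for r in (1, 2)]


SWEEPS: dict[str, Callable[[], list[Cell]]] = {
    "table1": lambda: _grid(),
    "fig1_learningcost": lambda: _grid(learning_cost=1.0),
    "fig2_innovationcost": lambda: _grid(innovation_costs=(10.0, 20.0, 40.0)),
}


def sweep_cells(name: str,
                resource_levels: Iterable[float] | None = None
                ) -> list[tuple[int, Cell]]:
    """(canonical index, cell) pairs of a named sweep, optionally filtered
    to a subset of resource levels (indices keep their canonical values)."""
    if name not in SWEEPS:
        raise ValueError(f"unknown sweep {name!r}; choose from "
                         f"{sorted(SWEEPS)}")
    cells = list(enumerate(SWEEPS[name]()))
    if resource_levels is not None:
        keep = {float(lv) for lv in resource_levels}
        cells = [(i, c) for i, c in cells if c.resource_level in keep]
    return cells


def cell_config(cell: Cell,
                base: SimulationConfig | None = None) -> SimulationConfig:
    base = base if base is not None else SimulationConfig()
    return base.replace(selection_differential=cell.selection_differential,
                        resource_level=cell.resource_level,
                        interaction_radius=cell.interaction_radius,
                        innovation_cost=cell.innovation_cost,
                        learning_cost=cell.learning_cost)


def run_cell(cell: Cell, base_seed: int, cell_index: int,
             n_runs: int | None = None, n_steps: int | None = None,
             base: SimulationConfig | None = None) -> pd.DataFrame:
    """Replicate end values of one cell, one row per replicate."""
    cfg = cell_config(cell, base)
    if n_runs is None:
        n_runs = cfg.n_runs
    rows = []
    for rep in range(n_runs):
        seed = base_seed + cell_index * n_runs + rep
        result = run(cfg, seed, n_steps=n_steps)
        rows.append({
            "selection_differential": cell.selection_differential,
            "resource_level": cell.resource_level,
            "regime": cell.regime,
            "innovation_cost": cell.innovation_cost,
            "learning_cost": cell.learning_cost,
            "replicate": rep,
            "seed": seed,
            "extinct": result.extinct,
            "end_step": result.end_values["step"],
            "pop": result.end_values["pop"],
            "n_groups": result.end_values["n_groups"],
            "mean_group_size": result.end_values["mean_group_size"],
            "mean_traits": result.end_values["mean_traits"],
            "competition": result.end_values["competition"],
        })
    return pd.DataFrame(rows)


def run_sweep(name: str, base_seed: int, n_runs: int | None = None,
              n_steps: int | None = None,
              resource_levels: Iterable[float] | None = None,
              base: SimulationConfig | None = None,
              progress: Callable[[Cell], None] | None = None) -> pd.DataFrame:
    """Run a named sweep; returns tidy replicate end values for all cells."""
    frames = []
    for idx, cell in sweep_cells(name, resource_levels):
        if progress is not None:
            progress(cell)
        frames.append(run_cell(cell, base_seed, idx, n_runs=n_runs,
                               n_steps=n_steps, base=base))
    return pd.concat(frames, ignore_index=True)
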