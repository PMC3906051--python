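"""Per-step scheduler and run drivers.

Phase order within one time step (one year):

1. resources replenish (stocks reset to the configured level);
2. the individual processing order is shuffled;
3. unconditional individual processes in that order: metabolism, foraging,
   mortality;
4. conditional individual processes in the same order: one social learning
   attempt then an invention attempt for individuals under pressure, then
   partner search and reproduction for eligible individuals (newborns do
   not act until the next step);
5. group processes: fission or migration of groups under pressure, in group
   id order;
6. observables are recorded and the step counter advances.

A single RNG stream, consumed in scheduled order, makes the whole trajectory
a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels, analysis
from .config import FORAGE_MODES, SimulationConfig, save_config
from .culture import group_histograms, neighbour_group_table
from .demography import fission_or_migrate
from .environment import init_world, replenish_resources
from .state import SimState

__all__ = ["step", "run", "run_replicates", "RunResult", "observables"]

TIMESERIES_COLUMNS = ["step", "pop", "mean_group_size", "mean_traits",
                      "competition", "n_groups"]
EVENT_COLUMNS = ["step", "group_id", "trait_index", "individual_id"]


def observables(state: SimState) -> dict:
    """The per-step observables recorded into the time series."""
    pop = state.population
    ngroups = state.n_groups
    return {
        "step": state.step_count,
        "pop": pop,
        "mean_group_size": pop / ngroups if ngroups else np.nan,
        "mean_traits": analysis.mean_traits(state) if pop else np.nan,
        "competition": analysis.competition(state) if pop else np.nan,
        "n_groups": ngroups,
    }


def step(state: SimState) -> SimState:
    """Advance the state by one time step (phases 1-6 above)."""
    cfg = state.config

    # Compact away dead slots when they dominate; ids are stable, no draws.
    if state.n_slots > 1024 and 4 * state.population < state.n_slots:
        state.compact()

    # (1) resources
    replenish_resources(state)

    # (2) shuffled processing order
    living = state.living_slots()
    order = state.rng.permutation(living) if living.size else living

    # (3) metabolize, forage, resolve deaths
    taken = np.zeros((state.n_slots, cfg.n_resource_types))
    _kernels.forage_phase(
        order, state.alive, state.age, state.energy, state.group,
        state.skills, state.ntraits, state.intake, state.pressure,
        state.group_x, state.group_y, state.gcount, state.stocks, taken,
        cfg.basic_rate, cfg.selection_differential, cfg.energy_cap,
        cfg.step_requirement, cfg.max_age, cfg.max_skill,
        FORAGE_MODES[cfg.forage_mode])

    # groups emptied by mortality disappear
    gtop = state.n_group_slots
    emptied = np.flatnonzero(state.group_alive[:gtop] & (state.gcount[:gtop] == 0))
    for g in emptied:
        state.group_alive[g] = False
        state.occ[state.group_x[g], state.group_y[g]] = -1

    # (4) learning / invention / reproduction, same order
    top = state.n_slots
    survivors = int(state.alive[:top].sum())
    state.ensure_capacity(top + survivors // 2 + 4)

    hist = group_histograms(state)
    table, lengths = neighbour_group_table(state)

    elig_flat, elig_off, elig_cnt, elig_pos = _partner_lists(state)
    paired = np.zeros(state.capacity, dtype=np.bool_)
    ev_cap = survivors + 8
    ev_id = np.zeros(ev_cap, dtype=np.int64)
    ev_group = np.zeros(ev_cap, dtype=np.int32)
    ev_trait = np.zeros(ev_cap, dtype=np.int32)

    new_top, n_ev = _kernels.learn_repro_phase(
        order, state.alive, state.sex, state.age, state.energy, state.group,
        state.skills, state.ntraits, state.intake, state.pressure, paired, state.ids,
        state.gcount, hist, table, lengths,
        elig_flat, elig_off, elig_cnt, elig_pos,
        ev_id, ev_group, ev_trait, top,
        cfg.copy_error_prob, cfg.max_skill, cfg.n_resource_types,
        cfg.learning_cost, cfg.innovation_cost, cfg.min_repro_age,
        cfg.repro_energy_threshold, cfg.birth_energy_transfer,
        cfg.energy_cap, state.rng)

    n_births = int(new_top) - top
    if n_births:
        state.ids[top:new_top] = np.arange(state.next_id,
                                           state.next_id + n_births)
        state.next_id += n_births
        state.n_slots = int(new_top)

    this_step = state.step_count + 1
    for e in range(int(n_ev)):
        state.event_log.append((this_step, int(ev_group[e]),
                                int(ev_trait[e]), int(ev_id[e])))

    # (5) group relocation, in stable group id order (groups created by a
    # fission this step are not re-evaluated)
    for g in state.living_groups():
        fission_or_migrate(state, int(g))

    # (6)
    state.step_count += 1
    return state


def _partner_lists(state: SimState):
    """Swap-removable per-(group, sex) lists of partner-eligible individuals."""
    cfg = state.config
    top = state.n_slots
    living = state.living_slots()
    mask = ((state.age[living] >= cfg.min_repro_age)
            & (state.energy[living] >= cfg.repro_energy_threshold))
    cand = living[mask]
    keys = state.group[cand].astype(np.int64) * 2 + state.sex[cand]
    nkeys = 2 * max(state.n_group_slots, 1)
    order = np.argsort(keys, kind="stable")
    elig_flat = cand[order].astype(np.int64)
    cnts = np.bincount(keys, minlength=nkeys).astype(np.int64)
    elig_off = np.concatenate([[0], np.cumsum(cnts)]).astype(np.int64)
    elig_pos = np.full(top, -1, dtype=np.int64)
    elig_pos[elig_flat] = np.arange(elig_flat.size)
    return elig_flat, elig_off, cnts, elig_pos


@dataclass
class RunResult:
    """Everything one run produces: config, trajectory, events, end values."""
    config: SimulationConfig
    seed: int
    timeseries: pd.DataFrame       # TIMESERIES_COLUMNS, one row per step
    events: pd.DataFrame           # innovation events, EVENT_COLUMNS
    end_values: dict               # observables at the last living step
    extinct: bool

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.timeseries.to_csv(outdir / "timeseries.csv", index=False)
        self.events.to_csv(outdir / "events.csv", index=False)
        (outdir / "end_values.json").write_text(
            json.dumps({k: (None if v is None or (isinstance(v, float) and np.isnan(v)) else v)
                        for k, v in {**self.end_values, "seed": self.seed,
                                     "extinct": self.extinct}.items()},
                       indent=2) + "\n")
        save_config(self.config, outdir / "config.resolved.json")
        return outdir


def run(config: SimulationConfig, seed: int,
        n_steps: int | None = None) -> RunResult:
    """Execute one run of ``n_steps`` steps (default from the config).

    Observables are recorded for the initial state (step 0) and after every
    step.  If the population goes extinct the run stops early, is flagged,
    and end values are taken at the last step with a living population.
    """
    if n_steps is None:
        n_steps = config.n_steps
    state = init_world(config, seed)
    rows = [observables(state)]
    extinct = False
    for _ in range(n_steps):
        step(state)
        obs = observables(state)
        rows.append(obs)
        if obs["pop"] == 0:
            extinct = True
            break
    ts = pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)
    events = pd.DataFrame(state.event_log or None, columns=EVENT_COLUMNS)
    living_rows = ts[ts["pop"] > 0]
    end = (living_rows.iloc[-1] if len(living_rows) else ts.iloc[-1]).to_dict()
    end["step"] = int(end["step"])
    end["pop"] = int(end["pop"])
    end["n_groups"] = int(end["n_groups"])
    return RunResult(config=config, seed=seed, timeseries=ts, events=events,
                     end_values=end, extinct=extinct)


def run_replicates(config: SimulationConfig, base_seed: int,
                   n_runs: int | None = None,
                   n_steps: int | None = None) -> list[RunResult]:
    """Independent replicate runs with seeds base_seed .. base_seed+n-1."""
    if n_runs is None:
        n_runs = config.n_runs
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    return [run(config, base_seed + r, n_steps=n_steps) for r in range(n_runs)]
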