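"""Individual energy budget: extraction rate, metabolism, foraging, death.

These are thin, testable wrappers over the jitted per-individual kernels;
the engine's unconditional phase loops over the same kernels, so the
semantics exercised here are exactly the semantics of a full run.
"""

from __future__ import annotations

import numpy as np

from .config import FORAGE_MODES
from .state import SimState
from . import _kernels

__all__ = ["extraction_rate", "metabolize", "forage", "check_death"]


def extraction_rate(basic_rate: float, selection_differential: float,
                    skill: int) -> float:
    """Per-step extraction rate of one trait: basic_rate + sd * (skill - 1).

    At skill 1 the rate is the basic rate; the selection differential is the
    increase per one-unit increase in skill, so the rate is strictly
    increasing in skill whenever the differential is positive.
    """
    if skill < 1:
        raise ValueError(f"skill must be >= 1, got {skill}")
    return basic_rate + selection_differential * (skill - 1)


def metabolize(state: SimState, i: int) -> bool:
    """Pay the per-step requirement and age one year.

    Energy is floored at zero; returns True if the individual could not pay
    the full requirement from its store (starvation mark — it will die this
    step unless foraging lifts it above zero).
    """
    cfg = state.config
    return bool(_kernels.metabolize_one(i, state.energy, state.age,
                                        cfg.step_requirement))


def forage(state: SimState, i: int) -> float:
    """Forage on the individual's own square; returns the realized intake.

    Owned traits are visited in descending order of current extraction rate
    (ties broken by trait index); each consumes min(per-step rate, remaining
    stock, storage headroom).  In the default needs-first mode the
    individual first secures the per-step requirement, then fills its store
    toward the cap.  Sets ``under_pressure`` iff the realized intake fell
    short of the per-step requirement.
    """
    cfg = state.config
    g = int(state.group[i])
    taken = np.zeros(cfg.n_resource_types)
    return float(_kernels.forage_one(
        i, state.group_x[g], state.group_y[g], state.energy, state.skills,
        state.ntraits, state.stocks, state.intake, state.pressure,
        cfg.basic_rate, cfg.selection_differential, cfg.energy_cap,
        cfg.step_requirement, cfg.max_skill, FORAGE_MODES[cfg.forage_mode],
        taken))


def check_death(state: SimState, i: int) -> bool:
    """Resolve mortality; returns True iff the individual stays alive.

    Death on starvation (energy <= 0 after foraging) or when age exceeds the
    maximum; the dead individual is removed from its group.
    """
    cfg = state.config
    if state.energy[i] <= 0.0 or state.age[i] > cfg.max_age:
        state.alive[i] = False
        state.gcount[state.group[i]] -= 1
        return False
    return True
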