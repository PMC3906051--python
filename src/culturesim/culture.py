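"""Cultural transmission and innovation.

Two innovation channels exist.  Modification innovation is the +-1 copying
error applied to every transmitted skill value: it is the only source of new
skill values in the population.  Independent innovation is the invention of
the next trait in the list, gated on mastery (maximum skill) of the last
owned trait and paid for in energy.  Both social learning and invention are
triggered only by resource pressure, at most one attempt per individual per
step, with learning tried before inventing.
"""

from __future__ import annotations

import numpy as np

from .environment import moore_neighbours
from .state import SimState
from . import _kernels

__all__ = ["copy_with_error", "vertical_transmission", "find_cultural_models",
           "social_learning_event", "attempt_invention",
           "group_histograms", "neighbour_group_table"]


def copy_with_error(value: int, config, rng: np.random.Generator) -> int:
    """Copy one skill value: unchanged with probability 1 - p, else +-1
    (equiprobable), clamped to [1, max_skill]."""
    if not (1 <= value <= config.max_skill):
        raise ValueError(f"skill value {value} outside [1, {config.max_skill}]")
    return int(_kernels.copy_with_error(value, config.copy_error_prob,
                                        config.max_skill, rng))


def vertical_transmission(state: SimState, mother: int, father: int) -> np.ndarray:
    """Newborn trait vector learned from the parents.

    The newborn holds the prefix of length min(k_mother, k_father) — the
    longest trait list both parents can teach — and each value is copied
    from a uniformly chosen parent through the copy error.
    """
    cfg = state.config
    n = cfg.n_resource_types
    skills = np.zeros((1, n), dtype=state.skills.dtype)
    ntraits = np.zeros(1, dtype=state.ntraits.dtype)
    # transmit into a scratch row, then return the trimmed vector
    buf_skills = np.vstack([state.skills[[mother, father]], skills])
    buf_ntraits = np.concatenate([state.ntraits[[mother, father]], ntraits])
    _kernels.transmit_vertical(2, 0, 1, buf_skills, buf_ntraits,
                               cfg.copy_error_prob, cfg.max_skill, state.rng)
    k = int(buf_ntraits[2])
    return buf_skills[2, :k].copy()


def find_cultural_models(state: SimState, learner: int) -> np.ndarray:
    """Slots of all potential cultural models of ``learner``.

    All living members of the learner's own group (excluding the learner),
    plus members of groups on Moore-neighbouring squares iff the interaction
    radius is 2.
    """
    g = int(state.group[learner])
    groups = [g]
    if state.config.interaction_radius == 2:
        shape = (state.config.grid_width, state.config.grid_height)
        for nx, ny in moore_neighbours((int(state.group_x[g]),
                                        int(state.group_y[g])), shape):
            og = int(state.occ[nx, ny])
            if og >= 0:
                groups.append(og)
    top = state.n_slots
    mask = state.alive[:top] & np.isin(state.group[:top], groups)
    mask[learner] = False
    return np.flatnonzero(mask)


def group_histograms(state: SimState) -> np.ndarray:
    """hist[g, t, v]: living members of group g holding trait t at value v."""
    cfg = state.config
    hist = np.zeros((state.n_group_slots, cfg.n_resource_types,
                     cfg.max_skill + 1), dtype=np.int32)
    _kernels.build_hists(state.living_slots(), state.alive, state.group,
                         state.skills, state.ntraits, hist)
    return hist


def neighbour_group_table(state: SimState) -> tuple[np.ndarray, np.ndarray]:
    """Per-group candidate-group lists for learning and partner search.

    Row g lists group g itself followed by the groups occupying its Moore
    neighbourhood when the interaction radius is 2 (within-group only at
    radius 1).  Returns (table, lengths).
    """
    cfg = state.config
    gtop = state.n_group_slots
    table = np.full((max(gtop, 1), 9), -1, dtype=np.int32)
    lengths = np.zeros(max(gtop, 1), dtype=np.int32)
    shape = (cfg.grid_width, cfg.grid_height)
    for g in state.living_groups():
        lst = [g]
        if cfg.interaction_radius == 2:
            for nx, ny in moore_neighbours((int(state.group_x[g]),
                                            int(state.group_y[g])), shape):
                og = int(state.occ[nx, ny])
                if og >= 0:
                    lst.append(og)
        table[g, :len(lst)] = lst
        lengths[g] = len(lst)
    return table, lengths


def social_learning_event(state: SimState, learner: int) -> bool:
    """One social learning attempt; returns True iff something was learned.

    Preference order: acquire the next trait from a model holding it, else
    improve an owned trait some model is strictly better at (copying the
    best model value).  On success the learning cost is deducted.  Fails if
    no eligible model exists or energy does not exceed the learning cost.
    """
    cfg = state.config
    # histograms include the learner; the kernel excludes it where it matters
    hist = group_histograms(state)
    table, lengths = neighbour_group_table(state)
    learned = bool(_kernels.learn_one(
        learner, int(state.group[learner]), state.skills, state.ntraits,
        state.energy, hist, table, lengths, cfg.copy_error_prob,
        cfg.max_skill, cfg.n_resource_types, cfg.learning_cost, state.rng))
    return learned


def attempt_invention(state: SimState, individual: int) -> bool:
    """Invent the next trait iff the last owned trait is at maximum skill,
    the trait list is not exhausted, and energy exceeds the innovation cost.

    On success the new trait starts at skill 1, the cost is deducted, and
    the event is appended to the state's innovation log.
    """
    cfg = state.config
    hist = np.zeros((state.n_group_slots, cfg.n_resource_types,
                     cfg.max_skill + 1), dtype=np.int32)
    g = int(state.group[individual])
    invented = bool(_kernels.invent_one(
        individual, g, state.skills, state.ntraits, state.energy, hist,
        cfg.max_skill, cfg.n_resource_types, cfg.innovation_cost))
    if invented:
        state.event_log.append((state.step_count, g,
                                int(state.ntraits[individual]),
                                int(state.ids[individual])))
    return invented
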