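"""Reproduction, partner search, and group-level responses to pressure.

Reproduction is sexual and energy-gated: both partners must be of
reproductive age and hold at least the reproduction energy threshold, and
each transfers a fixed energy amount to the newborn, which links the birth
rate to resource availability.  Pairing is monogamous within a step with one
offspring per pair.  Groups in which more than half the members went hungry
relocate: large groups fission onto an empty neighbouring square, small ones
migrate whole to a richer empty neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import moore_neighbours
from .state import FEMALE, SimState
from . import _kernels

__all__ = ["GroupPressure", "find_partner", "reproduce", "group_pressure",
           "fission_or_migrate"]


@dataclass(frozen=True)
class GroupPressure:
    group_id: int
    fraction_unmet: float        # members under pressure / members


def _eligible(state: SimState, i: int) -> bool:
    cfg = state.config
    return (bool(state.alive[i]) and state.age[i] >= cfg.min_repro_age
            and state.energy[i] >= cfg.repro_energy_threshold)


def find_partner(state: SimState, i: int,
                 paired: np.ndarray | None = None) -> int | None:
    """Uniformly random eligible partner for individual ``i``, or None.

    Candidates are of the opposite sex, of reproductive age, at or above the
    reproduction energy threshold and not already paired this step; the
    search covers the individual's own group, extended to groups on
    Moore-neighbouring squares iff the interaction radius is 2.
    """
    cfg = state.config
    g = int(state.group[i])
    groups = [g]
    if cfg.interaction_radius == 2:
        shape = (cfg.grid_width, cfg.grid_height)
        for nx, ny in moore_neighbours((int(state.group_x[g]),
                                        int(state.group_y[g])), shape):
            og = int(state.occ[nx, ny])
            if og >= 0:
                groups.append(og)
    cands = []
    for g2 in groups:
        for j in state.group_members(g2):
            if j == i or state.sex[j] == state.sex[i]:
                continue
            if paired is not None and paired[j]:
                continue
            if _eligible(state, int(j)):
                cands.append(int(j))
    if not cands:
        return None
    return cands[int(state.rng.integers(0, len(cands)))]


def reproduce(state: SimState, mother: int, father: int) -> int:
    """Create a newborn of the pair; returns its slot.

    The newborn starts at age 0 with twice the per-parent energy transfer,
    uniform sex, and a trait vector from vertical transmission; it joins the
    mother's group and does not act until the next step.
    """
    cfg = state.config
    state.ensure_capacity(state.n_slots + 1)
    nb = state.n_slots
    _kernels.reproduce_pair(mother, father, nb, state.sex, state.age,
                            state.energy, state.group, state.skills,
                            state.ntraits, state.intake, state.pressure,
                            state.alive, cfg.birth_energy_transfer,
                            cfg.energy_cap, cfg.copy_error_prob,
                            cfg.max_skill, state.gcount, state.rng)
    state.n_slots += 1
    state.ids[nb] = state.next_id
    state.next_id += 1
    return nb


def group_pressure(state: SimState, g: int) -> GroupPressure:
    """Fraction of the group's members that went hungry this step."""
    members = state.group_members(g)
    if members.size == 0:
        raise ValueError(f"group {g} has no members")
    frac = float(state.pressure[members].mean())
    return GroupPressure(group_id=g, fraction_unmet=frac)


def fission_or_migrate(state: SimState, g: int) -> None:
    """Group-level response when more than half the members went hungry.

    (i) A group at or above the fission threshold with an empty Moore
    neighbour splits: a uniformly random half of the members founds a new
    group on the empty neighbour with the highest total stocks.  (ii) A
    smaller group migrates whole to an empty neighbour with higher total
    stocks than its current square, if one exists.  Ties among target
    squares are broken uniformly.  Population is conserved either way.
    """
    cfg = state.config
    members = state.group_members(g)
    if members.size == 0:
        return
    frac = float(state.pressure[members].mean())
    if frac <= cfg.pressure_fission_fraction:
        return
    x, y = int(state.group_x[g]), int(state.group_y[g])
    shape = (cfg.grid_width, cfg.grid_height)
    empty = [(nx, ny) for nx, ny in moore_neighbours((x, y), shape)
             if state.occ[nx, ny] < 0]
    if not empty:
        return
    totals = np.array([state.stocks[nx, ny].sum() for nx, ny in empty])
    if members.size >= cfg.fission_min_size:
        best = totals.max()
        cands = [sq for sq, tot in zip(empty, totals) if tot >= best - 1e-9]
        nx, ny = cands[int(state.rng.integers(0, len(cands)))]
        new_g = state.add_group(nx, ny)
        movers = state.rng.permutation(members)[:members.size // 2]
        state.group[movers] = new_g
        state.gcount[g] -= movers.size
        state.gcount[new_g] += movers.size
    else:
        here = state.stocks[x, y].sum()
        richer = [(sq, tot) for sq, tot in zip(empty, totals) if tot > here]
        if not richer:
            return
        best = max(tot for _, tot in richer)
        cands = [sq for sq, tot in richer if tot >= best - 1e-9]
        nx, ny = cands[int(state.rng.integers(0, len(cands)))]
        state.occ[x, y] = -1
        state.occ[nx, ny] = g
        state.group_x[g] = nx
        state.group_y[g] = ny
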