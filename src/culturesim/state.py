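"""Simulation state: grid, groups and individuals in struct-of-arrays form.

The population lives in preallocated numpy arrays indexed by *slot*; slots are
append-only between compactions, and every individual additionally carries a
stable ``id`` that survives compaction.  ``Individual``, ``Group`` and
``Square`` are lightweight read-only views for inspection and testing; all
mutation goes through the engine and the operation modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig

__all__ = ["SimState", "Individual", "Group", "Square", "FEMALE", "MALE"]

FEMALE = 0
MALE = 1


@dataclass(frozen=True)
class Individual:
    """Read-only view of one agent."""
    id: int
    sex: int
    age: int
    energy: float
    group_id: int
    skills: np.ndarray           # prefix trait vector, length k, values 1..max_skill
    intake_this_step: float
    under_pressure: bool


@dataclass(frozen=True)
class Group:
    id: int
    coords: tuple[int, int]
    member_ids: np.ndarray       # stable individual ids


@dataclass(frozen=True)
class Square:
    coords: tuple[int, int]
    stocks: np.ndarray           # one stock per resource type
    occupant_group: int | None


class SimState:
    """Full mutable state of one run.

    Attributes of interest: ``stocks`` (width x height x n_resource_types),
    ``occ`` (group slot per square, -1 if empty), the per-individual arrays
    (``alive``, ``sex``, ``age``, ``energy``, ``group``, ``skills``,
    ``ntraits``, ``intake``, ``pressure``, ``ids``), ``rng`` (the single
    Generator every stochastic phase draws from), ``step_count`` and
    ``event_log`` (innovation events as (step, group_id, trait_index,
    individual_id) tuples).
    """

    def __init__(self, config: SimulationConfig, rng: np.random.Generator,
                 capacity: int = 1024, group_capacity: int = 64):
        self.config = config
        self.rng = rng
        self.step_count = 0
        self.event_log: list[tuple[int, int, int, int]] = []

        w, h, t = config.grid_width, config.grid_height, config.n_resource_types
        self.stocks = np.full((w, h, t), float(config.resource_level))
        self.occ = np.full((w, h), -1, dtype=np.int32)

        self.capacity = capacity
        self.n_slots = 0
        self.next_id = 0
        self.ids = np.zeros(capacity, dtype=np.int64)
        self.alive = np.zeros(capacity, dtype=np.bool_)
        self.sex = np.zeros(capacity, dtype=np.int8)
        self.age = np.zeros(capacity, dtype=np.int16)
        self.energy = np.zeros(capacity, dtype=np.float64)
        self.group = np.zeros(capacity, dtype=np.int32)
        self.skills = np.zeros((capacity, t), dtype=np.int16)
        self.ntraits = np.zeros(capacity, dtype=np.int16)
        self.intake = np.zeros(capacity, dtype=np.float64)
        self.pressure = np.zeros(capacity, dtype=np.bool_)

        self.group_capacity = group_capacity
        self.n_group_slots = 0
        self.group_alive = np.zeros(group_capacity, dtype=np.bool_)
        self.group_x = np.zeros(group_capacity, dtype=np.int32)
        self.group_y = np.zeros(group_capacity, dtype=np.int32)
        self.gcount = np.zeros(group_capacity, dtype=np.int32)

    # --- capacity management ----------------------------------------------

    _IND_ARRAYS = ("ids", "alive", "sex", "age", "energy", "group",
                   "skills", "ntraits", "intake", "pressure")

    def ensure_capacity(self, n: int) -> None:
        if n <= self.capacity:
            return
        new_cap = max(n, 2 * self.capacity)
        for name in self._IND_ARRAYS:
            arr = getattr(self, name)
            shape = (new_cap,) + arr.shape[1:]
            new = np.zeros(shape, dtype=arr.dtype)
            new[:self.n_slots] = arr[:self.n_slots]
            setattr(self, name, new)
        self.capacity = new_cap

    def ensure_group_capacity(self, n: int) -> None:
        if n <= self.group_capacity:
            return
        new_cap = max(n, 2 * self.group_capacity)
        for name in ("group_alive", "group_x", "group_y", "gcount"):
            arr = getattr(self, name)
            new = np.zeros(new_cap, dtype=arr.dtype)
            new[:self.n_group_slots] = arr[:self.n_group_slots]
            setattr(self, name, new)
        self.group_capacity = new_cap

    def compact(self) -> None:
        """Drop dead slots; stable ids are preserved, slot indices are not."""
        keep = np.flatnonzero(self.alive[:self.n_slots])
        for name in self._IND_ARRAYS:
            arr = getattr(self, name)
            shape = (self.capacity,) + arr.shape[1:]
            new = np.zeros(shape, dtype=arr.dtype)
            new[:keep.size] = arr[keep]
            setattr(self, name, new)
        self.n_slots = int(keep.size)

    # --- creation ----------------------------------------------------------

    def add_group(self, x: int, y: int) -> int:
        if self.occ[x, y] != -1:
            raise ValueError(f"square ({x},{y}) already occupied")
        self.ensure_group_capacity(self.n_group_slots + 1)
        g = self.n_group_slots
        self.n_group_slots += 1
        self.group_alive[g] = True
        self.group_x[g] = x
        self.group_y[g] = y
        self.gcount[g] = 0
        self.occ[x, y] = g
        return g

    def add_individual(self, sex: int, age: int, energy: float, group: int,
                       skills: np.ndarray) -> int:
        self.ensure_capacity(self.n_slots + 1)
        i = self.n_slots
        self.n_slots += 1
        self.ids[i] = self.next_id
        self.next_id += 1
        self.alive[i] = True
        self.sex[i] = sex
        self.age[i] = age
        self.energy[i] = energy
        self.group[i] = group
        skills = np.asarray(skills)
        self.skills[i, :] = 0
        self.skills[i, :skills.size] = skills
        self.ntraits[i] = skills.size
        self.intake[i] = 0.0
        self.pressure[i] = False
        self.gcount[group] += 1
        return i

    # --- queries ------------------------------------------------------------

    def living_slots(self) -> np.ndarray:
        return np.flatnonzero(self.alive[:self.n_slots])

    @property
    def population(self) -> int:
        return int(self.alive[:self.n_slots].sum())

    @property
    def n_groups(self) -> int:
        return int(self.group_alive[:self.n_group_slots].sum())

    def living_groups(self) -> np.ndarray:
        return np.flatnonzero(self.group_alive[:self.n_group_slots])

    def group_members(self, g: int) -> np.ndarray:
        """Slots of living members of group ``g``."""
        top = self.n_slots
        return np.flatnonzero(self.alive[:top] & (self.group[:top] == g))

    # --- views ---------------------------------------------------------------

    def individual(self, i: int) -> Individual:
        k = int(self.ntraits[i])
        return Individual(
            id=int(self.ids[i]), sex=int(self.sex[i]), age=int(self.age[i]),
            energy=float(self.energy[i]), group_id=int(self.group[i]),
            skills=self.skills[i, :k].copy(),
            intake_this_step=float(self.intake[i]),
            under_pressure=bool(self.pressure[i]),
        )

    def group_view(self, g: int) -> Group:
        members = self.group_members(g)
        return Group(id=g, coords=(int(self.group_x[g]), int(self.group_y[g])),
                     member_ids=self.ids[members].copy())

    def square(self, x: int, y: int) -> Square:
        og = int(self.occ[x, y])
        return Square(coords=(x, y), stocks=self.stocks[x, y].copy(),
                      occupant_group=None if og < 0 else og)

    # --- consistency ----------------------------------------------------------

    def check_invariants(self) -> None:
        """Raise AssertionError if any structural invariant is violated."""
        cfg = self.config
        top = self.n_slots
        live = self.living_slots()
        assert len(set(self.ids[live].tolist())) == live.size, "duplicate ids"
        e = self.energy[live]
        assert np.all((e >= 0) & (e <= cfg.energy_cap + 1e-9)), "energy bounds"
        assert np.all(self.stocks >= -1e-9), "negative stocks"
        assert np.all(self.stocks <= cfg.resource_level + 1e-9), "stocks above level"
        for i in live:
            k = int(self.ntraits[i])
            assert 1 <= k <= cfg.n_resource_types, "trait count out of range"
            vals = self.skills[i, :k]
            assert np.all((vals >= 1) & (vals <= cfg.max_skill)), "skill bounds"
            assert np.all(self.skills[i, k:] == 0), "trait set is not a prefix"
            g = int(self.group[i])
            assert self.group_alive[g], "member of dead group"
        gs = self.living_groups()
        sizes = np.array([self.group_members(g).size for g in gs], dtype=int)
        assert np.array_equal(sizes, self.gcount[gs]), "group size ledger"
        assert sizes.sum() == live.size, "population != sum of group sizes"
        occupied = [(int(self.group_x[g]), int(self.group_y[g])) for g in gs]
        assert len(set(occupied)) == len(occupied), "two groups on one square"
        for g in gs:
            assert self.occ[self.group_x[g], self.group_y[g]] == g, "occupancy map"
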