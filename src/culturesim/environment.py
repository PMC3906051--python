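"""World setup and per-step resource dynamics.

The habitat is a bounded rectangular grid (no wraparound); every square holds
one stock per resource type.  Stocks are a renewable flow: they reset to the
configured resource level at the start of every step, so depletion is a
within-step constraint that individuals on the same square compete over.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .state import FEMALE, MALE, SimState

__all__ = ["init_world", "replenish_resources", "moore_neighbours",
           "FOUNDING_GROUP_SIZE", "FOUNDER_AGE_RANGE", "FOUNDER_ENERGY"]

FOUNDING_GROUP_SIZE = 20
FOUNDER_AGE_RANGE = (15, 30)     # inclusive, uniform
FOUNDER_ENERGY = 25.0


def moore_neighbours(coords: tuple[int, int],
                     grid_shape: tuple[int, int]) -> list[tuple[int, int]]:
    """The <= 8 squares surrounding ``coords``; grid edges are absorbing."""
    x, y = coords
    w, h = grid_shape
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"coords {coords} outside {w}x{h} grid")
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            nx, ny = x + dx, y + dy
            if 0 <= nx < w and 0 <= ny < h:
                out.append((nx, ny))
    return out


def init_world(config: SimulationConfig, seed: int) -> SimState:
    """Fresh world: full stocks everywhere and one founding group of 20.

    Founders are placed on a uniformly random square with balanced sexes,
    ages uniform on 15..30, energy 25 and a single trait (trait 1 at skill
    1).  The returned state carries the run's only RNG, seeded here, so the
    whole trajectory is reproducible from (config, seed).
    """
    rng = np.random.default_rng(seed)
    state = SimState(config, rng)
    x = int(rng.integers(0, config.grid_width))
    y = int(rng.integers(0, config.grid_height))
    g = state.add_group(x, y)
    lo, hi = FOUNDER_AGE_RANGE
    ages = rng.integers(lo, hi + 1, size=FOUNDING_GROUP_SIZE)
    for i in range(FOUNDING_GROUP_SIZE):
        sex = FEMALE if i % 2 == 0 else MALE
        state.add_individual(sex=sex, age=int(ages[i]), energy=FOUNDER_ENERGY,
                             group=g, skills=np.array([1], dtype=np.int16))
    return state


def replenish_resources(state: SimState) -> SimState:
    """Reset every stock of every square to the configured resource level."""
    state.stocks[...] = float(state.config.resource_level)
    return state
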