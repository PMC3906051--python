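"""Shared fixtures: small configs and hand-built states."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from culturesim import SimulationConfig
from culturesim.state import SimState

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def config():
    """Small deterministic default configuration for unit tests."""
    return SimulationConfig(n_steps=50, n_runs=2)


@pytest.fixture
def make_state():
    """Factory for hand-built states.

    ``groups`` is a list of (x, y) coordinates; ``individuals`` a list of
    dicts with keys sex, age, energy, group, skills.
    """

    def _make(config=None, seed=0, groups=((0, 0),), individuals=()):
        config = config or SimulationConfig()
        state = SimState(config, np.random.default_rng(seed))
        for x, y in groups:
            state.add_group(x, y)
        for ind in individuals:
            state.add_individual(
                sex=ind.get("sex", 0), age=ind.get("age", 20),
                energy=ind.get("energy", 25.0), group=ind.get("group", 0),
                skills=np.asarray(ind.get("skills", [1]), dtype=np.int16))
        return state

    return _make
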