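"""Cultural transmission: copy error, vertical/oblique learning, invention."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from culturesim import (SimulationConfig, attempt_invention, copy_with_error,
                        find_cultural_models, social_learning_event,
                        vertical_transmission)


class TestCopyWithError:
    def test_identity_when_error_free(self):
        cfg = SimulationConfig(copy_error_prob=0.0)
        rng = np.random.default_rng(0)
        assert all(copy_with_error(v, cfg, rng) == v for v in range(1, 11))

    def test_error_law_frequencies(self):
        """~5% of copies shift by one unit, split evenly up and down."""
        cfg = SimulationConfig()
        rng = np.random.default_rng(42)
        n = 100_000
        draws = np.array([copy_with_error(3, cfg, rng) for _ in range(n)])
        freq = {v: (draws == v).mean() for v in (2, 3, 4)}
        # binomial 99.9% intervals at n = 1e5
        assert freq[3] == pytest.approx(0.95, abs=0.0033)
        assert freq[2] == pytest.approx(0.025, abs=0.0023)
        assert freq[4] == pytest.approx(0.025, abs=0.0023)
        assert set(np.unique(draws)) <= {2, 3, 4}

    def test_clamped_at_boundaries(self):
        cfg = SimulationConfig(copy_error_prob=1.0)
        rng = np.random.default_rng(1)
        lows = {copy_with_error(1, cfg, rng) for _ in range(200)}
        highs = {copy_with_error(10, cfg, rng) for _ in range(200)}
        assert lows == {1, 2}
        assert highs == {9, 10}

    @given(v=st.integers(1, 10), seed=st.integers(0, 2**20),
           p=st.floats(0.0, 1.0))
    @settings(max_examples=80, deadline=None)
    def test_stays_within_one_unit_and_bounds(self, v, seed, p):
        cfg = SimulationConfig(copy_error_prob=p)
        out = copy_with_error(v, cfg, np.random.default_rng(seed))
        assert abs(out - v) <= 1
        assert 1 <= out <= cfg.max_skill


class TestVerticalTransmission:
    def test_child_trait_count_is_parental_minimum(self, make_state):
        cfg = SimulationConfig(copy_error_prob=0.0)
        stt = make_state(config=cfg,
                         individuals=[{"skills": [3, 2]}, {"skills": [4]}])
        child = vertical_transmission(stt, 0, 1)
        assert child.size == 1
        assert child[0] in (3, 4)

    def test_identical_parents_no_error(self, make_state):
        cfg = SimulationConfig(copy_error_prob=0.0)
        stt = make_state(config=cfg,
                         individuals=[{"skills": [5, 5, 5]}] * 2)
        assert np.array_equal(vertical_transmission(stt, 0, 1), [5, 5, 5])

    def test_error_prob_one_always_shifts(self, make_state):
        cfg = SimulationConfig(copy_error_prob=1.0)
        stt = make_state(config=cfg,
                         individuals=[{"skills": [5, 5, 5]}] * 2)
        child = vertical_transmission(stt, 0, 1)
        assert all(v in (4, 6) for v in child)


class TestFindCulturalModels:
    def test_isolated_singleton_has_no_models(self, make_state):
        stt = make_state(individuals=[{"skills": [1]}])
        assert find_cultural_models(stt, 0).size == 0

    def test_radius_one_excludes_other_squares(self, make_state):
        cfg = SimulationConfig(interaction_radius=1)
        stt = make_state(config=cfg, groups=[(4, 4), (4, 5)],
                         individuals=[{"group": 0}, {"group": 0},
                                      {"group": 1}])
        assert set(find_cultural_models(stt, 0)) == {1}

    def test_radius_two_includes_moore_neighbours_only(self, make_state):
        cfg = SimulationConfig(interaction_radius=2)
        stt = make_state(config=cfg, groups=[(4, 4), (4, 5), (7, 7)],
                         individuals=[{"group": 0}, {"group": 0},
                                      {"group": 1}, {"group": 2}])
        assert set(find_cultural_models(stt, 0)) == {1, 2}


class TestSocialLearning:
    def test_acquires_next_trait_from_model(self, make_state):
        cfg = SimulationConfig(copy_error_prob=0.0, max_skill=10)
        stt = make_state(config=cfg,
                         individuals=[{"skills": [10], "energy": 30.0},
                                      {"skills": [10, 4], "energy": 30.0}])
        assert social_learning_event(stt, 0) is True
        assert stt.ntraits[0] == 2
        assert stt.skills[0, 1] == 4

    def test_no_superior_model_fails(self, make_state):
        cfg = SimulationConfig(copy_error_prob=0.0)
        stt = make_state(config=cfg,
                         individuals=[{"skills": [3], "energy": 30.0},
                                      {"skills": [3], "energy": 30.0},
                                      {"skills": [2], "energy": 30.0}])
        assert social_learning_event(stt, 0) is False
        assert stt.ntraits[0] == 1 and stt.skills[0, 0] == 3

    def test_learning_cost_deducted_on_success(self, make_state):
        cfg = SimulationConfig(copy_error_prob=0.0, learning_cost=1.0)
        stt = make_state(config=cfg,
                         individuals=[{"skills": [10], "energy": 30.0},
                                      {"skills": [10, 4], "energy": 30.0}])
        assert social_learning_event(stt, 0) is True
        assert stt.energy[0] == pytest.approx(29.0)

    def test_insufficient_energy_blocks_learning(self, make_state):
        cfg = SimulationConfig(copy_error_prob=0.0, learning_cost=1.0)
        stt = make_state(config=cfg,
                         individuals=[{"skills": [10], "energy": 1.0},
                                      {"skills": [10, 4], "energy": 30.0}])
        assert social_learning_event(stt, 0) is False

    def test_improvement_copies_a_model_value(self, make_state):
        # learner 3, single other model 7: gate passes, value copied is 7
        cfg = SimulationConfig(copy_error_prob=0.0)
        stt = make_state(config=cfg,
                         individuals=[{"skills": [3], "energy": 30.0},
                                      {"skills": [7], "energy": 30.0}])
        assert social_learning_event(stt, 0) is True
        assert stt.skills[0, 0] == 7

    def test_improvement_value_within_error_of_a_model(self, make_state):
        """The learned value is within +-1 of some model's value."""
        cfg = SimulationConfig()
        for seed in range(30):
            stt = make_state(config=cfg, seed=seed,
                             individuals=[{"skills": [3], "energy": 30.0},
                                          {"skills": [7], "energy": 30.0},
                                          {"skills": [5], "energy": 30.0}])
            assert social_learning_event(stt, 0) is True
            assert int(stt.skills[0, 0]) in {4, 5, 6, 7, 8}


class TestInvention:
    def test_invention_requires_mastery_of_last_trait(self, make_state):
        stt = make_state(individuals=[{"skills": [7], "energy": 30.0}])
        assert attempt_invention(stt, 0) is False
        assert stt.ntraits[0] == 1

    def test_successful_invention(self, make_state):
        cfg = SimulationConfig(innovation_cost=10.0)
        stt = make_state(config=cfg,
                         individuals=[{"skills": [10], "energy": 30.0}])
        assert attempt_invention(stt, 0) is True
        assert stt.ntraits[0] == 2
        assert stt.skills[0, 1] == 1
        assert stt.energy[0] == pytest.approx(20.0)
        assert stt.event_log == [(0, 0, 2, 0)]

    def test_exhausted_trait_list(self, make_state):
        stt = make_state(individuals=[{"skills": [10] * 10, "energy": 49.0}])
        assert attempt_invention(stt, 0) is False

    def test_unaffordable_invention(self, make_state):
        cfg = SimulationConfig(innovation_cost=40.0)
        stt = make_state(config=cfg,
                         individuals=[{"skills": [10], "energy": 40.0}])
        assert attempt_invention(stt, 0) is False   # strict energy > cost


def test_prefix_invariant_preserved_by_culture_ops(make_state):
    """Trait lists stay prefixes of 1..k under repeated learning/invention."""
    cfg = SimulationConfig(interaction_radius=1)
    stt = make_state(config=cfg, seed=9, individuals=[
        {"skills": [10, 4], "energy": 40.0},
        {"skills": [10], "energy": 40.0},
        {"skills": [5, 9, 2], "energy": 40.0},
    ])
    for step in range(40):
        for i in range(3):
            if not social_learning_event(stt, i):
                attempt_invention(stt, i)
        stt.check_invariants()
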