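"""Observables and end-value statistics (exact rank-sum, Bonferroni, tables)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from culturesim import (bonferroni, competition, mean_traits, summarize_sweep,
                        sweep_comparisons, table1_layout, wilcoxon_rank_sum)
from culturesim.demography import group_pressure


def brute_force_rank_sum_p(a, b):
    """Independent oracle: two-sided permutation p from pairwise counts.

    U is computed by counting pairs (a_i > b_j) with half-credit for ties —
    no midrank formula — and the null distribution by enumerating every
    C(n+m, n) relabeling of the pooled values.
    """
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)

    def u_of(sample_a, sample_b):
        u = 0.0
        for x in sample_a:
            for y in sample_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    obs = abs(u_of(a, b) - n * m / 2)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(idx)] = True
        u = u_of(pooled[mask], pooled[~mask])
        if abs(u - n * m / 2) >= obs - 1e-9:
            count += 1
        total += 1
    return count / total


class TestWilcoxonRankSum:
    def test_identical_samples_give_p_one(self):
        u, p = wilcoxon_rank_sum([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0

    def test_fully_separated_three_vs_three(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)        # 2 of the 20 labelings

    def test_fully_separated_ten_vs_ten(self):
        a = 39.1 + np.arange(10) * 0.3
        b = 12.4 + np.arange(10) * 0.2
        u, p = wilcoxon_rank_sum(a, b)
        assert u == 100.0
        assert p == pytest.approx(2 / 184756)

    def test_agrees_with_scipy_exact_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n, m = rng.integers(3, 9, size=2)
            a = rng.normal(size=n)
            b = rng.normal(size=m)
            u, p = wilcoxon_rank_sum(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("n,m", [(n, m) for n in range(1, 7)
                                     for m in range(n, 7) if n + m <= 12])
    def test_matches_brute_force_enumeration(self, n, m):
        """Exact p equals full-enumeration oracle, including tied data."""
        rng = np.random.default_rng(n * 100 + m)
        for _ in range(3):
            a = rng.integers(0, 4, size=n).astype(float)   # many ties
            b = rng.integers(0, 4, size=m).astype(float)
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(brute_force_rank_sum_p(a, b))

    @given(st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None)
    def test_p_in_unit_interval_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 8))
        b = rng.normal(size=rng.integers(2, 8))
        _, p_ab = wilcoxon_rank_sum(a, b)
        _, p_ba = wilcoxon_rank_sum(b, a)
        assert 0.0 < p_ab <= 1.0
        assert p_ab == pytest.approx(p_ba)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected",
                             [(0.01, 6, 0.06), (0.3, 6, 1.0), (0.02, 3, 0.06)])
    def test_correction(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_corrected_never_below_raw(self):
        for p in (1e-6, 0.04, 0.5):
            for m in (1, 3, 6):
                assert bonferroni(p, m) >= p


class TestObservables:
    def test_competition_counts_pressured_fraction(self, make_state):
        stt = make_state(individuals=[{} for _ in range(100)])
        stt.pressure[:25] = True
        assert competition(stt) == pytest.approx(0.25)

    def test_competition_equals_size_weighted_group_pressure(self, make_state):
        stt = make_state(groups=[(0, 0), (5, 5)],
                         individuals=[{"group": 0} for _ in range(8)]
                         + [{"group": 1} for _ in range(4)])
        stt.pressure[[0, 1, 8]] = True
        weighted = sum(group_pressure(stt, g).fraction_unmet * stt.gcount[g]
                       for g in stt.living_groups()) / stt.population
        assert competition(stt) == pytest.approx(weighted)

    def test_mean_traits(self, make_state):
        stt = make_state(individuals=[{"skills": [1, 1]}, {"skills": [1] * 4}])
        assert mean_traits(stt) == pytest.approx(3.0)
        assert mean_traits(stt) <= 10

    def test_empty_population_is_missing(self, make_state):
        stt = make_state(groups=(), individuals=())
        assert math.isnan(competition(stt))
        assert math.isnan(mean_traits(stt))


def _tidy(rows):
    return pd.DataFrame(rows, columns=["selection_differential",
                                       "resource_level", "regime",
                                       "replicate", "mean_traits",
                                       "mean_group_size", "competition"])


class TestSummaries:
    def test_mean_and_sample_sd(self):
        rows = [(0.5, 50, "isolated", r, v, 10.0, 0.1)
                for r, v in enumerate([3.0, 3.0, 3.0])]
        rows += [(0.5, 50, "interacting", r, v, 12.0, 0.2)
                 for r, v in enumerate([2.0, 4.0])]
        out = summarize_sweep(_tidy(rows))
        iso = out[out.regime == "isolated"].iloc[0]
        inter = out[out.regime == "interacting"].iloc[0]
        assert iso["mean_traits_mean"] == pytest.approx(3.0)
        assert iso["mean_traits_sd"] == pytest.approx(0.0)
        assert inter["mean_traits_mean"] == pytest.approx(3.0)
        assert inter["mean_traits_sd"] == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_missing_cells_reported_not_dropped(self):
        rows = [(0.5, 50, "isolated", r, 3.0, 10.0, 0.1) for r in range(3)]
        out = summarize_sweep(_tidy(rows),
                              expected_cells=[(0.5, 50, "isolated"),
                                              (0.5, 100, "isolated")])
        missing = out[(out.resource_level == 100)]
        assert len(missing) == 1
        assert missing.iloc[0]["n_replicates"] == 0
        assert np.isnan(missing.iloc[0]["mean_traits_mean"])

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            summarize_sweep(_tidy([(0.5, 50, "isolated", 0, 3.0, 10.0, 0.1)]))

    def test_table1_layout_shape(self):
        rows = []
        for sd in (0.01, 0.5):
            for lv in (50, 100):
                for rg in ("isolated", "interacting"):
                    for r in range(2):
                        rows.append((sd, lv, rg, r, 2.0 + r, 10.0, 0.1))
        table = table1_layout(summarize_sweep(_tidy(rows)))
        assert table.shape[0] == 4            # sd x level rows
        assert ("isolated", "n_traits") in table.columns
        assert ("interacting", "group_size") in table.columns

    def test_sweep_comparisons_families_and_factors(self):
        rng = np.random.default_rng(1)
        rows = []
        for sd in (0.01, 0.1, 0.5, 1.0):
            for rg in ("isolated", "interacting"):
                for r in range(5):
                    rows.append((sd, 50, rg, r, rng.normal(3), 10.0, 0.1))
        comps = sweep_comparisons(_tidy(rows), metrics=["mean_traits"])
        sd_family = comps[comps.family == "selection_differential"]
        assert len(sd_family) == 2 * 6        # per regime, C(4,2) pairs
        assert set(sd_family.factor) == {6}
        regime_family = comps[comps.family == "regime"]
        assert len(regime_family) == 4
        assert set(regime_family.factor) == {1}
        assert (comps.p_corrected >= comps.p_raw - 1e-12).all()
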