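"""Observables and end-value statistics.

Replicate end values are compared with two-sided Wilcoxon rank-sum
(Mann-Whitney) tests.  With ten runs per condition the samples are small, so
the null distribution is obtained by complete enumeration of all
C(n+m, n) rank assignments (midranks under ties), not by the normal
approximation.  Families of pairwise tests are Bonferroni-corrected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .state import SimState

__all__ = ["competition", "mean_traits", "wilcoxon_rank_sum", "bonferroni",
           "ComparisonResult", "summarize_sweep", "table1_layout",
           "sweep_comparisons"]

# complete enumeration up to C(20,10) = 184756 labelings
_EXACT_LIMIT = 20

CELL_KEYS = ["selection_differential", "resource_level", "regime"]
METRICS = ["mean_traits", "mean_group_size", "competition"]


def competition(state: SimState) -> float:
    """Fraction of the living population that went hungry this step."""
    living = state.living_slots()
    if living.size == 0:
        return float("nan")
    return float(state.pressure[living].mean())


def mean_traits(state: SimState) -> float:
    """Mean trait-list length over living individuals."""
    living = state.living_slots()
    if living.size == 0:
        return float("nan")
    return float(state.ntraits[living].mean())


def wilcoxon_rank_sum(sample_a: Sequence[float],
                      sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney test; returns (U of sample_a, p).

    Midranks are used under ties and the p-value is the exact permutation
    probability of a U at least as far from n*m/2 as observed, from complete
    enumeration of all C(n+m, n) labelings (asymptotic fallback beyond
    n+m = 20, far larger than the replicate counts used here).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = float(ranks[:n].sum() - n * (n + 1) / 2)
    if n + m <= _EXACT_LIMIT:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n + m), n)),
            dtype=np.int64).reshape(-1, n)
        us = ranks[idx].sum(axis=1) - n * (n + 1) / 2
        centre = n * m / 2
        p = float(np.mean(np.abs(us - centre) >= abs(u - centre) - 1e-9))
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic").pvalue)
    return u, p


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value for a family of m tests: min(1, m*p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


@dataclass(frozen=True)
class ComparisonResult:
    label_a: str
    label_b: str
    metric: str
    statistic: float             # Mann-Whitney U of sample a
    p_raw: float
    p_corrected: float
    factor: int
    significant_05: bool
    significant_01: bool

    @classmethod
    def from_samples(cls, label_a: str, sample_a, label_b: str, sample_b,
                     metric: str, factor: int) -> "ComparisonResult":
        u, p = wilcoxon_rank_sum(sample_a, sample_b)
        pc = bonferroni(p, factor)
        return cls(label_a, label_b, metric, u, p, pc, factor,
                   pc < 0.05, pc < 0.01)


def summarize_sweep(end_values: pd.DataFrame,
                    expected_cells: Iterable[tuple] | None = None
                    ) -> pd.DataFrame:
    """Mean and sample SD of replicate end values per parameter cell.

    ``end_values`` is tidy: one row per replicate with CELL_KEYS columns
    plus the metric columns.  Cells listed in ``expected_cells`` (tuples of
    the CELL_KEYS values) but absent from the data are reported as rows of
    NaN with ``n_replicates`` 0 rather than silently dropped.
    """
    for col in CELL_KEYS + METRICS:
        if col not in end_values.columns:
            raise ValueError(f"end_values is missing column {col!r}")
    grouped = end_values.groupby(CELL_KEYS, sort=True)
    rows = []
    for cell, sub in grouped:
        if len(sub) < 2:
            raise ValueError(f"cell {cell} has fewer than 2 replicates")
        row = dict(zip(CELL_KEYS, cell))
        row["n_replicates"] = len(sub)
        for metric in METRICS:
            row[f"{metric}_mean"] = sub[metric].mean()
            row[f"{metric}_sd"] = sub[metric].std(ddof=1)
        rows.append(row)
    present = {tuple(r[k] for k in CELL_KEYS) for r in rows}
    if expected_cells is not None:
        for cell in expected_cells:
            if tuple(cell) not in present:
                row = dict(zip(CELL_KEYS, cell))
                row["n_replicates"] = 0
                for metric in METRICS:
                    row[f"{metric}_mean"] = np.nan
                    row[f"{metric}_sd"] = np.nan
                rows.append(row)
    out = pd.DataFrame(rows).sort_values(CELL_KEYS).reset_index(drop=True)
    return out


def table1_layout(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot a sweep summary into the published layout: rows are resource
    level within selection differential, column blocks are the isolated and
    interacting regimes with group size and trait number."""
    cols = {}
    for regime in ["isolated", "interacting"]:
        sub = summary[summary["regime"] == regime].set_index(
            ["selection_differential", "resource_level"])
        cols[(regime, "group_size")] = sub["mean_group_size_mean"]
        cols[(regime, "group_size_sd")] = sub["mean_group_size_sd"]
        cols[(regime, "n_traits")] = sub["mean_traits_mean"]
        cols[(regime, "n_traits_sd")] = sub["mean_traits_sd"]
    return pd.DataFrame(cols)


def _cell_samples(end_values: pd.DataFrame, metric: str):
    return {cell: sub[metric].to_numpy()
            for cell, sub in end_values.groupby(CELL_KEYS, sort=True)}


def sweep_comparisons(end_values: pd.DataFrame,
                      metrics: Sequence[str] = ("mean_traits",
                                                "mean_group_size",
                                                "competition")
                      ) -> pd.DataFrame:
    """All pairwise end-value comparisons of a sweep, per metric.

    Three families, each Bonferroni-corrected by its own number of pairwise
    tests: across the four selection differentials (factor 6) at fixed
    level/regime, across the three resource levels (factor 3) at fixed
    differential/regime, and between the two interaction regimes (factor 1)
    at fixed differential/level.  Families with fewer distinct values use
    the correspondingly smaller factor.
    """
    rows = []
    for metric in metrics:
        samples = _cell_samples(end_values, metric)
        diffs = sorted({c[0] for c in samples})
        levels = sorted({c[1] for c in samples})
        regimes = sorted({c[2] for c in samples})

        def _add(family, pairs):
            factor = len(pairs)
            for (cell_a, cell_b) in pairs:
                if cell_a not in samples or cell_b not in samples:
                    continue
                rows.append({"family": family, "metric": metric,
                             **_compare(samples, cell_a, cell_b, factor)})

        for lv in levels:
            for rg in regimes:
                _add("selection_differential",
                     [((d1, lv, rg), (d2, lv, rg))
                      for d1, d2 in itertools.combinations(diffs, 2)])
        for d in diffs:
            for rg in regimes:
                _add("resource_level",
                     [((d, l1, rg), (d, l2, rg))
                      for l1, l2 in itertools.combinations(levels, 2)])
        for d in diffs:
            for lv in levels:
                _add("regime",
                     [((d, lv, r1), (d, lv, r2))
                      for r1, r2 in itertools.combinations(regimes, 2)])
    return pd.DataFrame(rows)


def _compare(samples, cell_a, cell_b, factor):
    res = ComparisonResult.from_samples(str(cell_a), samples[cell_a],
                                        str(cell_b), samples[cell_b],
                                        metric="", factor=factor)
    return {"cell_a": res.label_a, "cell_b": res.label_b,
            "U": res.statistic, "p_raw": res.p_raw,
            "p_corrected": res.p_corrected, "factor": res.factor,
            "significant_05": res.significant_05,
            "significant_01": res.significant_01}
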