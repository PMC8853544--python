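"""Permutation comparison of normalization strategies, with BH adjustment.

Two normalization strategies are compared through the identity of their
"five best" miRNAs — the five with the least variances of log2-normalized
values. The union of the two top-5 sets (5-10 probes) forms a list; within
the list each strategy ranks the probes 1..|L| by ascending variance, and
the statistic is T = sum_i |rank_A(i) - rank_B(i)|. The null holds every
assignment of one strategy's ranks over the list equally likely, and the
p-value is the probability of a permutation with T at least the observed
value. All six pairwise p-values among the four strategies are adjusted by
the Benjamini-Hochberg step-up procedure.

The exhaustive null distribution of T is computed exactly: relabeling the
list by rank_A reduces T under a uniformly permuted rank_B to
D(pi) = sum_i |i - pi(i)| with pi uniform on S_n, whose distribution is
obtained by dynamic programming over subsets of used rank values
(equivalent to enumerating all n! permutations, without doing so).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import CountMatrix
from .filtering import FilterRule, filter_probes
from .normalization import DEFAULT_TOP_K, STRATEGIES, normalize_by_name

MAX_EXHAUSTIVE = 10  # union list of 5-10 probes; larger lists use Monte Carlo

STRATEGY_PAIRS = tuple(itertools.combinations(STRATEGIES, 2))


@dataclass(frozen=True)
class RankConcordanceInput:
    """Union list of the two strategies' best probes with within-list ranks.

    ``ranks_a`` and ``ranks_b`` are each a permutation of 1..|L| aligned to
    ``union_list``.
    """

    union_list: tuple[str, ...]
    ranks_a: tuple[int, ...]
    ranks_b: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.union_list)
        expected = set(range(1, n + 1))
        if set(self.ranks_a) != expected or set(self.ranks_b) != expected:
            raise ValueError("ranks must each be a permutation of 1..|L|")


@dataclass(frozen=True)
class StrategyComparisonResult:
    pair: tuple[str, str]
    union_list: tuple[str, ...]
    T_obs: int
    p_unadjusted: float
    n_permutations: int
    mode: str  # "exhaustive" | "monte_carlo"
    p_adjusted: float | None = None


def _within_list_ranks(variances: Mapping[str, float], union: Sequence[str]) -> tuple[int, ...]:
    # serial numbers by ascending variance; probe id breaks exact ties
    order = sorted(union, key=lambda pid: (variances[pid], pid))
    position = {pid: i + 1 for i, pid in enumerate(order)}
    return tuple(position[pid] for pid in union)


def build_union_list(
    variances_a: Mapping[str, float],
    variances_b: Mapping[str, float],
    k: int = 5,
) -> RankConcordanceInput:
    """Union of the k least-variance probes under each strategy, with ranks."""
    probes = set(variances_a)
    if probes != set(variances_b):
        raise ValueError("the two variance maps cover different probe sets")
    if len(probes) < k:
        raise ValueError(f"need at least {k} probes, have {len(probes)}")

    def top(variances: Mapping[str, float]) -> list[str]:
        return sorted(probes, key=lambda pid: (variances[pid], pid))[:k]

    union = tuple(sorted(set(top(variances_a)) | set(top(variances_b))))
    return RankConcordanceInput(
        union_list=union,
        ranks_a=_within_list_ranks(variances_a, union),
        ranks_b=_within_list_ranks(variances_b, union),
    )


def rank_distance(ranks_a: Sequence[int], ranks_b: Sequence[int]) -> int:
    """T = sum of absolute rank differences over the union list."""
    if len(ranks_a) != len(ranks_b):
        raise ValueError("rank vectors differ in length")
    return int(np.abs(np.asarray(ranks_a) - np.asarray(ranks_b)).sum())


@lru_cache(maxsize=None)
def rank_distance_null(n: int) -> tuple[int, ...]:
    """Counts of permutations of S_n by D(pi) = sum |i - pi(i)|, T = 0..floor(n^2/2).

    Subset DP: after assigning positions 0..|S|-1 the used values form S;
    adding value j at position i = |S| contributes |i - j|.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    max_t = n * n // 2
    states: list[np.ndarray | None] = [None] * (1 << n)
    start = np.zeros(max_t + 1, dtype=np.int64)
    start[0] = 1
    states[0] = start
    for s in range(1 << n):
        f = states[s]
        if f is None:
            continue
        i = bin(s).count("1")
        if i == n:
            continue
        for j in range(n):
            if s >> j & 1:
                continue
            d = abs(i - j)
            t = s | 1 << j
            g = states[t]
            if g is None:
                g = np.zeros(max_t + 1, dtype=np.int64)
                states[t] = g
            if d == 0:
                g += f
            else:
                g[d:] += f[: max_t + 1 - d]
        states[s] = None  # free as we go
    return tuple(int(c) for c in states[(1 << n) - 1])


def permutation_p(
    rc: RankConcordanceInput,
    mode: str = "exhaustive",
    n_mc: int = 100_000,
    seed: int | None = None,
) -> StrategyComparisonResult:
    """Permutation p-value for the observed rank distance.

    Exhaustive mode uses the exact null distribution of T over all |L|!
    equally likely permutations; Monte Carlo mode samples ``n_mc`` uniform
    permutations and applies the add-one estimator (count + 1)/(n_mc + 1).
    """
    n = len(rc.union_list)
    t_obs = rank_distance(rc.ranks_a, rc.ranks_b)
    if mode == "exhaustive":
        if n > MAX_EXHAUSTIVE:
            raise ValueError(f"exhaustive mode supports |L| <= {MAX_EXHAUSTIVE}")
        null = rank_distance_null(n)
        total = sum(null)
        extreme = sum(null[t_obs:])
        p = extreme / total
        n_perm = total
    elif mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        b = np.asarray(rc.ranks_b)
        draws = np.stack([rng.permutation(b) for _ in range(n_mc)])
        ts = np.abs(draws - np.asarray(rc.ranks_a)[None, :]).sum(axis=1)
        p = (int((ts >= t_obs).sum()) + 1) / (n_mc + 1)
        n_perm = n_mc
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return StrategyComparisonResult(
        pair=("A", "B"),
        union_list=rc.union_list,
        T_obs=t_obs,
        p_unadjusted=float(p),
        n_permutations=n_perm,
        mode=mode,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def strategy_variances(
    matrix: CountMatrix,
    group: str,
    retained: set[str],
    name: str,
    top_k: int = DEFAULT_TOP_K,
) -> pd.Series:
    """Per-probe variance of log2-normalized values under one strategy."""
    normalized = normalize_by_name(matrix, group, retained, name, top_k=top_k)
    return normalized.values.var(axis=1, ddof=1)


def compare_all_strategies(
    matrix: CountMatrix,
    group: str,
    k: int = 5,
    rule: FilterRule = FilterRule(),
    top_k: int = DEFAULT_TOP_K,
    mode: str = "exhaustive",
    n_mc: int = 100_000,
    seed: int | None = None,
) -> list[StrategyComparisonResult]:
    """All six pairwise strategy comparisons for *group*, BH-adjusted."""
    retained = filter_probes(matrix, group, rule)
    variances = {
        name: strategy_variances(matrix, group, retained, name, top_k=top_k)
        for name in STRATEGIES
    }
    results = []
    for a, b in STRATEGY_PAIRS:
        rc = build_union_list(dict(variances[a]), dict(variances[b]), k=k)
        base = permutation_p(rc, mode=mode, n_mc=n_mc, seed=seed)
        results.append(
            StrategyComparisonResult(
                pair=(a, b),
                union_list=base.union_list,
                T_obs=base.T_obs,
                p_unadjusted=base.p_unadjusted,
                n_permutations=base.n_permutations,
                mode=base.mode,
            )
        )
    adjusted = bh_adjust([r.p_unadjusted for r in results])
    return [
        StrategyComparisonResult(
            pair=r.pair,
            union_list=r.union_list,
            T_obs=r.T_obs,
            p_unadjusted=r.p_unadjusted,
            n_permutations=r.n_permutations,
            mode=r.mode,
            p_adjusted=float(q),
        )
        for r, q in zip(results, adjusted)
    ]
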