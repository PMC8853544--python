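"""Paired dispersion tests on composite (geometric-mean) normalizers.

A composite normalizer is the per-sample arithmetic mean of several miRNAs'
log2-normalized values — the log of their geometric mean. To ask whether
the five most stable miRNAs give a genuinely tighter normalizer than the
five next most stable, the two composite series are compared sample-by-
sample with two paired dispersion tests:

* the paired Grambsch test of equal variances, a robust Pitman–Morgan
  construction: with D = x - y and S = x + y, under H0 the products
  u_i = (D_i - Dbar)(S_i - Sbar) have mean zero, and
  T = sqrt(n) * ubar / sd(u) is asymptotically standard normal;
* the paired Bonett–Seier test of equal mean absolute deviations from
  the median, a delta-method statistic on log(tau_x / tau_y) with a
  paired covariance term in the standard error.

Both are two-sided and invariant to adding a common constant to both
series. Inputs shorter than 3 pairs, or degenerate inputs (e.g. x == y,
for which sd(u) = 0), raise :class:`DegenerateInputError`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import CountMatrix, NormalizedMatrix
from .filtering import FilterRule, filter_probes
from .normalization import DEFAULT_TOP_K, normalize_by_name
from .stability import combined_rank_sum, top_k_stable

MIN_PAIRS = 3


class DegenerateInputError(ValueError):
    """The paired series admit no dispersion comparison (e.g. x == y)."""


@dataclass(frozen=True)
class CompositeSeries:
    """Per-sample mean of several probes' log2-normalized values."""

    values: pd.Series
    member_probes: tuple[str, ...]
    strategy: str


@dataclass(frozen=True)
class PairedDispersionResult:
    method: str  # "grambsch" | "bonett_seier"
    statistic: float
    p_value: float
    n_pairs: int


def composite_series(normalized: NormalizedMatrix, probes: list[str]) -> CompositeSeries:
    missing = set(probes) - set(normalized.values.index)
    if missing:
        raise KeyError(f"probes absent from normalized matrix: {sorted(missing)}")
    if not probes:
        raise ValueError("member probe list is empty")
    values = normalized.values.loc[list(probes)].mean(axis=0)
    return CompositeSeries(
        values=values, member_probes=tuple(probes), strategy=normalized.strategy
    )


def _check_pairs(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    n = x.size
    if n < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} pairs, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite input")
    return x, y, n


def grambsch_paired(x, y) -> PairedDispersionResult:
    """Robust paired test of var(x) = var(y) via the (D, S) covariance."""
    x, y, n = _check_pairs(x, y)
    d = x - y
    s = x + y
    u = (d - d.mean()) * (s - s.mean())
    s_u = float(np.std(u, ddof=1))
    if s_u == 0.0:
        raise DegenerateInputError("sd of (D - Dbar)(S - Sbar) is zero (x == y?)")
    t = float(np.sqrt(n) * u.mean() / s_u)
    p = float(2.0 * norm.sf(abs(t)))
    return PairedDispersionResult("grambsch", t, p, n)


def bonett_seier_paired(x, y) -> PairedDispersionResult:
    """Paired test of equal mean absolute deviations from the median."""
    x, y, n = _check_pairs(x, y)
    a = np.abs(x - np.median(x))
    b = np.abs(y - np.median(y))
    tau_x = float(a.mean())
    tau_y = float(b.mean())
    if tau_x == 0.0 or tau_y == 0.0:
        raise DegenerateInputError("a series has zero mean absolute deviation")
    cov_ab = float(np.cov(a, b, ddof=1)[0, 1])
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    se2 = (var_a / tau_x**2 + var_b / tau_y**2 - 2.0 * cov_ab / (tau_x * tau_y)) / n
    log_ratio = float(np.log(tau_x / tau_y))
    # exactly proportional series (y = a + b*x) zero out the SE; report the
    # deterministic limit instead of dividing by zero
    floor = 1e-10 * (var_a / tau_x**2 + var_b / tau_y**2) / n
    if se2 <= floor:
        if log_ratio == 0.0:
            return PairedDispersionResult("bonett_seier", 0.0, 1.0, n)
        z = float(np.sign(log_ratio) * np.inf)
        return PairedDispersionResult("bonett_seier", z, 0.0, n)
    z = float(log_ratio / np.sqrt(se2))
    p = float(2.0 * norm.sf(abs(z)))
    return PairedDispersionResult("bonett_seier", z, p, n)


def compare_top5_next5(
    matrix: CountMatrix,
    group: str,
    strategy: str,
    rule: FilterRule = FilterRule(),
    n_top: int = 5,
    n_next: int = 5,
    top_k: int = DEFAULT_TOP_K,
) -> tuple[PairedDispersionResult, PairedDispersionResult]:
    """Run both paired tests on the top-5 vs next-5 composite normalizers.

    The probe sets come from the combined rank-sum ordering (positions
    1..n_top and n_top+1..n_top+n_next); the composites are then computed
    under the requested normalization *strategy*.
    """
    retained = filter_probes(matrix, group, rule)
    if len(retained) < n_top + n_next:
        raise ValueError(
            f"need at least {n_top + n_next} retained probes, have {len(retained)}"
        )
    table = combined_rank_sum(matrix, group, retained, top_k=top_k)
    ordering = top_k_stable(table, n_top + n_next)
    best, runners = ordering[:n_top], ordering[n_top:]
    normalized = normalize_by_name(matrix, group, retained, strategy, top_k=top_k)
    x = composite_series(normalized, best).values.to_numpy()
    y = composite_series(normalized, runners).values.to_numpy()
    return grambsch_paired(x, y), bonett_seier_paired(x, y)
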