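"""Variability measures, per-measure ranking and combined rank sums.

Four scale measures summarise the within-group spread of each miRNA's
log2-normalized values: standard deviation (n-1 denominator), range
(max - min), interquartile range (Q3 - Q1 with linear interpolation
between order statistics, h = (n-1)p + 1), and the mean absolute
deviation from the median (MADM). For each (measure, strategy)
combination probes are ranked ascending — rank 1 is the least variable,
ties share the average of the tied positions — and a probe's combined
rank sum over 4 measures x 2 strategies (housekeeping and total-miRNA
normalization) orders the stability table: the smaller the rank sum,
the more stable the miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import CountMatrix
from .normalization import DEFAULT_TOP_K, normalize_by_name

MEASURES = ("sd", "range", "iqr", "madm")
DEFAULT_RANKING_STRATEGIES = ("housekeeping", "total_mirna")


def variability_measures(values: np.ndarray) -> tuple[float, float, float, float]:
    """(sd, range, iqr, madm) of a vector of log2 values, n >= 2."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector with n >= 2")
    if not np.isfinite(x).all():
        raise ValueError("non-finite input")
    sd = float(np.std(x, ddof=1))
    rng = float(np.max(x) - np.min(x))
    q1, q3 = np.quantile(x, [0.25, 0.75])  # linear interpolation convention
    madm = float(np.mean(np.abs(x - np.median(x))))
    return sd, rng, float(q3 - q1), madm


def rank_probes(values: pd.Series) -> pd.Series:
    """Ascending ranks (1 = least variable), average ranks for ties."""
    if len(values) == 0:
        raise ValueError("empty input")
    return pd.Series(rankdata(values.to_numpy(), method="average"), index=values.index)


@dataclass
class StabilityTable:
    """Per-probe measures, ranks and combined rank sums, ordered stable-first.

    ``frame`` columns: ``{measure}__{strategy}`` values,
    ``rank_{measure}__{strategy}`` ranks, ``rank_sum`` and ``final_rank``.
    """

    frame: pd.DataFrame
    group: str
    strategies: tuple[str, ...]

    @property
    def ordering(self) -> list[str]:
        return list(self.frame.index)


def measure_frame(normalized_values: pd.DataFrame) -> pd.DataFrame:
    """All four variability measures per probe (rows) of a value matrix."""
    rows = {
        pid: variability_measures(normalized_values.loc[pid].to_numpy())
        for pid in normalized_values.index
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(MEASURES))


def combined_rank_sum(
    matrix: CountMatrix,
    group: str,
    retained: set[str],
    strategies: tuple[str, ...] = DEFAULT_RANKING_STRATEGIES,
    top_k: int = DEFAULT_TOP_K,
) -> StabilityTable:
    """Rank-sum stability table for *group* over *strategies*.

    Ties in the rank sum are broken by the SD under the last strategy
    listed (total-miRNA normalization by default), then by probe id.
    """
    if not strategies:
        raise ValueError("need at least one strategy")
    blocks: dict[str, pd.DataFrame] = {}
    for name in strategies:
        normalized = normalize_by_name(matrix, group, retained, name, top_k=top_k)
        blocks[name] = measure_frame(normalized.values)

    probe_ids = sorted(retained)
    frame = pd.DataFrame(index=pd.Index(probe_ids, name="probe_id"))
    rank_cols = []
    for name in strategies:
        measures = blocks[name].loc[probe_ids]
        for m in MEASURES:
            frame[f"{m}__{name}"] = measures[m]
            col = f"rank_{m}__{name}"
            frame[col] = rank_probes(measures[m])
            rank_cols.append(col)
    frame["rank_sum"] = frame[rank_cols].sum(axis=1)

    tiebreak_sd = frame[f"sd__{strategies[-1]}"]
    order = sorted(
        probe_ids, key=lambda pid: (frame.at[pid, "rank_sum"], tiebreak_sd[pid], pid)
    )
    frame = frame.loc[order]
    frame["final_rank"] = np.arange(1, len(order) + 1)
    return StabilityTable(frame=frame, group=group, strategies=tuple(strategies))


def top_k_stable(table: StabilityTable, k: int) -> list[str]:
    """The k most stable probe ids, in table order."""
    if k < 0 or k > len(table.frame):
        raise ValueError(f"k = {k} out of range for {len(table.frame)} probes")
    return table.ordering[:k]
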