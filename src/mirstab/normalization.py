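"""Log2 normalization of miRNA counts under four normalizer choices.

Each strategy names a set of normalizer probes; the normalized value of a
retained endogenous miRNA p in sample s is

    value(p, s) = log2(count(p, s)) - log2(sum of normalizer counts in s),

i.e. the binary log of the miRNA's share of the normalizing molecules.
Normalizer totals are plain sums of molecule counts (not geometric means).
A numerator count of zero is floored at ``count_floor`` (default 1) so the
logarithm exists; normalizer totals are used as-is and must be positive.

Strategies
----------
housekeeping
    The five housekeeping mRNA probes of the codeset.
total_mirna
    All endogenous miRNAs retained by the group's low-count filter
    ("all miRNAs found").
top75
    The ``top_k`` retained miRNAs with the largest total count over the
    group's samples ("most represented"); ties broken by probe id.
positive_control
    The six positive-control ladder probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import CountMatrix, NormalizedMatrix, ProbeClass, ValidationError

STRATEGIES = ("housekeeping", "total_mirna", "top75", "positive_control")

DEFAULT_TOP_K = 75


@dataclass(frozen=True)
class NormalizationStrategy:
    name: str
    normalizer_probes: frozenset[str]
    top_k: int = DEFAULT_TOP_K

    def __post_init__(self) -> None:
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.name!r}")
        if not self.normalizer_probes:
            raise ValueError("normalizer_probes must be non-empty")


def resolve_normalizer(
    matrix: CountMatrix,
    group: str,
    retained: set[str],
    name: str,
    top_k: int = DEFAULT_TOP_K,
) -> set[str]:
    """Resolve the normalizer probe set for one strategy in one group."""
    if name == "housekeeping":
        probes = matrix.probes_of_class(ProbeClass.HOUSEKEEPING)
        if not probes:
            raise ValidationError("no housekeeping probes annotated")
        return set(probes)
    if name == "positive_control":
        probes = matrix.probes_of_class(ProbeClass.POSITIVE)
        if not probes:
            raise ValidationError("no positive-control probes annotated")
        return set(probes)
    if name == "total_mirna":
        if not retained:
            raise ValidationError("no retained miRNAs to normalize against")
        return set(retained)
    if name == "top75":
        if len(retained) < top_k:
            raise ValidationError(
                f"top{top_k} needs {top_k} retained probes, have {len(retained)}"
            )
        totals = matrix.subset_counts(sorted(retained), matrix.group_samples(group)).sum(axis=1)
        # largest totals first; probe id breaks ties deterministically
        order = sorted(totals.index, key=lambda pid: (-totals[pid], pid))
        return set(order[:top_k])
    raise ValueError(f"unknown strategy {name!r}")


def normalize(
    matrix: CountMatrix,
    group: str,
    retained: set[str],
    strategy: NormalizationStrategy,
    count_floor: int = 1,
) -> NormalizedMatrix:
    """Log2-normalize the retained miRNAs of *group* under *strategy*."""
    sample_ids = matrix.group_samples(group)
    probe_ids = sorted(retained)
    if not probe_ids:
        raise ValidationError("no retained probes to normalize")
    missing = strategy.normalizer_probes - set(matrix.probe_ids)
    if missing:
        raise ValidationError(f"normalizer probes absent from matrix: {sorted(missing)}")
    totals = matrix.subset_counts(sorted(strategy.normalizer_probes), sample_ids).sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValidationError(f"zero normalizer total in samples {bad}")
    numer = matrix.subset_counts(probe_ids, sample_ids).astype(float)
    n_floored = int((numer.to_numpy() < count_floor).sum())
    values = np.log2(numer.clip(lower=count_floor)) - np.log2(totals.to_numpy())[None, :]
    return NormalizedMatrix(
        values=values,
        strategy=strategy.name,
        normalizer_probes=strategy.normalizer_probes,
        n_floored=n_floored,
    )


def normalize_by_name(
    matrix: CountMatrix,
    group: str,
    retained: set[str],
    name: str,
    top_k: int = DEFAULT_TOP_K,
    count_floor: int = 1,
) -> NormalizedMatrix:
    """Resolve the normalizer and normalize in one step."""
    probes = resolve_normalizer(matrix, group, retained, name, top_k=top_k)
    strategy = NormalizationStrategy(name=name, normalizer_probes=frozenset(probes), top_k=top_k)
    return normalize(matrix, group, retained, strategy, count_floor=count_floor)
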