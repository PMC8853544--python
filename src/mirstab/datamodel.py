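"""Core data containers for NanoString nCounter count analysis.

The raw unit of data is a probe-by-sample matrix of molecule counts, with
probe-level annotation (endogenous miRNA, housekeeping mRNA, positive or
negative control) and sample-level annotation (tissue group, optional
subgroup and codeset batch label). The ``pooled`` pseudo-group is the union
of all samples and is resolved by :meth:`CountMatrix.group_samples`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

POOLED = "pooled"

#: Canonical housekeeping mRNAs included in the nCounter miRNA codesets.
HOUSEKEEPING_MRNAS = ("ACTB", "B2M", "GAPDH", "RPL19", "RPLP0")


class ProbeClass(str, Enum):
    ENDOGENOUS = "endogenous_mirna"
    HOUSEKEEPING = "housekeeping_mrna"
    POSITIVE = "positive_control"
    NEGATIVE = "negative_control"


class ValidationError(ValueError):
    """A container violates one of its structural invariants."""


@dataclass
class CountMatrix:
    """Probes x samples integer molecule counts plus annotations.

    Parameters
    ----------
    counts
        DataFrame indexed by probe_id with one column per sample_id;
        non-negative integer molecule counts, no missing cells.
    probes
        DataFrame indexed by probe_id with columns ``probe_class`` (one of
        :class:`ProbeClass` values) and optional boolean ``merged`` marking
        probes that measure the summed content of two miRNAs (names joined
        by "+").
    samples
        DataFrame indexed by sample_id with column ``group`` and optional
        ``subgroup`` and ``codeset``.
    """

    counts: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate probe_id in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample_id in count matrix")
        if self.probes.index.has_duplicates:
            raise ValidationError("duplicate probe_id in probe annotation")
        if self.samples.index.has_duplicates:
            raise ValidationError("duplicate sample_id in sample annotation")
        if set(self.counts.index) != set(self.probes.index):
            missing = set(self.counts.index) ^ set(self.probes.index)
            raise ValidationError(
                f"probe ids of counts and annotation differ: {sorted(missing)[:5]}"
            )
        if set(self.counts.columns) != set(self.samples.index):
            missing = set(self.counts.columns) ^ set(self.samples.index)
            raise ValidationError(
                f"sample ids of counts and annotation differ: {sorted(missing)[:5]}"
            )
        if self.counts.isna().any().any():
            raise ValidationError("missing cells in count matrix")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric count")
        if np.any(values < 0):
            raise ValidationError("negative count")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("non-integer count")
        if "probe_class" not in self.probes.columns:
            raise ValidationError("probe annotation lacks probe_class column")
        valid = {c.value for c in ProbeClass}
        bad = set(self.probes["probe_class"]) - valid
        if bad:
            raise ValidationError(f"unknown probe_class values: {sorted(bad)}")
        if "group" not in self.samples.columns:
            raise ValidationError("sample annotation lacks group column")
        if POOLED in set(self.samples["group"]):
            raise ValidationError("'pooled' is a derived group, not an annotation")
        # align annotation order to the matrix for positional operations
        self.probes = self.probes.loc[self.counts.index]
        self.samples = self.samples.loc[self.counts.columns]
        self.counts.index.name = "probe_id"
        self.counts.columns.name = None
        self.probes.index.name = "probe_id"
        self.samples.index.name = "sample_id"

    # -- accessors --------------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> list[str]:
        """Annotated groups in first-appearance order (excludes 'pooled')."""
        return list(dict.fromkeys(self.samples["group"]))

    def probes_of_class(self, probe_class: ProbeClass | str) -> list[str]:
        value = ProbeClass(probe_class).value
        mask = self.probes["probe_class"] == value
        return list(self.probes.index[mask])

    def group_samples(self, group: str) -> list[str]:
        """Sample ids in *group*; ``'pooled'`` means every sample."""
        if group == POOLED:
            return self.sample_ids
        ids = list(self.samples.index[self.samples["group"] == group])
        if not ids:
            raise KeyError(f"no samples in group {group!r}")
        return ids

    def subset_counts(self, probe_ids: Sequence[str], sample_ids: Sequence[str]) -> pd.DataFrame:
        return self.counts.loc[list(probe_ids), list(sample_ids)]


@dataclass
class NormalizedMatrix:
    """Log2-normalized endogenous miRNA values under one named strategy.

    ``values`` holds log2(count / normalizer total) for every retained
    endogenous probe; ``normalizer_probes`` is the resolved normalizer set;
    ``n_floored`` counts numerator cells where the count floor was applied.
    """

    values: pd.DataFrame
    strategy: str
    normalizer_probes: frozenset[str]
    n_floored: int = 0

    def __post_init__(self) -> None:
        if not self.normalizer_probes:
            raise ValidationError("empty normalizer probe set")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("non-finite normalized value")


def probe_annotation_frame(
    endogenous: Iterable[str],
    housekeeping: Iterable[str] = HOUSEKEEPING_MRNAS,
    positive: Iterable[str] = (),
    negative: Iterable[str] = (),
) -> pd.DataFrame:
    """Assemble a probe annotation table from per-class id lists."""
    rows = []
    for ids, cls in (
        (endogenous, ProbeClass.ENDOGENOUS),
        (housekeeping, ProbeClass.HOUSEKEEPING),
        (positive, ProbeClass.POSITIVE),
        (negative, ProbeClass.NEGATIVE),
    ):
        for pid in ids:
            rows.append((pid, cls.value, "+" in pid))
    frame = pd.DataFrame(rows, columns=["probe_id", "probe_class", "merged"])
    return frame.set_index("probe_id")
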