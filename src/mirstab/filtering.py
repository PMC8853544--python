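"""Low-count exclusion of endogenous miRNA probes.

A miRNA is excluded from a group's analysis when it shows fewer than
``min_molecules`` counts in more than ``max_low_fraction`` of the group's
samples; both comparisons are strict, so with n = 4 samples exactly two
low-count samples is not "more than 50%" and the probe is retained. The
rule applies only to endogenous miRNAs — housekeeping and control probes
are never part of the retained set. The pooled group applies the rule over
the union of all samples.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import CountMatrix, ProbeClass


@dataclass(frozen=True)
class FilterRule:
    min_molecules: int = 50
    max_low_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_molecules < 0:
            raise ValueError("min_molecules must be >= 0")
        if not 0.0 <= self.max_low_fraction <= 1.0:
            raise ValueError("max_low_fraction must be in [0, 1]")


def filter_probes(
    matrix: CountMatrix,
    group: str,
    rule: FilterRule = FilterRule(),
) -> set[str]:
    """Retained endogenous probe ids for *group* under *rule*.

    Probe p is excluded iff
    ``#{s in group : count(p, s) < min_molecules} > max_low_fraction * n``.
    """
    sample_ids = matrix.group_samples(group)
    if not sample_ids:
        raise ValueError("empty sample group")
    endogenous = matrix.probes_of_class(ProbeClass.ENDOGENOUS)
    counts = matrix.subset_counts(endogenous, sample_ids)
    n_low = (counts < rule.min_molecules).sum(axis=1)
    threshold = rule.max_low_fraction * len(sample_ids)
    return set(counts.index[~(n_low > threshold)])
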