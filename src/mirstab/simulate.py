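"""Synthetic NanoString-like count matrices with planted ground truth.

The generator emulates an nCounter miRNA panel: ~800 endogenous probes of
which only a minority are expressed above background, five housekeeping
mRNAs, a six-point positive-control ladder, eight negative controls,
per-sample (lane) size factors, and overdispersed count noise. Expressed
miRNAs are split into a planted *stable* class (low biological variation,
no group effect) and a planted *variable* class (high biological variation
plus a group-level expression shift), giving every downstream stage a
known answer to recover.

Counts are negative-binomial around the product of size factor, base
abundance, a lognormal biological term and (for variable probes) a
group effect. ``dispersion = 0`` switches to the deterministic noise-free
limit (counts are the rounded expected values), which is useful for
exactness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    HOUSEKEEPING_MRNAS,
    CountMatrix,
    ProbeClass,
    probe_annotation_frame,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic nCounter experiment.

    Defaults describe a three-tissue study of 12 samples per group
    (36 total) on an 800-probe panel with ~200 expressed miRNAs, of which
    5 are planted stable and the rest vary between samples and groups.
    """

    n_mirna_probes: int = 800
    n_expressed: int = 200
    n_stable: int = 5
    n_variable: int = 195
    groups: tuple[tuple[str, int], ...] = (
        ("thyroid", 12),
        ("glioma", 12),
        ("bone_marrow", 12),
    )
    #: SD of per-sample log2 size factors (lane-to-lane binding variation).
    size_factor_sd: float = 0.25
    #: SD of the lognormal biological term (natural-log scale) per class.
    biological_cv_stable: float = 0.05
    biological_cv_variable: float = 0.4
    #: Expressed probes planted in neither class get this intermediate CV.
    biological_cv_other: float = 0.2
    #: Magnitude of the group-level expression shift for variable probes.
    group_effect_log2: float = 1.0
    #: Negative-binomial overdispersion: var = mu + dispersion * mu^2.
    dispersion: float = 0.005
    #: Mean log2 abundance and spread of expressed probes (counts scale).
    expressed_log2_mean: float = 9.5
    expressed_log2_sd: float = 1.2
    hk_levels: tuple[float, ...] = (12000.0, 9000.0, 15000.0, 5000.0, 7000.0)
    #: Positive-control ladder mean counts (4x steps, as in spike ladders).
    pos_ladder: tuple[float, ...] = (24576.0, 6144.0, 1536.0, 384.0, 96.0, 24.0)
    neg_mean: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.n_stable and 0 <= self.n_variable):
            raise ValueError("planted class sizes must be non-negative")
        if self.n_stable + self.n_variable > self.n_expressed:
            raise ValueError("n_stable + n_variable exceeds n_expressed")
        if self.n_expressed > self.n_mirna_probes:
            raise ValueError("n_expressed exceeds n_mirna_probes")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.hk_levels) == 0 or len(self.pos_ladder) == 0:
            raise ValueError("control level lists must be non-empty")
        if min(self.hk_levels) <= 0 or min(self.pos_ladder) <= 0:
            raise ValueError("control means must be positive")
        if self.neg_mean <= 0:
            raise ValueError("neg_mean must be positive")
        if any(n <= 0 for _, n in self.groups) or not self.groups:
            raise ValueError("each group needs at least one sample")


@dataclass
class GroundTruth:
    """Planted structure of a simulated matrix."""

    stable_set: frozenset[str]
    variable_set: frozenset[str]
    expressed_set: frozenset[str]
    size_factors: pd.Series
    base_abundance: pd.Series
    #: log2 shift applied to (variable probe, group) pairs.
    group_effects: pd.DataFrame

    def __post_init__(self) -> None:
        if self.stable_set & self.variable_set:
            raise ValueError("stable and variable sets overlap")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2.

    dispersion == 0 is the deterministic limit: rounded expected values.
    """
    if dispersion == 0:
        return np.round(mean).astype(np.int64)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int64)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw one synthetic count matrix; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    width = max(4, len(str(config.n_mirna_probes)))
    mirna_ids = [f"miR-sim-{i + 1:0{width}d}" for i in range(config.n_mirna_probes)]
    hk_ids = list(HOUSEKEEPING_MRNAS[: len(config.hk_levels)])
    if len(hk_ids) < len(config.hk_levels):
        hk_ids += [f"HK{i}" for i in range(len(hk_ids), len(config.hk_levels))]
    pos_ids = [f"POS_{chr(ord('A') + i)}" for i in range(len(config.pos_ladder))]
    neg_ids = [f"NEG_{chr(ord('A') + i)}" for i in range(8)]

    sample_ids, group_labels = [], []
    for gname, n in config.groups:
        for i in range(n):
            sample_ids.append(f"{gname}_{i + 1:02d}")
            group_labels.append(gname)
    group_names = [g for g, _ in config.groups]
    n_samples = len(sample_ids)

    # fixed draw order: structure, size factors, abundances, effects, noise
    perm = rng.permutation(config.n_mirna_probes)
    expressed = [mirna_ids[i] for i in perm[: config.n_expressed]]
    stable = frozenset(expressed[: config.n_stable])
    variable = frozenset(expressed[config.n_stable : config.n_stable + config.n_variable])

    size_factors = pd.Series(
        np.exp2(rng.normal(0.0, config.size_factor_sd, n_samples)),
        index=sample_ids,
        name="size_factor",
    )

    base = pd.Series(config.neg_mean, index=mirna_ids, dtype=float)
    base.loc[expressed] = np.exp2(
        rng.normal(config.expressed_log2_mean, config.expressed_log2_sd, len(expressed))
    )

    # each variable probe shifts in exactly one group, up or down
    effects = pd.DataFrame(0.0, index=sorted(variable), columns=group_names)
    if len(variable):
        which = rng.integers(0, len(group_names), len(effects))
        signs = rng.choice([-1.0, 1.0], len(effects))
        for row, (g, s) in enumerate(zip(which, signs)):
            effects.iloc[row, g] = s * config.group_effect_log2

    cv = pd.Series(0.0, index=mirna_ids)
    cv.loc[expressed] = config.biological_cv_other
    cv.loc[list(stable)] = config.biological_cv_stable
    cv.loc[list(variable)] = config.biological_cv_variable

    mean = np.outer(base.to_numpy(), size_factors.to_numpy())
    bio = np.exp(
        rng.normal(0.0, 1.0, (config.n_mirna_probes, n_samples))
        * cv.to_numpy()[:, None]
    )
    mean = mean * bio
    group_of = np.array([group_names.index(g) for g in group_labels])
    for pid in effects.index:
        i = mirna_ids.index(pid)
        mean[i, :] *= np.exp2(effects.loc[pid].to_numpy()[group_of])

    mirna_counts = _nb_counts(rng, mean, config.dispersion)
    hk_counts = _nb_counts(
        rng,
        np.outer(np.asarray(config.hk_levels), size_factors.to_numpy()),
        config.dispersion,
    )
    pos_counts = _nb_counts(
        rng,
        np.outer(np.asarray(config.pos_ladder), size_factors.to_numpy()),
        config.dispersion,
    )
    neg_counts = _nb_counts(
        rng, np.full((len(neg_ids), n_samples), config.neg_mean), config.dispersion
    )

    counts = pd.DataFrame(
        np.vstack([mirna_counts, hk_counts, pos_counts, neg_counts]),
        index=mirna_ids + hk_ids + pos_ids + neg_ids,
        columns=sample_ids,
    )
    probes = probe_annotation_frame(mirna_ids, hk_ids, pos_ids, neg_ids)
    samples = pd.DataFrame(
        {"group": group_labels, "codeset": "sim-v1"}, index=pd.Index(sample_ids, name="sample_id")
    )
    matrix = CountMatrix(counts=counts, probes=probes, samples=samples)
    truth = GroundTruth(
        stable_set=stable,
        variable_set=variable,
        expressed_set=frozenset(expressed),
        size_factors=size_factors,
        base_abundance=base,
        group_effects=effects,
    )
    return matrix, truth


TINY_CONFIG = SimulationConfig(
    n_mirna_probes=20,
    n_expressed=12,
    n_stable=3,
    n_variable=9,
    groups=(("thyroid", 4), ("glioma", 4)),
)

#: Panel and group sizes mirroring the motivating three-tissue study
#: (32 thyroid specimens, 6 glioma patients x 2 tissues, 12 bone marrow).
PAPER_LIKE_CONFIG = SimulationConfig(
    groups=(("thyroid", 32), ("glioma", 12), ("bone_marrow", 12)),
)


def make_fixture(kind: str, seed: int = 0) -> tuple[CountMatrix, GroundTruth]:
    """Return a ready-made simulated dataset: ``tiny`` or ``paper_like``."""
    if kind == "tiny":
        config = replace(TINY_CONFIG, seed=seed)
    elif kind == "paper_like":
        config = replace(PAPER_LIKE_CONFIG, seed=seed)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return simulate_counts(config)
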