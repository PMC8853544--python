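import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from mirstab import (
    combined_rank_sum,
    filter_probes,
    normalize_by_name,
    rank_probes,
    top_k_stable,
    variability_measures,
)
from mirstab.stability import MEASURES, measure_frame

from conftest import build_matrix


class TestVariabilityMeasures:
    def test_constant_vector_is_all_zero(self):
        assert variability_measures([1.0, 1.0, 1.0, 1.0]) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_arithmetic_1234(self):
        sd, rng_, iqr, madm = variability_measures([1.0, 2.0, 3.0, 4.0])
        assert sd == pytest.approx(math.sqrt(5.0 / 3.0))
        assert rng_ == 3.0
        assert iqr == pytest.approx(1.5)  # linear-interpolation quantiles
        assert madm == pytest.approx(1.0)  # mean of (1.5, .5, .5, 1.5)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 30))
            c = rng.normal() * 10
            np.testing.assert_allclose(
                variability_measures(x), variability_measures(x + c), atol=1e-9
            )

    def test_range_dominates_iqr_and_madm(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.normal(size=rng.integers(2, 40))
            sd, rng_, iqr, madm = variability_measures(x)
            assert rng_ >= iqr >= 0
            assert rng_ >= madm >= 0

    @pytest.mark.parametrize("bad", [[1.0], [1.0, np.inf], []])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            variability_measures(bad)


class TestRankProbes:
    def test_serial_ranking(self):
        ranks = rank_probes(pd.Series({"a": 0.3, "b": 0.1, "c": 0.2}))
        assert ranks.to_dict() == {"a": 3.0, "b": 1.0, "c": 2.0}

    def test_average_ranks_for_ties(self):
        ranks = rank_probes(pd.Series({"a": 0.1, "b": 0.1, "c": 0.2}))
        assert ranks.to_dict() == {"a": 1.5, "b": 1.5, "c": 3.0}

    def test_single_probe(self):
        assert rank_probes(pd.Series({"a": 0.5})).to_dict() == {"a": 1.0}

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rank_probes(pd.Series(dtype=float))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        values = pd.Series(rng.random(20), index=[f"p{i}" for i in range(20)])
        pd.testing.assert_series_equal(rank_probes(values), rank_probes(np.exp(values)))


def _two_probe_matrix():
    # miR-a constant and dominating the miRNA total, miR-b noisy: a is less
    # variable on every measure under both ranking strategies
    return build_matrix(
        {"miR-a": [10000] * 4, "miR-b": [60, 400, 90, 800]},
        ["g"] * 4,
    )


class TestCombinedRankSum:
    def test_minimum_attainable_rank_sum(self):
        matrix = _two_probe_matrix()
        table = combined_rank_sum(matrix, "g", {"miR-a", "miR-b"})
        assert table.frame.at["miR-a", "rank_sum"] == 8  # 4 measures x 2 strategies
        assert table.frame.at["miR-b", "rank_sum"] == 16
        assert table.ordering == ["miR-a", "miR-b"]

    def test_zero_variance_probe_ranks_first(self, tiny_matrix):
        # plant a constant probe: constant share of the housekeeping total
        matrix = build_matrix(
            {
                "miR-const": [500] * 6,
                "miR-u": [100, 900, 300, 700, 150, 850],
                "miR-v": [60, 600, 1200, 90, 500, 200],
                "miR-w": [1000, 80, 60, 950, 400, 320],
            },
            ["g"] * 6,
        )
        table = combined_rank_sum(matrix, "g", filter_probes(matrix, "g"))
        assert table.ordering[0] == "miR-const"

    def test_sample_permutation_invariance(self, tiny_matrix):
        retained = filter_probes(tiny_matrix, "pooled")
        table = combined_rank_sum(tiny_matrix, "pooled", retained)
        rng = np.random.default_rng(5)
        perm = rng.permutation(tiny_matrix.counts.columns)
        matrix2 = type(tiny_matrix)(
            counts=tiny_matrix.counts[perm],
            probes=tiny_matrix.probes.copy(),
            samples=tiny_matrix.samples.loc[perm].copy(),
        )
        table2 = combined_rank_sum(matrix2, "pooled", retained)
        pd.testing.assert_frame_equal(table.frame, table2.frame)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            endog = {
                f"miR-{i:02d}": list(map(int, rng.integers(60, 4000, 6)))
                for i in range(10)
            }
            matrix = build_matrix(endog, ["g"] * 6)
            retained = set(endog)
            table = combined_rank_sum(matrix, "g", retained)

            # oracle: plain-python measures and average ranks per strategy
            def plain_ranks(values_by_probe):
                ordered = sorted(values_by_probe.values())
                ranks = {}
                for pid, v in values_by_probe.items():
                    below = len([w for w in ordered if w < v])
                    equal = len([w for w in ordered if w == v])
                    ranks[pid] = below + (equal + 1) / 2.0
                return ranks

            expected = {pid: 0.0 for pid in retained}
            for strategy in ("housekeeping", "total_mirna"):
                values = normalize_by_name(matrix, "g", retained, strategy).values
                per_measure = {
                    pid: variability_measures(values.loc[pid].to_numpy())
                    for pid in retained
                }
                for m_idx in range(4):
                    col = {p: per_measure[p][m_idx] for p in retained}
                    for pid, r in plain_ranks(col).items():
                        expected[pid] += r
            for pid in retained:
                assert table.frame.at[pid, "rank_sum"] == pytest.approx(expected[pid])


class TestTopK:
    def test_boundaries(self, tiny_matrix):
        retained = filter_probes(tiny_matrix, "pooled")
        table = combined_rank_sum(tiny_matrix, "pooled", retained)
        assert top_k_stable(table, 0) == []
        assert top_k_stable(table, len(retained)) == table.ordering
        with pytest.raises(ValueError):
            top_k_stable(table, len(retained) + 1)


def test_measure_frame_columns(tiny_matrix):
    retained = filter_probes(tiny_matrix, "pooled")
    normalized = normalize_by_name(tiny_matrix, "pooled", retained, "housekeeping")
    frame = measure_frame(normalized.values)
    assert list(frame.columns) == list(MEASURES)
    assert (frame >= 0).all().all()
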