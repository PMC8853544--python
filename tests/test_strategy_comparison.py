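import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirstab import (
    RankConcordanceInput,
    bh_adjust,
    build_union_list,
    compare_all_strategies,
    permutation_p,
    rank_distance,
    rank_distance_null,
)
from conftest import HK_IDS, POS_IDS, build_matrix


class TestBuildUnionList:
    def test_full_overlap_gives_five(self):
        var = {f"p{i}": float(i) for i in range(8)}
        rc = build_union_list(var, dict(var), k=5)
        assert len(rc.union_list) == 5
        assert rc.ranks_a == rc.ranks_b

    def test_disjoint_top_fives_give_ten(self):
        var_a = {f"p{i}": float(i) for i in range(10)}
        var_b = {f"p{i}": float(-i) for i in range(10)}
        rc = build_union_list(var_a, var_b, k=5)
        assert len(rc.union_list) == 10

    def test_reversed_variances_give_six(self):
        names = list("abcdef")
        var_a = {n: float(i + 1) for i, n in enumerate(names)}
        var_b = {n: float(6 - i) for i, n in enumerate(names)}
        rc = build_union_list(var_a, var_b, k=5)
        assert set(rc.union_list) == set(names)
        # ranks under A: a..f -> 1..6; under B: reversed -> T = 2*(5+3+1)
        assert rank_distance(rc.ranks_a, rc.ranks_b) == 18

    def test_ranks_are_permutations(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            probes = [f"p{i}" for i in range(12)]
            var_a = {p: float(v) for p, v in zip(probes, rng.random(12))}
            var_b = {p: float(v) for p, v in zip(probes, rng.random(12))}
            rc = build_union_list(var_a, var_b, k=5)
            n = len(rc.union_list)
            assert 5 <= n <= 10
            assert sorted(rc.ranks_a) == sorted(rc.ranks_b) == list(range(1, n + 1))

    def test_too_few_probes(self):
        with pytest.raises(ValueError):
            build_union_list({"a": 1.0}, {"a": 1.0}, k=5)

    def test_mismatched_probe_sets(self):
        with pytest.raises(ValueError):
            build_union_list({"a": 1.0, "b": 2.0}, {"a": 1.0, "c": 2.0}, k=1)


class TestRankDistance:
    def test_identical_rankings_zero(self):
        assert rank_distance([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 0

    def test_reversal_of_five(self):
        assert rank_distance([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == 12

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(2, 11))
            a = list(rng.permutation(n) + 1)
            b = list(rng.permutation(n) + 1)
            assert rank_distance(a, b) == rank_distance(b, a)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rank_distance([1, 2], [1, 2, 3])


class TestNullDistribution:
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_matches_enumeration(self, n):
        null = rank_distance_null(n)
        counted: dict[int, int] = {}
        for perm in itertools.permutations(range(n)):
            t = sum(abs(i - j) for i, j in enumerate(perm))
            counted[t] = counted.get(t, 0) + 1
        import math

        assert sum(null) == math.factorial(n)
        for t, c in enumerate(null):
            assert c == counted.get(t, 0)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_maximum_distance_is_half_n_squared(self, n):
        null = rank_distance_null(n)
        attained = max(t for t, c in enumerate(null) if c > 0)
        assert attained == n * n // 2


class TestPermutationP:
    def _rc(self, a, b, names=None):
        n = len(a)
        names = names or tuple(f"p{i}" for i in range(n))
        return RankConcordanceInput(union_list=tuple(names), ranks_a=tuple(a), ranks_b=tuple(b))

    def test_t_zero_gives_p_one(self):
        result = permutation_p(self._rc([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]))
        assert result.T_obs == 0 and result.p_unadjusted == 1.0

    def test_two_element_reversal_gives_half(self):
        result = permutation_p(self._rc([1, 2], [2, 1]))
        assert result.p_unadjusted == pytest.approx(0.5)

    def test_five_element_reversal_matches_enumeration(self):
        result = permutation_p(self._rc([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]))
        n_max = sum(
            1
            for perm in itertools.permutations(range(1, 6))
            if sum(abs(a - b) for a, b in zip([1, 2, 3, 4, 5], perm)) >= 12
        )
        assert result.T_obs == 12
        assert result.p_unadjusted == pytest.approx(n_max / 120)

    def test_monte_carlo_agrees_with_exhaustive(self):
        rng = np.random.default_rng(3)
        for i in range(5):
            n = int(rng.integers(4, 7))
            a = list(rng.permutation(n) + 1)
            b = list(rng.permutation(n) + 1)
            rc = self._rc(a, b)
            exact = permutation_p(rc).p_unadjusted
            mc = permutation_p(rc, mode="monte_carlo", n_mc=20_000, seed=int(i)).p_unadjusted
            se = np.sqrt(exact * (1 - exact) / 20_000)
            assert abs(mc - exact) <= max(3 * se, 2e-4)

    def test_exhaustive_refuses_large_lists(self):
        a = tuple(range(1, 13))
        rc = self._rc(a, a)
        with pytest.raises(ValueError):
            permutation_p(rc)


class TestBhAdjust:
    def test_published_six_comparison_vector(self):
        adjusted = bh_adjust([0.13, 0.014, 0.77, 0.77, 0.014, 0.014])
        np.testing.assert_allclose(
            adjusted, [0.195, 0.028, 0.77, 0.77, 0.028, 0.028], atol=1e-12
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_step_up_definition(self, p):
        adjusted = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, p[order[i]] * m / (i + 1))
            expected[order[i]] = running
        np.testing.assert_allclose(adjusted, expected, atol=1e-12)
        assert np.all(adjusted >= np.asarray(p) - 1e-15)


class TestCompareAllStrategies:
    def test_proportional_normalizers_give_identity_pair(self):
        # per-probe positive-control counts equal the housekeeping counts,
        # so the two normalizer totals are proportional (6/5) in every
        # sample: variance rankings coincide and T = 0, p = 1 for the pair
        rng = np.random.default_rng(6)
        endog = {
            f"miR-{i:02d}": list(map(int, rng.integers(60, 4000, 6))) for i in range(8)
        }
        hk_counts = rng.integers(500, 2000, 6) * 2
        hk = {pid: list(map(int, hk_counts)) for pid in HK_IDS}
        # 6 positives x 500 = 3000 per sample vs hk total 5 * hk_counts
        pos = {pid: list(map(int, hk_counts)) for pid in POS_IDS}
        matrix = build_matrix(endog, ["g"] * 6, hk=hk, pos=pos)
        results = compare_all_strategies(matrix, "g", k=5, top_k=8)
        by_pair = {r.pair: r for r in results}
        identical = by_pair[("housekeeping", "positive_control")]
        assert identical.T_obs == 0
        assert identical.p_unadjusted == 1.0
        assert len(results) == 6
        for r in results:
            assert r.p_adjusted >= r.p_unadjusted - 1e-15

    def test_sample_order_invariance(self, tiny_matrix):
        results = compare_all_strategies(tiny_matrix, "pooled", k=3, top_k=5)
        perm = np.random.default_rng(8).permutation(tiny_matrix.counts.columns)
        matrix2 = type(tiny_matrix)(
            counts=tiny_matrix.counts[perm],
            probes=tiny_matrix.probes.copy(),
            samples=tiny_matrix.samples.loc[perm].copy(),
        )
        results2 = compare_all_strategies(matrix2, "pooled", k=3, top_k=5)
        for r1, r2 in zip(results, results2):
            assert r1.pair == r2.pair
            assert r1.T_obs == r2.T_obs
            assert r1.p_unadjusted == r2.p_unadjusted
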