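import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vnscluster as vc
from vnscluster.errors import ValidationError
from vnscluster.evaluation import run_stats


def ari_pair_counting(a, b):
    """Independent ARI oracle: Hubert-Arabie permutation-model form computed
    straight from the contingency table with explicit loops."""
    a = list(a)
    b = list(b)
    n = len(a)
    cats_a = sorted(set(map(str, a)))
    cats_b = sorted(set(map(str, b)))
    table = {(x, y): 0 for x in cats_a for y in cats_b}
    for x, y in zip(a, b):
        table[(str(x), str(y))] += 1
    comb2 = lambda v: v * (v - 1) // 2
    index = sum(comb2(v) for v in table.values())
    sum_a = sum(comb2(sum(table[(x, y)] for y in cats_b)) for x in cats_a)
    sum_b = sum(comb2(sum(table[(x, y)] for x in cats_a)) for y in cats_b)
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        # only possible when both partitions are degenerate in the same way
        # (both all-singletons or both one cluster), i.e. identical: ARI = 1
        return 1.0
    return (index - expected) / (max_index - expected)


partitions = st.lists(st.integers(0, 4), min_size=2, max_size=40)


class TestAdjustedRandIndex:
    def test_identical_up_to_relabeling(self):
        assert vc.adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == pytest.approx(1.0)

    def test_single_cluster_vs_singletons_is_zero(self):
        # expected index equals index -> chance-level agreement
        assert vc.adjusted_rand_index([1, 1, 1, 1], [1, 2, 3, 4]) == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            vc.adjusted_rand_index([1, 2], [1, 2, 3])

    def test_random_partitions_agree_at_chance(self):
        rng = np.random.default_rng(0)
        vals = [
            vc.adjusted_rand_index(
                rng.integers(0, 5, size=1000), rng.integers(0, 5, size=1000)
            )
            for _ in range(200)
        ]
        assert abs(float(np.mean(vals))) < 0.01

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(a=partitions, seed=st.integers(0, 1000))
    def test_matches_independent_pair_counting_oracle(self, a, seed):
        rng = np.random.default_rng(seed)
        b = rng.integers(0, 4, size=len(a)).tolist()
        got = vc.adjusted_rand_index(a, b)
        expected = ari_pair_counting(a, b)
        if math.isfinite(expected):
            assert got == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=partitions, seed=st.integers(0, 1000))
    def test_symmetric_and_relabel_invariant(self, a, seed):
        rng = np.random.default_rng(seed)
        b = rng.integers(0, 4, size=len(a)).tolist()
        assert vc.adjusted_rand_index(a, b) == pytest.approx(
            vc.adjusted_rand_index(b, a)
        )
        relabel = {v: f"x{v}" for v in set(a)}
        assert vc.adjusted_rand_index([relabel[v] for v in a], b) == pytest.approx(
            vc.adjusted_rand_index(a, b)
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=partitions)
    def test_self_agreement_is_one(self, a):
        if len(set(a)) in (1, len(a)):
            return  # degenerate partitions have undefined self-ARI normalizer
        assert vc.adjusted_rand_index(a, a) == pytest.approx(1.0)


def err_sigma_straight_loop(per_run_F):
    """Independent recomputation of the batch statistics with plain loops."""
    f_best = min(per_run_F)
    errs = []
    for F in per_run_F:
        errs.append(0.0 if F == 0 else abs(F - f_best) / abs(F))
    err = sum(errs) / len(errs)
    sigma = math.sqrt(sum((e - err) ** 2 for e in errs) / len(errs))
    return f_best, err, sigma


class TestRunStats:
    def test_hand_worked_example(self):
        stats = run_stats([10.0, 10.0, 12.5])
        assert stats.f_VNS == 10.0
        assert stats.per_run_err == pytest.approx([0.0, 0.0, 0.2])
        assert stats.err == pytest.approx(0.2 / 3)  # 0.0667
        assert stats.sigma == pytest.approx(np.sqrt(2 * (0.2 / 3) ** 2 / 3 + (0.2 - 0.2 / 3) ** 2 / 3))

    def test_identical_runs_collapse(self):
        stats = run_stats([7.5] * 20)
        assert stats.err == 0.0 and stats.sigma == 0.0 and stats.f_VNS == 7.5

    def test_single_run(self):
        stats = run_stats([3.25])
        assert (stats.f_VNS, stats.err, stats.sigma) == (3.25, 0.0, 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        Fs=st.lists(
            st.floats(min_value=0.01, max_value=1e6, allow_nan=False), min_size=1, max_size=40
        )
    )
    def test_matches_straight_loop(self, Fs):
        stats = run_stats(Fs)
        f_best, err, sigma = err_sigma_straight_loop(Fs)
        assert stats.f_VNS == f_best
        assert stats.err == pytest.approx(err, abs=1e-12)
        assert stats.sigma == pytest.approx(sigma, abs=1e-12)

    def test_tie_for_best_resolves_to_earliest_seed(self):
        stats = run_stats([5.0, 4.0, 4.0], per_run_time=[1.0, 2.0, 3.0], seeds=[10, 11, 12])
        assert stats.best_index == 1
        assert stats.t_VNS == 2.0


class TestRunBatch:
    def test_batch_over_two_pair(self, two_pair_D, feasibility_check):
        cfg = vc.VNSConfig(k=2, alpha=0.0, max_iter=100, seed=0, n_runs=5)
        stats, best, _ = vc.run_batch(two_pair_D, cfg)
        assert stats.f_VNS == pytest.approx(2.0)
        assert stats.seeds == [0, 1, 2, 3, 4]
        assert best.F == stats.f_VNS
        feasibility_check(best, two_pair_D, 2)

    def test_batch_deterministic(self, random_instance):
        D = vc.build_distance_model(random_instance(20, seed=2), alpha=0.5)
        cfg = vc.VNSConfig(k=3, alpha=0.5, max_iter=60, seed=7, n_runs=4)
        s1, b1, _ = vc.run_batch(D, cfg)
        s2, b2, _ = vc.run_batch(D, cfg)
        assert s1.per_run_F == s2.per_run_F
        np.testing.assert_array_equal(b1.Y, b2.Y)
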