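import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vnscluster as vc
from vnscluster.errors import ConfigError, ShakeError, SolutionError
from vnscluster.vns import (
    assign,
    initial_solution,
    local_search,
    neighbor_order,
    objective,
    shake,
)


def toy_distance(matrix, alpha=0.0):
    m = np.asarray(matrix, dtype=float)
    return vc.DistanceModel(matrix=m, alpha=alpha)


class TestAssign:
    def test_forced_by_minimality(self):
        D = toy_distance(
            [[0, 1, 3, 2], [1, 0, 3, 4], [3, 3, 0, 1], [2, 4, 1, 0]]
        )
        X = assign([0, 2], D)
        assert X[1] == 0  # D(1,0)=1 < D(1,2)=3

    def test_centroids_self_assigned(self, random_instance):
        D = vc.build_distance_model(random_instance(10, seed=4), alpha=0.5)
        X = assign([1, 5, 8], D)
        assert X[1] == 1 and X[5] == 5 and X[8] == 8

    def test_tie_breaks_to_lowest_centroid_index(self):
        D = toy_distance([[0, 5, 5, 2], [5, 0, 5, 2], [5, 5, 0, 9], [2, 2, 9, 0]])
        # cell 3 equidistant (2) from centroids 0 and 1
        assert assign([1, 0], D)[3] == 0

    def test_duplicate_Y_rejected(self, two_pair_D):
        with pytest.raises(SolutionError):
            assign([0, 0], two_pair_D)


class TestObjective:
    def test_all_cells_centroids_gives_zero(self, random_instance):
        D = vc.build_distance_model(random_instance(6, seed=2), alpha=0.8)
        assert objective(range(6), D) == 0.0

    def test_two_pair_optimum_value(self, two_pair_D):
        # one representative per pair: F = 1 + 1 (enumeration-confirmed optimum)
        assert objective([0, 2], two_pair_D) == pytest.approx(2.0)

    def test_duplicated_cell_adds_zero(self):
        ds = vc.two_pair_instance()
        dup = vc.CellDataset(
            ds.cell_ids + ["c5"],
            np.vstack([ds.coords, ds.coords[0]]),
            np.vstack([ds.embeddings, ds.embeddings[0]]),
        )
        D4 = vc.build_distance_model(ds, alpha=0.0)
        D5 = vc.build_distance_model(dup, alpha=0.0)
        assert objective([0, 2], D5) == pytest.approx(objective([0, 2], D4))


class TestInitialSolution:
    def test_full_subset_when_k_equals_n(self):
        rng = np.random.default_rng(0)
        assert set(initial_solution(5, 5, rng)) == {0, 1, 2, 3, 4}

    def test_deterministic_per_seed(self):
        a = initial_solution(100, 3, np.random.default_rng(42))
        b = initial_solution(100, 3, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_uniform_over_cells(self):
        # n=5, K=1: each cell should appear with frequency 0.2 +/- 0.02
        rng = np.random.default_rng(7)
        draws = [initial_solution(5, 1, rng)[0] for _ in range(10_000)]
        freq = np.bincount(draws, minlength=5) / 10_000
        np.testing.assert_allclose(freq, 0.2, atol=0.02)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ConfigError):
            initial_solution(3, 4, np.random.default_rng(0))


class TestShake:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(4, 30),
        k_frac=st.integers(1, 100),
        seed=st.integers(0, 10_000),
    )
    def test_shake_contract(self, n, k_frac, seed):
        """Y' keeps exactly K-k incumbents, entrants come from outside Y,
        and all K entries stay distinct."""
        rng = np.random.default_rng(seed)
        K = int(rng.integers(1, n))
        k = 1 + (k_frac * min(K, n - K)) // 101
        Y = rng.choice(n, size=K, replace=False)
        Yp = shake(Y, k, n, rng)
        assert np.unique(Yp).size == K
        kept = set(Yp) & set(Y)
        assert len(kept) == K - k
        assert all(0 <= y < n for y in Yp)
        assert (set(Yp) - set(Y)).isdisjoint(set(Y))

    def test_full_shake_disjoint(self):
        rng = np.random.default_rng(1)
        Y = np.array([1, 2, 3])
        Yp = shake(Y, 3, 10, rng)
        assert set(Yp).isdisjoint({1, 2, 3})

    def test_empty_pool_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ShakeError):
            shake(np.arange(4), 1, 4, rng)

    def test_pool_smaller_than_k_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ShakeError):
            shake(np.arange(4), 2, 5, rng)


class TestLocalSearch:
    def test_m_zero_returns_input(self, two_pair_D):
        rng = np.random.default_rng(0)
        Yp = np.array([0, 1])
        out = local_search(Yp, two_pair_D, m=0, p=5, F_star=100.0, rng=rng)
        np.testing.assert_array_equal(out, Yp)

    def test_no_strict_improvement_returns_input(self, two_pair_D):
        # Y'=[0,3] is already optimal (F=2.0 = enumeration optimum), so no
        # pass can beat F_star and Y' must come back unchanged after p passes
        assert vc.solve_exact(two_pair_D, 2).best_F == pytest.approx(2.0)
        rng = np.random.default_rng(5)
        Yp = np.array([0, 3])
        out = local_search(Yp, two_pair_D, m=3, p=20, F_star=2.0, rng=rng)
        np.testing.assert_array_equal(out, Yp)

    def test_finds_improvement_with_high_probability(self, random_instance):
        """From a deliberately bad start on a 20-cell instance, persistent
        passes should find a strictly better vector nearly always."""
        ds = random_instance(20, seed=11)
        D = vc.build_distance_model(ds, alpha=0.5, normalize_coords=True)
        nn = neighbor_order(D)
        # worst 2-subset by objective among a few candidates
        bad_Y = max(
            ([i, j] for i in range(5) for j in range(i + 1, 8)),
            key=lambda y: objective(y, D),
        )
        F_bad = objective(bad_Y, D)
        improved = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            out = local_search(np.array(bad_Y), D, m=5, p=50, F_star=F_bad, rng=rng, nn_order=nn)
            improved += objective(out, D) < F_bad
        assert improved >= 95

    def test_result_stays_feasible(self, random_instance):
        ds = random_instance(15, seed=3)
        D = vc.build_distance_model(ds, alpha=0.2)
        rng = np.random.default_rng(9)
        for _ in range(20):
            Yp = initial_solution(15, 4, rng)
            out = local_search(Yp, D, m=6, p=3, F_star=objective(Yp, D), rng=rng)
            assert np.unique(out).size == 4
            assert out.min() >= 0 and out.max() < 15


class TestVnsRun:
    def test_zero_iterations_returns_initial(self, two_pair_D):
        cfg = vc.VNSConfig(k=2, alpha=0.0, max_iter=0, seed=8)
        sol, trace = vc.vns_run(two_pair_D, cfg)
        assert len(trace.F_star) == 1
        assert sol.F == pytest.approx(trace.F_star[0])

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_two_pair_reaches_optimum(self, two_pair_D, seed, feasibility_check):
        cfg = vc.VNSConfig(k=2, alpha=0.0, max_iter=200, seed=seed)
        sol, _ = vc.vns_run(two_pair_D, cfg)
        assert sol.F == pytest.approx(2.0)
        feasibility_check(sol, two_pair_D, 2)

    def test_trace_monotone_nonincreasing(self, random_instance):
        D = vc.build_distance_model(random_instance(30, seed=6), alpha=0.5)
        for seed in range(5):
            _, trace = vc.vns_run(D, vc.VNSConfig(k=4, alpha=0.5, max_iter=150, seed=seed))
            F = np.asarray(trace.F_star)
            assert np.all(np.diff(F) <= 0.0)

    def test_bit_identical_under_same_seed(self, random_instance):
        D = vc.build_distance_model(random_instance(25, seed=8), alpha=0.9)
        cfg = vc.VNSConfig(k=3, alpha=0.9, max_iter=100, seed=123)
        s1, t1 = vc.vns_run(D, cfg)
        s2, t2 = vc.vns_run(D, cfg)
        np.testing.assert_array_equal(s1.Y, s2.Y)
        np.testing.assert_array_equal(s1.X, s2.X)
        assert s1.F == s2.F
        assert t1.F_star == t2.F_star

    def test_k_equals_n_degenerate(self, random_instance):
        D = vc.build_distance_model(random_instance(5, seed=1), alpha=0.5)
        sol, _ = vc.vns_run(D, vc.VNSConfig(k=5, alpha=0.5, max_iter=50, seed=0))
        assert sol.F == 0.0
        assert set(sol.Y) == set(range(5))

    def test_solutions_feasible_across_seeds(self, random_instance, feasibility_check):
        ds = random_instance(18, seed=10)
        D = vc.build_distance_model(ds, alpha=0.5, normalize_coords=True)
        for seed in range(8):
            sol, _ = vc.vns_run(D, vc.VNSConfig(k=3, alpha=0.5, max_iter=80, seed=seed))
            feasibility_check(sol, D, 3)


class TestVNSConfig:
    def test_k_max_cannot_exceed_k(self):
        with pytest.raises(ConfigError):
            vc.VNSConfig(k=3, k_max=5)

    def test_alpha_range(self):
        with pytest.raises(ConfigError):
            vc.VNSConfig(k=2, alpha=-0.1)

    def test_k_max_defaults_to_min_10_K(self):
        assert vc.VNSConfig(k=3).resolved_k_max() == 3
        assert vc.VNSConfig(k=50).resolved_k_max() == 10

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ConfigError):
            vc.VNSConfig(k=10).validate_against(5)
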