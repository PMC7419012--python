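"""Edit distance, recurrence quantification and Lyapunov spectra."""

import itertools

import numpy as np
import pytest

from olivenet.chaos import (EditCostScheme, complexity_entropy,
                            diagonal_line_lengths, distance_matrix_repair,
                            edit_distance, entropy_lyapunov_map, kaplan_yorke,
                            lyapunov_spectrum, modified_edit_distance,
                            recurrence_plot, spike_train_recurrence)


def brute_force_edit_distance(a, b, costs=EditCostScheme()):
    """Oracle: enumerate all monotone matchings between the two windows."""
    a, b = list(a), list(b)
    best = np.inf
    na, nb = len(a), len(b)
    k_max = min(na, nb)
    for k in range(k_max + 1):
        for ia in itertools.combinations(range(na), k):
            for ib in itertools.combinations(range(nb), k):
                cost = (na - k) * costs.delete + (nb - k) * costs.insert
                cost += sum(costs.shift_per_s * abs(a[i] - b[j])
                            for i, j in zip(ia, ib))
                best = min(best, cost)
    return best


class TestEditDistance:
    def test_identical_windows_zero(self):
        t = [0.5, 1.2, 3.3]
        assert edit_distance(t, t) == 0.0

    def test_single_spike_versus_empty_costs_one(self):
        assert edit_distance([1.0], []) == 1.0
        assert edit_distance([], [1.0]) == 1.0

    def test_shift_versus_delete_insert_tradeoff(self):
        # 1-s shift costs 0.2; a 12-s shift (2.4) loses to delete+insert (2)
        assert edit_distance([1.0], [2.0]) == pytest.approx(0.2)
        assert edit_distance([1.0], [13.0]) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_small_windows(self, seed):
        rng = np.random.default_rng(seed)
        a = np.sort(rng.uniform(0, 10, rng.integers(0, 6)))
        b = np.sort(rng.uniform(0, 10, rng.integers(0, 6)))
        assert edit_distance(a, b) == pytest.approx(
            brute_force_edit_distance(a, b))

    def test_symmetry(self, rng):
        a = np.sort(rng.uniform(0, 50, 20))
        b = np.sort(rng.uniform(0, 50, 25))
        assert edit_distance(a, b) == pytest.approx(edit_distance(b, a))


class TestModifiedEditDistance:
    def test_no_boundary_spikes_equals_plain(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.5, 2.5])
        plain = edit_distance(a, b)
        assert modified_edit_distance(a, 0.0, b, 0.0, window=5.0) == \
            pytest.approx(plain)

    def test_boundary_spike_reduces_distance(self):
        # a has a spike just outside its right edge matching a spike just
        # inside b's window: including it converts delete+insert to a shift
        a = np.array([1.0, 5.05])
        b = np.array([1.0, 4.95])
        window = 5.0
        plain = edit_distance(a[a < window], b)
        mod = modified_edit_distance(a, 0.0, b, 0.0, window=window)
        assert mod < plain

    def test_symmetric_in_argument_order(self, rng):
        a = np.sort(rng.uniform(0, 20, 15))
        b = np.sort(rng.uniform(0, 20, 18))
        d1 = modified_edit_distance(a, 2.0, b, 6.0, window=10.0)
        d2 = modified_edit_distance(b, 6.0, a, 2.0, window=10.0)
        assert d1 == pytest.approx(d2)


def brute_floyd_warshall(D):
    n = D.shape[0]
    R = D.copy().astype(float)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                R[i, j] = min(R[i, j], R[i, k] + R[k, j])
    return R


class TestDistanceRepair:
    def test_metric_matrix_unchanged(self):
        D = np.array([[0, 1, 2], [1, 0, 1.5], [2, 1.5, 0.0]])
        np.testing.assert_allclose(distance_matrix_repair(D), D)

    def test_hand_shortcut(self):
        D = np.array([[0, 5, 10], [5, 0, 1], [10, 1, 0.0]])
        R = distance_matrix_repair(D)
        assert R[0, 2] == pytest.approx(6.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_floyd_warshall(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        D = rng.uniform(0.1, 10, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        np.testing.assert_allclose(distance_matrix_repair(D),
                                   brute_floyd_warshall(D))

    def test_never_increases_and_idempotent(self, rng):
        n = 12
        D = rng.uniform(0.1, 10, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        R = distance_matrix_repair(D)
        assert np.all(R <= D + 1e-12)
        np.testing.assert_allclose(distance_matrix_repair(R), R)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            distance_matrix_repair(np.array([[0, 1], [2, 0.0]]))


class TestRecurrencePlot:
    def test_exact_ten_percent_for_distinct_values(self, rng):
        n = 15  # 105 distinct off-diagonal values
        D = rng.permutation(np.arange(1.0, n * (n - 1) / 2 + 1))
        M = np.zeros((n, n))
        M[np.triu_indices(n, 1)] = D
        M = M + M.T
        R, thresh = recurrence_plot(M, rate=0.10)
        marked = R[np.triu_indices(n, 1)].sum()
        assert marked == round(0.10 * n * (n - 1) / 2)

    def test_symmetric_with_recurrent_main_diagonal(self, rng):
        n = 12
        D = rng.uniform(1, 10, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        R, _ = recurrence_plot(D)
        np.testing.assert_array_equal(R, R.T)
        assert np.all(np.diag(R) == 1)

    def test_all_equal_distances_rejected(self):
        D = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError, match="threshold undefined"):
            recurrence_plot(D)


class TestComplexityEntropy:
    def test_two_equal_length_classes_give_complexity_one(self):
        # plot with one diagonal run of length 2 and one of length 3:
        # H = 1 bit, complexity = 1/H = 1
        n = 9
        R = np.eye(n, dtype=int)
        for i in range(2):       # run of length 2 at offset 2
            R[i, i + 2] = R[i + 2, i] = 1
        for i in range(4, 7):    # run of length 3 at offset 4... build offset 4
            R[i - 4, i] = R[i, i - 4] = 1
        lengths = diagonal_line_lengths(R)
        assert sorted(lengths.tolist()) == [2, 3]
        assert complexity_entropy(R) == pytest.approx(1.0)

    def test_single_length_class_gives_sentinel(self):
        n = 8
        R = np.eye(n, dtype=int)
        R[0, 2] = R[1, 3] = 1
        R[2, 0] = R[3, 1] = 1
        with pytest.warns(UserWarning):
            assert np.isnan(complexity_entropy(R))

    def test_periodic_train_has_long_diagonals(self):
        # strictly periodic spiking: every window pair is similar, and the
        # line-length distribution is dominated by long runs
        t = np.arange(0.25, 200.0, 0.5)
        rs = spike_train_recurrence(t + 0.01 * np.sin(t), 200.0,
                                    window=20.0, step=2.0)
        assert rs.line_lengths.max() >= 10


class TestLyapunov:
    def test_linear_system_exponents_match_eigenvalue_real_parts(self):
        A = np.array([[0.1, -1.0, 0.0],
                      [1.0, 0.1, 0.0],
                      [0.0, 0.0, -0.5]])
        f = lambda x: A @ x
        lam = lyapunov_spectrum(f, np.array([0.1, 0.1, 0.1]), dt=5e-3,
                                duration=400.0, transient=0.0,
                                tangent_transient=50.0, units="nats",
                                jac=lambda x: A)
        expected = np.sort(np.linalg.eigvals(A).real)[::-1]
        np.testing.assert_allclose(lam, expected, atol=0.02)

    def test_damped_oscillator_negative_exponents(self):
        A = np.array([[-0.2, -1.0], [1.0, -0.2]])
        lam = lyapunov_spectrum(lambda x: A @ x, np.array([1.0, 0.0]),
                                dt=5e-3, duration=100.0, transient=0.0,
                                tangent_transient=20.0, units="nats")
        np.testing.assert_allclose(lam, [-0.2, -0.2], atol=0.02)

    def test_limit_cycle_has_zero_leading_exponent(self):
        # van der Pol oscillator: one zero exponent along the cycle
        def f(x):
            return np.array([x[1], 2.0 * (1 - x[0] ** 2) * x[1] - x[0]])
        lam = lyapunov_spectrum(f, np.array([0.5, 0.0]), dt=1e-3,
                                duration=300.0, transient=50.0,
                                tangent_transient=50.0, units="nats")
        assert abs(lam[0]) < 0.03
        assert lam[1] < -0.1

    def test_kaplan_yorke_hand_value(self):
        # (0.1, 0, -0.5): k=2, D = 2 + 0.1/0.5 = 2.2
        assert kaplan_yorke([0.1, 0.0, -0.5]) == pytest.approx(2.2)

    def test_kaplan_yorke_edge_cases(self):
        assert kaplan_yorke([-0.1, -0.5]) == 0.0
        assert kaplan_yorke([0.3, 0.1]) == 2.0


class TestEntropyLyapunovMap:
    def test_perfect_linear_pairs_give_r2_one(self):
        e = np.linspace(0.2, 0.25, 20)
        lam = 700.0 * e - 140.0
        res = entropy_lyapunov_map(e, lam)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(700.0)
        assert res["predict"](0.21) == pytest.approx(7.0)

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError):
            entropy_lyapunov_map([0.2, 0.2, 0.2], [1.0, 2.0, 3.0])
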