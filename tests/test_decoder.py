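"""Transition models and Viterbi decoding."""

import itertools

import numpy as np
import pytest

import lapaint as lp
from lapaint.decoder import TransitionModel, viterbi_decode


def brute_force_best_path(logpost, model):
    """Exhaustive maximum over all K^T state sequences."""
    T, K = logpost.shape
    log_pi = model.log_pi()
    logA = model.log_A()
    best, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        score = log_pi[path[0]] + logpost[0, path[0]]
        for t in range(1, T):
            score += logA[path[t - 1], path[t]] + logpost[t, path[t]]
        if score > best:
            best, best_path = score, path
    return best, best_path


class TestPenaltyTransitions:
    def test_zero_penalty_is_uniform(self):
        m = lp.build_transition_penalty(9, 0.0)
        np.testing.assert_allclose(m.A, np.full((9, 9), 1 / 9))

    def test_printed_formula_at_large_penalty(self):
        m = lp.build_transition_penalty(9, 10_000.0)
        off = m.A[~np.eye(9, dtype=bool)]
        np.testing.assert_allclose(off, 1 / 10_009)
        np.testing.assert_allclose(np.diag(m.A), 1 - 8 / 10_009)

    @pytest.mark.parametrize("K", [1, 2, 5, 9])
    @pytest.mark.parametrize("x", [0.0, 1.0, 37.0, 1e4, 1e9])
    def test_rows_sum_to_one_exactly(self, K, x):
        m = lp.build_transition_penalty(K, x)
        np.testing.assert_allclose(m.A.sum(axis=1), 1.0, atol=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lp.build_transition_penalty(0, 1.0)
        with pytest.raises(ValueError):
            lp.build_transition_penalty(3, -1.0)


class TestDistanceTransitions:
    def test_equal_distances_reduce_to_penalty_model(self):
        D = np.full((4, 4), 2.5)
        np.fill_diagonal(D, 0.0)
        m = lp.build_transition_distance(D, penalty=100.0)
        ref = lp.build_transition_penalty(4, 100.0)
        np.testing.assert_allclose(m.A, ref.A, atol=1e-12)

    def test_k2_off_diagonals_independent_of_distance(self):
        for d in (0.1, 5.0):
            D = np.array([[0.0, d], [d, 0.0]])
            m = lp.build_transition_distance(D, self_weight=0.9)
            np.testing.assert_allclose(m.A[0, 1], 0.1)
            np.testing.assert_allclose(m.A[1, 0], 0.1)

    def test_inverse_distance_ratio_identity(self):
        rng = np.random.default_rng(0)
        K = 5
        D = rng.uniform(0.5, 3.0, size=(K, K))
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        m = lp.build_transition_distance(D, self_weight=0.8)
        np.testing.assert_allclose(m.A.sum(axis=1), 1.0, atol=1e-12)
        for i in range(K):
            for j in range(K):
                for k in range(K):
                    if len({i, j, k}) == 3:
                        assert m.A[i, j] / m.A[i, k] == \
                            pytest.approx(D[i, k] / D[i, j])

    def test_zero_distance_is_error(self):
        D = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="zero off-diagonal"):
            lp.build_transition_distance(D)

    def test_asymmetric_distance_warns_and_symmetrizes(self):
        D = np.array([[0.0, 1.0, 2.0], [3.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.warns(UserWarning, match="symmetriz"):
            m = lp.build_transition_distance(D, self_weight=0.5)
        ref = lp.build_transition_distance(0.5 * (D + D.T), self_weight=0.5)
        np.testing.assert_allclose(m.A, ref.A, atol=1e-12)


class TestViterbi:
    def test_single_state_chain(self):
        m = lp.build_transition_penalty(1, 5.0)
        trace = viterbi_decode(np.zeros((6, 1)), m)
        np.testing.assert_array_equal(trace.path, np.zeros(6, dtype=int))

    def test_single_window_is_prior_weighted_argmax(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=(1, 4))
        pi = rng.dirichlet(np.ones(4))
        m = lp.build_transition_penalty(4, 3.0, pi=pi)
        trace = viterbi_decode(e, m)
        assert trace.path[0] == np.argmax(np.log(pi) + e[0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 5))
        T = int(rng.integers(1, 7))
        e = rng.normal(scale=3.0, size=(T, K))
        x = float(rng.uniform(0, 50))
        m = lp.build_transition_penalty(K, x, pi=rng.dirichlet(np.ones(K)))
        trace = viterbi_decode(e, m)
        best, _ = brute_force_best_path(e, m)
        assert trace.log_prob == pytest.approx(best, abs=1e-9)

    def test_tie_breaks_toward_lowest_state(self):
        m = lp.build_transition_penalty(3, 0.0)  # fully symmetric
        trace = viterbi_decode(np.zeros((4, 3)), m)
        np.testing.assert_array_equal(trace.path, np.zeros(4, dtype=int))

    def test_beats_random_state_sequences(self):
        rng = np.random.default_rng(1)
        T, K = 12, 3
        e = rng.normal(size=(T, K))
        m = lp.build_transition_penalty(K, 7.0)
        trace = viterbi_decode(e, m)
        log_pi, logA = m.log_pi(), m.log_A()
        for _ in range(1000):
            path = rng.integers(0, K, size=T)
            score = log_pi[path[0]] + e[0, path[0]]
            score += sum(logA[path[t - 1], path[t]] + e[t, path[t]]
                         for t in range(1, T))
            assert score <= trace.log_prob + 1e-9

    def test_invariant_to_row_constants(self):
        rng = np.random.default_rng(2)
        e = rng.normal(size=(10, 3))
        m = lp.build_transition_penalty(3, 10.0)
        shifted = e + rng.normal(scale=50.0, size=(10, 1))
        np.testing.assert_array_equal(viterbi_decode(e, m).path,
                                      viterbi_decode(shifted, m).path)

    def test_switches_non_increasing_in_penalty(self):
        rng = np.random.default_rng(3)
        e = rng.normal(scale=2.0, size=(60, 4))
        counts = []
        for x in (0.0, 10.0, 100.0, 1000.0, 10000.0):
            m = lp.build_transition_penalty(4, x)
            counts.append(viterbi_decode(e, m).n_switches)
        assert counts == sorted(counts, reverse=True)

    def test_extreme_penalty_freezes_path_at_summed_argmax(self):
        """When log(K+x) exceeds the total emission preference, no switch pays."""
        rng = np.random.default_rng(4)
        e = rng.normal(scale=0.3, size=(8, 3))  # total preference << 20.7
        m = lp.build_transition_penalty(3, 1e9)
        trace = viterbi_decode(e, m)
        assert trace.n_switches == 0
        assert trace.path[0] == np.argmax(m.log_pi() + e.sum(axis=0))

    def test_no_admissible_path_raises(self):
        m = TransitionModel(A=np.eye(2), pi=np.array([1.0, 0.0]))
        e = np.array([[0.0, 0.0], [-np.inf, 0.0]])
        with pytest.raises(ValueError, match="no admissible path"):
            viterbi_decode(e, m)
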