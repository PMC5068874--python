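"""Transition counting, probability estimation, weights and entropy rate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from behentropy import (
    Ethogram,
    JumpChain,
    NoTransitionsError,
    ParameterError,
    count_transitions,
    entropy_rate,
    estimate_transition_matrix,
    max_entropy_rate,
    simulate_jump_chain,
    stationary_distribution,
    stationary_weights,
)
from behentropy.bouts import segment_bouts

from conftest import make_session, random_irreducible_matrix


def seq_from_letters(letters, session_id="s1"):
    """Bout sequence with unit durations from a string of state letters."""
    intervals = [(i, i + 1, c) for i, c in enumerate(letters)]
    return segment_bouts(
        make_session(intervals, session_id=session_id, window=(0, len(letters)))
    )


class TestCountTransitions:
    def test_enumerated_counts(self, abc_ethogram):
        seq = seq_from_letters("ABAC")
        N = count_transitions([seq], abc_ethogram)
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = expected[0, 2] = 1
        assert np.array_equal(N, expected)
        assert N.sum() == 3

    def test_single_bout_session_has_no_transitions(self, abc_ethogram):
        assert count_transitions([seq_from_letters("A")], abc_ethogram).sum() == 0

    def test_transitions_never_span_sessions(self, abc_ethogram):
        seqs = [seq_from_letters("AB", "s1"), seq_from_letters("BA", "s2")]
        N = count_transitions(seqs, abc_ethogram)
        assert N[0, 1] == 1 and N[1, 0] == 1 and N.sum() == 2  # no B->B

    def test_splitting_a_session_removes_exactly_one_transition(
        self, abc_ethogram
    ):
        whole = [seq_from_letters("ABCABC")]
        parts = [seq_from_letters("ABC", "s1"), seq_from_letters("ABC", "s2")]
        n_whole = count_transitions(whole, abc_ethogram).sum()
        n_parts = count_transitions(parts, abc_ethogram).sum()
        assert n_parts == n_whole - 1

    def test_gap_separated_same_behavior_bouts_do_not_count(self, abc_ethogram):
        sess = make_session(
            [(0, 2, "A"), (5, 7, "A"), (7, 9, "B")], window=(0, 20)
        )
        N = count_transitions([segment_bouts(sess)], abc_ethogram)
        assert N[0, 0] == 0 and N[0, 1] == 1 and N.sum() == 1


class TestEstimateTransitionMatrix:
    def test_row_normalization(self):
        N = np.array([[0, 3, 1], [1, 0, 0], [2, 2, 0]])
        P = estimate_transition_matrix(N)
        assert np.allclose(P[0], [0, 0.75, 0.25])
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diag(P) == 0)

    def test_single_outgoing_count_gives_certainty(self):
        N = np.array([[0, 1, 0], [1, 0, 0], [1, 0, 0]])
        assert estimate_transition_matrix(N)[0, 1] == 1.0

    def test_pseudocount_fills_empty_rows(self):
        N = np.array([[0, 0, 0], [1, 0, 1], [1, 1, 0]])
        P = estimate_transition_matrix(N, pseudocount=1.0)
        assert np.allclose(P[0], [0, 0.5, 0.5])

    def test_empty_row_without_pseudocount_is_nan(self):
        N = np.array([[0, 0, 0], [1, 0, 1], [1, 1, 0]])
        P = estimate_transition_matrix(N)
        assert np.isnan(P[0, 1]) and np.allclose(P[1:].sum(axis=1), 1.0)

    def test_all_zero_counts_error(self):
        with pytest.raises(NoTransitionsError):
            estimate_transition_matrix(np.zeros((3, 3)))


class TestStationaryWeights:
    def test_deterministic_cycle_is_uniform_by_both_methods(self):
        N = 10 * np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        P = estimate_transition_matrix(N)
        for method in ("empirical", "eigen"):
            w = stationary_weights(N, P, method=method)
            assert np.allclose(w, 1 / 3)

    def test_period_two_chain_eigen(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        N = np.array([[0, 5], [4, 0]])
        w = stationary_weights(N, P, method="eigen")
        assert np.allclose(w, [0.5, 0.5])

    def test_eigen_matches_independent_linear_solve(self):
        P = np.array([[0, 0.8, 0.2], [0.5, 0, 0.5], [0.9, 0.1, 0]])
        # independent oracle: eliminate w2, w3 by hand from w = wP, sum w = 1
        A = np.vstack([(P - np.eye(3)).T[:2], np.ones(3)])
        w_oracle = np.linalg.lstsq(A, np.array([0.0, 0.0, 1.0]), rcond=None)[0]
        w = stationary_distribution(P)
        assert np.allclose(w, w_oracle, atol=1e-10)
        assert np.abs(w @ P - w).sum() < 1e-10

    def test_reducible_chain_falls_back_to_empirical(self):
        # two disjoint 2-cycles: stationary weights are not unique
        N = np.array(
            [[0, 3, 0, 0], [3, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]]
        )
        P = estimate_transition_matrix(N)
        with pytest.warns(UserWarning, match="empirical"):
            w = stationary_weights(N, P, method="eigen")
        assert np.allclose(w, N.sum(axis=1) / N.sum())

    def test_no_transitions_is_an_error(self):
        with pytest.raises(NoTransitionsError):
            stationary_weights(np.zeros((3, 3)), method="empirical")


class TestEntropyRate:
    def test_deterministic_cycle_has_zero_entropy(self):
        P = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        w = np.full(3, 1 / 3)
        assert entropy_rate(P, w, base=2) == 0.0

    @pytest.mark.parametrize("k", [3, 6])
    def test_uniform_off_diagonal_attains_log_k_minus_1(self, k):
        P = np.full((k, k), 1 / (k - 1))
        np.fill_diagonal(P, 0.0)
        w = np.full(k, 1 / k)
        assert entropy_rate(P, w, base=2) == pytest.approx(
            np.log2(k - 1), abs=1e-12
        )
        assert max_entropy_rate(k) == pytest.approx(np.log2(k - 1))

    def test_matches_hand_computed_weighted_row_entropies(self):
        P = np.array([[0, 0.8, 0.2], [0.5, 0, 0.5], [0.9, 0.1, 0]])
        w = stationary_distribution(P)
        rows = [
            -(0.8 * np.log2(0.8) + 0.2 * np.log2(0.2)),
            1.0,
            -(0.9 * np.log2(0.9) + 0.1 * np.log2(0.1)),
        ]
        assert entropy_rate(P, w) == pytest.approx(float(w @ rows), abs=1e-12)

    def test_monte_carlo_long_run_oracle(self):
        """Empirical conditional entropy of a simulated path matches H."""
        P = np.array([[0, 0.8, 0.2], [0.5, 0, 0.5], [0.9, 0.1, 0]])
        H = entropy_rate(P, stationary_distribution(P))
        rng = np.random.default_rng(11)
        path = simulate_jump_chain(P, 10**6, rng)
        N = np.zeros((3, 3))
        np.add.at(N, (path[:-1], path[1:]), 1)
        H_hat = entropy_rate(
            estimate_transition_matrix(N), N.sum(axis=1) / N.sum()
        )
        assert H_hat == pytest.approx(H, abs=0.005)

    def test_base_conversion(self):
        P = np.array([[0, 0.5, 0.5], [1, 0, 0], [1, 0, 0]])
        w = np.array([0.5, 0.25, 0.25])
        assert entropy_rate(P, w, base=np.e) == pytest.approx(
            entropy_rate(P, w, base=2) * np.log(2), abs=1e-12
        )

    def test_bad_base_rejected(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ParameterError):
            entropy_rate(P, np.array([0.5, 0.5]), base=1.0)


class TestEstimatorConsistency:
    def test_recovers_known_matrix_and_entropy(self):
        """Estimates converge to truth on long simulated jump chains."""
        rng = np.random.default_rng(5)
        P = random_irreducible_matrix(6, rng)
        H = entropy_rate(P, stationary_distribution(P))
        path = simulate_jump_chain(P, 50_000, rng)
        N = np.zeros((6, 6))
        np.add.at(N, (path[:-1], path[1:]), 1)
        P_hat = estimate_transition_matrix(N)
        w_hat = stationary_weights(N, P_hat, method="empirical")
        assert np.nanmax(np.abs(P_hat - P)) < 0.02
        assert abs(entropy_rate(P_hat, w_hat) - H) < 0.02


class TestInvariants:
    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10**6))
    def test_entropy_bounds_and_row_sums(self, seed):
        """0 <= H <= log2(k-1) and fitted rows are stochastic."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        labels = tuple(chr(65 + i) for i in range(k))
        eth = Ethogram(labels)
        path = simulate_jump_chain(
            random_irreducible_matrix(k, rng), 200, rng
        )
        letters = "".join(labels[s] for s in path)
        model = JumpChain([seq_from_letters(letters)], eth).fit()
        P = model.probs
        fitted_rows = ~np.isnan(P).any(axis=1)
        assert np.allclose(P[fitted_rows].sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diag(model.counts) == 0)
        H = model.entropy_rate()
        assert -1e-12 <= H <= max_entropy_rate(k) + 1e-12

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10**6))
    def test_permutation_invariance(self, seed):
        """Relabeling states leaves entropy and fragmentation unchanged."""
        from behentropy import fragmentation_metrics

        rng = np.random.default_rng(seed)
        k = 4
        labels = ("A", "B", "C", "D")
        path = simulate_jump_chain(
            random_irreducible_matrix(k, rng), 150, rng
        )
        letters = "".join(labels[s] for s in path)
        perm = rng.permutation(k)
        mapping = {labels[i]: labels[perm[i]] for i in range(k)}
        permuted = "".join(mapping[c] for c in letters)

        m1 = JumpChain([seq_from_letters(letters)], Ethogram(labels)).fit()
        m2 = JumpChain([seq_from_letters(permuted)], Ethogram(labels)).fit()
        assert m2.entropy_rate() == pytest.approx(m1.entropy_rate(), abs=1e-12)
        for lab in labels:
            f1 = fragmentation_metrics([seq_from_letters(letters)], lab)
            f2 = fragmentation_metrics([seq_from_letters(permuted)],
                                       mapping[lab])
            assert (f1.n_bouts, f1.total_duration) == (f2.n_bouts,
                                                       f2.total_duration)
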