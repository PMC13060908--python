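"""Multilayer modularity, the ordinal Louvain optimizer, consensus, and the
switching / allegiance measures."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from netswitch import (
    CommunityAssignment,
    ModularityParams,
    MultilayerNetwork,
    WindowStack,
    allegiance,
    allegiance_matrix,
    consensus_assignment,
    exhaustive_optimum,
    generalized_louvain,
    modularity_Q,
    switching,
)
from conftest import planted_stack, random_stack


def two_cliques_stack():
    a = np.zeros((6, 6, 1))
    for grp in ([0, 1, 2], [3, 4, 5]):
        for i in grp:
            for j in grp:
                if i != j:
                    a[i, j, 0] = 1.0
    return WindowStack(a, 3, 1, list("abcdef"))


def single_layer_modularity_bruteforce(a, gamma=1.0):
    """Independent single-layer oracle: best Newman-Girvan Q over all
    partitions, computed directly from the definition."""
    n = a.shape[0]
    k = a.sum(axis=1)
    two_m = a.sum()

    def q_of(labels):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    total += a[i, j] - gamma * k[i] * k[j] / two_m
        return total / two_m

    best = -np.inf
    for labels in itertools.product(range(n), repeat=n):
        best = max(best, q_of(labels))
    return best


class TestModularityQ:
    def test_two_disjoint_cliques_q_half(self):
        stack = two_cliques_stack()
        net = MultilayerNetwork.from_stack(stack, 0.0)
        params = ModularityParams(gamma=1.0, omega=0.0)
        lab = CommunityAssignment(np.array([[1], [1], [1], [2], [2], [2]]))
        assert modularity_Q(net, lab, params) == pytest.approx(0.5)

    def test_single_community_q_zero(self, rng):
        a = rng.uniform(0, 1, (5, 5, 1))
        a = (a + a.transpose(1, 0, 2)) / 2
        np.fill_diagonal(a[:, :, 0], 0)
        net = MultilayerNetwork(a, 0.0)
        lab = CommunityAssignment(np.ones((5, 1), dtype=int))
        q = modularity_Q(net, lab, ModularityParams(gamma=1.0, omega=0.0))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_optimal_partition_beats_all_others_by_enumeration(self):
        stack = random_stack(4, 2, seed=42)
        params = ModularityParams(gamma=1.0, omega=0.7)
        net = MultilayerNetwork.from_stack(stack, params.omega)
        _, best_q = exhaustive_optimum(stack, params)
        # spot-check: every partition of the 8 supra-nodes scores <= best_q
        r = np.random.default_rng(0)
        for _ in range(200):
            lab = CommunityAssignment(
                canonical(r.integers(1, 4, size=(4, 2)))
            )
            assert modularity_Q(net, lab, params) <= best_q + 1e-12

    def test_zero_strength_layer_handled(self, caplog):
        a = np.zeros((4, 4, 2))
        a[0, 1, 1] = a[1, 0, 1] = 1.0
        net = MultilayerNetwork(a, 0.5)
        lab = CommunityAssignment(np.ones((4, 2), dtype=int))
        with caplog.at_level("WARNING"):
            q = modularity_Q(net, lab, ModularityParams(omega=0.5))
        assert np.isfinite(q)


def canonical(arr):
    from netswitch.community import canonical_labels

    return canonical_labels(arr)


class TestGeneralizedLouvain:
    def test_strong_coupling_gives_layer_constant_assignment(self):
        member = np.array([[1, 1, 1], [1, 1, 1], [2, 2, 2], [2, 2, 2], [2, 2, 2]])
        stack = planted_stack(5, 3, member)
        res = generalized_louvain(stack, ModularityParams(omega=50.0, seed=3))
        assert np.all(res.assignment.labels == res.assignment.labels[:, [0]])

    def test_omega_zero_matches_independent_single_layer_oracle(self):
        stack = random_stack(5, 2, seed=7)
        params = ModularityParams(gamma=1.0, omega=0.0, seed=0)
        res_q = max(
            generalized_louvain(stack, params, seed=s).q for s in range(30)
        )
        # with omega=0, total Q decomposes over layers weighted by 2m_s / 2mu
        per_layer_best = [
            single_layer_modularity_bruteforce(stack.weights[:, :, s])
            for s in range(2)
        ]
        two_m = [stack.weights[:, :, s].sum() for s in range(2)]
        expect = sum(q * m for q, m in zip(per_layer_best, two_m)) / sum(two_m)
        assert res_q == pytest.approx(expect, abs=1e-10)

    def test_planted_flip_recovered(self):
        member = np.array(
            [
                [1, 1, 1], [1, 1, 1], [1, 1, 1],
                [1, 2, 1],  # node 3 flips community in layer 2
                [2, 2, 2], [2, 2, 2], [2, 2, 2], [2, 2, 2],
            ]
        )
        stack = planted_stack(8, 3, member)
        res = generalized_louvain(stack, ModularityParams(omega=0.1, seed=5))
        got = canonical(res.assignment.labels)
        np.testing.assert_array_equal(got, canonical(member))

    def test_q_history_monotone_nondecreasing(self):
        stack = random_stack(6, 3, seed=11)
        res = generalized_louvain(stack, ModularityParams(omega=0.4, seed=2))
        diffs = np.diff(res.q_history)
        assert np.all(diffs >= -1e-12)

    def test_deterministic_given_seed(self):
        stack = random_stack(6, 3, seed=13)
        params = ModularityParams(omega=0.5, seed=9)
        a = generalized_louvain(stack, params)
        b = generalized_louvain(stack, params)
        np.testing.assert_array_equal(a.assignment.labels, b.assignment.labels)
        assert a.q == b.q

    def test_returned_q_equals_modularity_of_assignment(self):
        stack = random_stack(5, 3, seed=17)
        params = ModularityParams(omega=0.8, seed=4)
        res = generalized_louvain(stack, params)
        net = MultilayerNetwork.from_stack(stack, params.omega)
        assert res.q == pytest.approx(modularity_Q(net, res.assignment, params))

    def test_matches_enumeration_on_small_fixture(self):
        stack = random_stack(4, 2, seed=23)
        params = ModularityParams(omega=0.6, seed=0)
        _, q_opt = exhaustive_optimum(stack, params)
        best = max(generalized_louvain(stack, params, seed=s).q for s in range(25))
        assert best == pytest.approx(q_opt, abs=1e-10)


class TestConsensus:
    def test_identical_runs_consensus_is_indicator(self):
        member = np.tile(np.array([1, 1, 2, 2, 2])[:, None], (1, 3))
        stack = planted_stack(5, 3, member)
        params = ModularityParams(omega=1.0, n_runs=5, seed=1)
        assignment = consensus_assignment(stack, params)
        np.testing.assert_array_equal(
            canonical(assignment.labels), canonical(member)
        )

    def test_consensus_values_are_multiples_of_one_over_runs(self):
        # reconstruct the consensus stack the same way and check its grid
        from netswitch.community import generalized_louvain as gl

        stack = random_stack(6, 2, seed=31)
        params = ModularityParams(omega=0.2, n_runs=4, seed=6)
        ss = np.random.SeedSequence(params.seed, spawn_key=(17,))
        seeds = ss.generate_state(params.n_runs + 1) % (2**31)
        co = np.zeros((6, 6, 2))
        for r in range(params.n_runs):
            lab = gl(stack, params, seed=int(seeds[r])).assignment.labels
            for s in range(2):
                co[:, :, s] += lab[:, s][:, None] == lab[:, s][None, :]
        co /= params.n_runs
        grid = np.arange(params.n_runs + 1) / params.n_runs
        assert np.all(np.isin(np.round(co, 12), np.round(grid, 12)))


class TestSwitchingAllegiance:
    def test_hand_counted_switching(self):
        lab = np.array([[1, 1, 2, 2, 1]])
        lab = np.vstack([lab, np.ones((1, 5), dtype=int)])
        prof = switching(CommunityAssignment(canonical(lab)))
        assert prof.per_node[0] == pytest.approx(0.5)
        assert prof.per_node[1] == pytest.approx(0.0)
        assert prof.global_mean == pytest.approx(0.25)

    def test_alternating_labels_switch_every_transition(self):
        lab = np.array([[1, 2, 1, 2], [1, 1, 1, 1]])
        prof = switching(CommunityAssignment(lab))
        assert prof.per_node[0] == 1.0

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            switching(CommunityAssignment(np.ones((3, 1), dtype=int)))

    def test_hand_counted_allegiance(self):
        lab = CommunityAssignment(np.array([[1, 1, 2], [1, 2, 2]]))
        assert allegiance(lab, 0, 1) == pytest.approx(2 / 3)
        assert allegiance(lab, 0, 0) == 1.0

    def test_allegiance_matrix_matches_double_loop(self, rng):
        raw = rng.integers(1, 4, size=(5, 6))
        lab = CommunityAssignment(canonical(raw))
        mat = allegiance_matrix(lab)
        for i in range(5):
            for j in range(5):
                expect = 1.0 if i == j else np.mean(
                    lab.labels[i] == lab.labels[j]
                )
                assert mat[i, j] == pytest.approx(expect)

    def test_equal_allegiance_implies_equal_switching(self, rng):
        raw = canonical(rng.integers(1, 3, size=(4, 5)))
        raw[1] = raw[0]  # force allegiance(0,1) == 1
        lab = CommunityAssignment(canonical(raw))
        prof = switching(lab)
        assert allegiance(lab, 0, 1) == 1.0
        assert prof.per_node[0] == prof.per_node[1]

    @given(st.integers(min_value=0, max_value=10_000))
    def test_label_permutation_invariance(self, perm_seed):
        r = np.random.default_rng(4242)
        raw = canonical(r.integers(1, 4, size=(5, 4)))
        k = raw.max()
        perm = np.random.default_rng(perm_seed).permutation(k) + 1
        permuted = canonical(perm[raw - 1])
        stack = random_stack(5, 4, seed=77)
        params = ModularityParams(omega=0.3)
        net = MultilayerNetwork.from_stack(stack, params.omega)
        q1 = modularity_Q(net, CommunityAssignment(raw), params)
        q2 = modularity_Q(net, CommunityAssignment(permuted), params)
        assert q1 == pytest.approx(q2)
        np.testing.assert_allclose(
            switching(CommunityAssignment(raw)).per_node,
            switching(CommunityAssignment(permuted)).per_node,
        )
        np.testing.assert_allclose(
            allegiance_matrix(CommunityAssignment(raw)),
            allegiance_matrix(CommunityAssignment(permuted)),
        )

    def test_switching_bounds_and_global_mean_identity(self, rng):
        raw = canonical(rng.integers(1, 5, size=(7, 9)))
        prof = switching(CommunityAssignment(raw))
        assert np.all((prof.per_node >= 0) & (prof.per_node <= 1))
        assert prof.global_mean == pytest.approx(prof.per_node.mean())
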