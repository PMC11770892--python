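"""Windows, dynamic FC, multislice modularity (with enumeration oracle),
Louvain, and switching rates."""

import itertools

import numpy as np
import pytest

from brainnetkit.multilayer import (
    LayerStack,
    MultilayerPartition,
    dynamic_fc,
    group_compare_switching,
    louvain_multilayer,
    make_windows,
    multilayer_modularity,
    run_switching_analysis,
    switching_rate,
)
from brainnetkit.synthetic import DynamicBoldSpec, generate_dynamic_bold


class TestWindows:
    def test_study_convention_yields_201_windows(self):
        assert len(make_windows(210, 20, 0.95)) == 201

    def test_single_window(self):
        starts = make_windows(20, 20, 0.95)
        assert starts.tolist() == [0]

    def test_unit_step(self):
        assert len(make_windows(40, 20, 1)) == 21

    def test_window_longer_than_series(self):
        with pytest.raises(ValueError):
            make_windows(10, 20, 1)


class TestDynamicFc:
    def test_duplicated_node_full_weight(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((60, 3))
        x[:, 2] = x[:, 0]
        stack = dynamic_fc(x, make_windows(60, 20, 10), 20)
        assert np.allclose(stack.matrices[:, 0, 2], 1.0)

    def test_layer_count_matches_windows(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((210, 5))
        stack = dynamic_fc(x, make_windows(210, 20, 0.95), 20)
        assert stack.n_layers == 201

    def test_negatives_zeroed_and_nonneg(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((100, 8))
        stack = dynamic_fc(x, make_windows(100, 20, 5), 20)
        assert (stack.matrices >= 0).all()
        assert np.allclose(np.diagonal(stack.matrices, axis1=1, axis2=2), 0)

    def test_white_noise_null_weights_small(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((400, 20))
        stack = dynamic_fc(x, make_windows(400, 20, 20), 20)
        off = ~np.eye(20, dtype=bool)
        assert stack.matrices[:, off].mean() < 0.3

    def test_zero_variance_node_warned_and_zeroed(self):
        x = np.random.default_rng(4).standard_normal((40, 3))
        x[:, 1] = 2.0
        with pytest.warns(UserWarning, match="zero-variance"):
            stack = dynamic_fc(x, make_windows(40, 20, 10), 20)
        assert np.allclose(stack.matrices[:, 1, :], 0)


# ---------------------------------------------------------------------------
# modularity oracle
# ---------------------------------------------------------------------------

def set_partitions(n):
    """All set partitions of n items as restricted-growth strings."""
    def rec(prefix, mx):
        if len(prefix) == n:
            yield list(prefix)
            return
        for v in range(mx + 2):
            yield from rec(prefix + [v], max(mx, v))
    yield from rec([], -1)


def oracle_q(mats, labels, gamma, omega):
    """Direct evaluation of the multislice quality by explicit summation."""
    L, N, _ = mats.shape
    twom = mats.sum(axis=(1, 2))
    two_mu = twom.sum() + 2 * omega * N * (L - 1)
    if two_mu == 0:
        return 0.0
    total = 0.0
    for s in range(L):
        k = mats[s].sum(axis=1)
        for i in range(N):
            for j in range(N):
                if labels[s][i] == labels[s][j]:
                    total += mats[s, i, j]
                    if twom[s] > 0:
                        total -= gamma * k[i] * k[j] / twom[s]
    for s in range(L - 1):
        for i in range(N):
            if labels[s][i] == labels[s + 1][i]:
                total += 2 * omega
    return total / two_mu


class TestModularity:
    def test_two_disjoint_triangles(self):
        mats = np.zeros((1, 6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            mats[0, i, j] = mats[0, j, i] = 1
        lab = np.array([[1, 1, 1, 2, 2, 2]])
        assert np.isclose(multilayer_modularity(LayerStack(mats), lab, 1.0, 0.0), 0.5)

    def test_single_module_null_cancellation(self):
        mats = np.zeros((1, 6, 6))
        for i, j in [(0, 1), (2, 3), (4, 5)]:
            mats[0, i, j] = mats[0, j, i] = 1
        lab = np.ones((1, 6), dtype=int)
        assert np.isclose(multilayer_modularity(LayerStack(mats), lab, 1.0, 0.0), 0.0)

    def test_two_layer_toy_matches_enumeration(self):
        mats = np.zeros((2, 3, 3))
        mats[0, 0, 1] = mats[0, 1, 0] = 1.0
        mats[1, 1, 2] = mats[1, 2, 1] = 1.0
        stack = LayerStack(mats)
        for gamma, omega in itertools.product([0.9, 1.0, 1.1], [0.0, 0.5, 1.0]):
            for part in itertools.islice(set_partitions(6), 0, None, 7):
                lab = np.array(part).reshape(2, 3) + 1
                assert np.isclose(
                    multilayer_modularity(stack, lab, gamma, omega),
                    oracle_q(mats, lab, gamma, omega),
                )


class TestLouvain:
    def test_planted_two_modules_recovered_every_repeat(self):
        rng = np.random.default_rng(0)
        L, N = 10, 12
        modules = np.array([0] * 6 + [1] * 6)
        mats = np.zeros((L, N, N))
        for s in range(L):
            w = 0.9 * (modules[:, None] == modules[None, :]) + 0.05 * rng.random((N, N))
            w = np.triu(w, 1)
            mats[s] = w + w.T
        best, reps = louvain_multilayer(LayerStack(mats), 1.0, 1.0, n_repeats=5, seed=1)
        for p in reps:
            for s in range(L):
                row = p.assignment[s]
                assert len(set(row[:6])) == 1 and len(set(row[6:])) == 1
                assert row[0] != row[6]

    @pytest.mark.parametrize("seed", range(8))
    def test_best_of_repeats_attains_enumeration_optimum(self, seed):
        rng = np.random.default_rng(seed)
        L, N = 2, 3
        mats = np.zeros((L, N, N))
        for s in range(L):
            w = rng.random((N, N)) * (rng.random((N, N)) < 0.7)
            w = np.triu(w, 1)
            mats[s] = w + w.T
        gamma, omega = rng.choice([0.9, 1.0, 1.1]), rng.choice([0.25, 1.0])
        stack = LayerStack(mats)
        q_star = max(
            oracle_q(mats, np.array(p).reshape(L, N) + 1, gamma, omega)
            for p in set_partitions(L * N)
        )
        best, _ = louvain_multilayer(stack, gamma, omega, n_repeats=20, seed=seed)
        assert np.isclose(best.Q, q_star, atol=1e-9)

    def test_returned_q_self_consistent(self):
        rng = np.random.default_rng(5)
        mats = np.abs(rng.random((4, 8, 8)))
        mats = (mats + np.transpose(mats, (0, 2, 1))) / 2
        for s in range(4):
            np.fill_diagonal(mats[s], 0)
        stack = LayerStack(mats)
        best, _ = louvain_multilayer(stack, 1.0, 0.5, n_repeats=3, seed=2)
        assert best.Q == multilayer_modularity(stack, best.assignment, 1.0, 0.5)

    def test_seeded_repeat_sequence_identical(self):
        rng = np.random.default_rng(6)
        mats = np.abs(rng.random((3, 6, 6)))
        mats = (mats + np.transpose(mats, (0, 2, 1))) / 2
        for s in range(3):
            np.fill_diagonal(mats[s], 0)
        stack = LayerStack(mats)
        _, r1 = louvain_multilayer(stack, 1.0, 1.0, n_repeats=4, seed=9)
        _, r2 = louvain_multilayer(stack, 1.0, 1.0, n_repeats=4, seed=9)
        assert [p.Q for p in r1] == [p.Q for p in r2]
        for a, b in zip(r1, r2):
            assert np.array_equal(a.assignment, b.assignment)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            louvain_multilayer(LayerStack(np.zeros((0, 3, 3))), 1.0, 1.0)


class TestSwitchingRate:
    def test_constant_assignment_zero(self):
        p = MultilayerPartition(np.ones((5, 4), dtype=int), 0.0, 1.0, 1.0)
        assert np.allclose(switching_rate(p), 0.0)

    def test_alternating_node_full_rate(self):
        g = np.ones((4, 2), dtype=int)
        g[:, 0] = [1, 2, 1, 2]
        p = MultilayerPartition(g, 0.0, 1.0, 1.0)
        assert switching_rate(p)[0] == 1.0

    def test_half_rate(self):
        g = np.array([[1], [1], [2]])
        assert switching_rate(MultilayerPartition(g, 0.0, 1.0, 1.0))[0] == 0.5

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            switching_rate(MultilayerPartition(np.ones((1, 3), dtype=int), 0.0, 1.0, 1.0))

    def test_invariant_under_module_relabeling(self):
        rng = np.random.default_rng(0)
        g = rng.integers(1, 4, size=(6, 5))
        p1 = MultilayerPartition(g, 0.0, 1.0, 1.0)
        perm = np.array([0, 3, 1, 2])  # relabel 1->3, 2->1, 3->2
        p2 = MultilayerPartition(perm[g], 0.0, 1.0, 1.0)
        assert np.allclose(switching_rate(p1), switching_rate(p2))


class TestSwitchingAnalysis:
    def test_settings_grid_shape(self):
        spec = DynamicBoldSpec(n_subjects=2, n_regions=12, n_volumes=60,
                               n_modules=2, seed=0)
        subs, _ = generate_dynamic_bold(spec)
        res = run_switching_analysis([d.to_numpy() for d in subs],
                                     omegas=(0.5, 1.0), gammas=(0.9, 1.1),
                                     window_length=20, step=5, n_repeats=2, seed=0)
        assert res["rates"].shape == (2, 4, 12)
        assert res["q"].shape == (2, 4)
        assert len(res["settings"]) == 4

    def test_deterministic_under_seed(self):
        spec = DynamicBoldSpec(n_subjects=1, n_regions=10, n_volumes=60,
                               n_modules=2, seed=1)
        subs, _ = generate_dynamic_bold(spec)
        x = [d.to_numpy() for d in subs]
        r1 = run_switching_analysis(x, omegas=(1.0,), gammas=(1.0,),
                                    window_length=20, step=10, n_repeats=2, seed=5)
        r2 = run_switching_analysis(x, omegas=(1.0,), gammas=(1.0,),
                                    window_length=20, step=10, n_repeats=2, seed=5)
        assert np.array_equal(r1["rates"], r2["rates"])
        assert np.array_equal(r1["q"], r2["q"])

    def test_higher_omega_does_not_increase_switching(self):
        spec = DynamicBoldSpec(n_subjects=1, n_regions=30, n_volumes=120,
                               n_modules=3, switch_nodes=(0, 10),
                               switch_epochs=(40, 80), seed=2)
        subs, _ = generate_dynamic_bold(spec)
        x = [subs[0].to_numpy()]
        res = run_switching_analysis(x, omegas=(0.5, 1.0), gammas=(1.0,),
                                     window_length=20, step=1.0,
                                     n_repeats=8, seed=3)
        low, high = res["rates"][0, 0].mean(), res["rates"][0, 1].mean()
        assert high <= low + 0.02  # monotone up to repeat noise


class TestGroupCompare:
    def test_swapped_groups_negate_t_same_fdr_set(self):
        rng = np.random.default_rng(0)
        r1 = rng.uniform(0.0, 0.2, size=(10, 8))
        r2 = rng.uniform(0.1, 0.3, size=(12, 8))
        a = group_compare_switching(r1, r2)
        b = group_compare_switching(r2, r1)
        assert np.allclose(a["t"], -b["t"])
        assert np.array_equal(a["significant"], b["significant"])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            group_compare_switching(np.zeros((1, 5)), np.zeros((4, 5)))
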