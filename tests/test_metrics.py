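"""Signed modularity, Louvain maximization, and nodal cartography."""

import itertools

import numpy as np
import pytest
import networkx as nx
from hypothesis import given, settings, strategies as st

from netfluct.errors import InvalidInputError
from netfluct.metrics import (Partition, maximize_modularity,
                              participation_coefficient, signed_modularity,
                              within_module_zscore)


def all_partitions(n):
    """Every set partition of n labeled nodes (restricted growth strings)."""
    def rec(prefix, m):
        if len(prefix) == n:
            yield np.array(prefix)
            return
        for v in range(m + 1):
            yield from rec(prefix + [v], max(m, v + 1))
    yield from rec([], 0)


def _sym(w):
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    return w


class TestSignedModularity:
    def test_all_positive_matches_newman_girvan(self, rng):
        # with no negative weights the second term vanishes and Q equals
        # the standard quality function (networkx as the textbook oracle)
        w = np.abs(_sym(rng.uniform(0, 1, (8, 8))))
        w[w < 0.4] = 0.0
        g = nx.from_numpy_array(w)
        part = np.array([0, 0, 0, 1, 1, 1, 2, 2])
        communities = [{i for i in range(8) if part[i] == c}
                       for c in range(3)]
        expected = nx.community.modularity(g, communities, weight="weight")
        assert signed_modularity(w, part) == pytest.approx(expected, abs=1e-12)

    def test_four_node_toy_exhaustive_maximum(self):
        # two positive dyads bridged by a negative edge
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        w[1, 2] = w[2, 1] = -0.5
        best_q, best_p = max(
            ((signed_modularity(w, p), p) for p in all_partitions(4)),
            key=lambda t: t[0])
        q, part = maximize_modularity(w, n_restarts=20, seed=0)
        assert q == pytest.approx(best_q, abs=1e-12)
        # the maximizing partition separates the dyads across the bridge
        a = part.assignment
        assert a[0] == a[1] and a[2] == a[3] and a[1] != a[2]

    def test_negative_bridge_prefers_split(self):
        # two positive cliques joined only by negative edges: splitting
        # scores higher than the single-module partition
        w = np.zeros((6, 6))
        for i, j in itertools.combinations(range(3), 2):
            w[i, j] = w[j, i] = 1.0
            w[i + 3, j + 3] = w[j + 3, i + 3] = 1.0
        w[2, 3] = w[3, 2] = -1.0
        split = np.array([0, 0, 0, 1, 1, 1])
        lumped = np.zeros(6, dtype=int)
        assert signed_modularity(w, split) > signed_modularity(w, lumped)

    def test_relabeling_invariance(self, rng):
        w = _sym(rng.standard_normal((7, 7)))
        p = np.array([0, 1, 1, 2, 0, 2, 1])
        relabeled = np.array([5, 3, 3, 9, 5, 9, 3])
        assert signed_modularity(w, p) == pytest.approx(
            signed_modularity(w, relabeled), abs=1e-14)

    def test_no_positive_weights_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -1.0
        with pytest.raises(InvalidInputError):
            signed_modularity(w, np.zeros(3, dtype=int))


class TestMaximizeModularity:
    def test_disconnected_cliques_found_exactly(self):
        w = np.zeros((6, 6))
        for i, j in itertools.combinations(range(3), 2):
            w[i, j] = w[j, i] = 1.0
            w[i + 3, j + 3] = w[j + 3, i + 3] = 1.0
        q, part = maximize_modularity(w, n_restarts=10, seed=1)
        a = part.assignment
        assert len(set(a[:3])) == 1 and len(set(a[3:])) == 1
        assert a[0] != a[3]
        assert q == pytest.approx(signed_modularity(w, a), abs=1e-14)

    def test_matches_exhaustive_maximum_on_small_graphs(self, rng):
        hits = 0
        trials = 30
        for t in range(trials):
            n = int(rng.integers(5, 8))
            w = _sym(rng.standard_normal((n, n)))
            w[np.abs(w) < 0.3] = 0.0
            if not (w > 0).any():
                continue
            best = max(signed_modularity(w, p) for p in all_partitions(n))
            q, _ = maximize_modularity(w, n_restarts=20, seed=t)
            hits += abs(q - best) < 1e-12
        assert hits / trials >= 0.95

    def test_deterministic_under_seed(self, rng):
        w = _sym(rng.standard_normal((12, 12)))
        q1, p1 = maximize_modularity(w, n_restarts=10, seed=5)
        q2, p2 = maximize_modularity(w, n_restarts=10, seed=5)
        assert q1 == q2
        assert np.array_equal(p1.assignment, p2.assignment)

    def test_never_below_trivial_partitions(self, rng):
        for t in range(10):
            w = _sym(np.random.default_rng(t).standard_normal((9, 9)))
            if not (w > 0).any():
                continue
            q, _ = maximize_modularity(w, n_restarts=1, seed=t)
            singletons = np.arange(9)
            lumped = np.zeros(9, dtype=int)
            assert q >= signed_modularity(w, singletons) - 1e-12
            assert q >= signed_modularity(w, lumped) - 1e-12

    def test_partition_labels_contiguous_from_one(self, rng):
        w = _sym(np.abs(rng.standard_normal((10, 10))))
        _, part = maximize_modularity(w, n_restarts=5, seed=2)
        labels = np.unique(part.assignment)
        assert labels[0] == 1
        assert np.array_equal(labels, np.arange(1, len(labels) + 1))


class TestWithinModuleZscore:
    def test_equal_degrees_give_zero(self):
        w = np.zeros((4, 4))
        for i, j in itertools.combinations(range(4), 2):
            w[i, j] = w[j, i] = 1.0
        z = within_module_zscore(w, np.zeros(4, dtype=int))
        assert np.allclose(z, 0.0)

    def test_per_module_standardization(self, rng):
        w = _sym(np.abs(rng.standard_normal((10, 10))))
        p = np.array([0] * 5 + [1] * 5)
        z = within_module_zscore(w, p)
        for m in (0, 1):
            sel = p == m
            assert z[sel].mean() == pytest.approx(0.0, abs=1e-9)
            assert z[sel].std() == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_oracle_on_weighted_toy(self):
        w = np.zeros((5, 5))
        edges = [(0, 1, 2.0), (0, 2, 1.0), (1, 2, 3.0), (3, 4, 1.5),
                 (2, 3, -0.5)]
        for i, j, v in edges:
            w[i, j] = w[j, i] = v
        p = np.array([0, 0, 0, 1, 1])
        z = within_module_zscore(w, p)
        kappa = np.array([w[0, 1] + w[0, 2], w[1, 0] + w[1, 2],
                          w[2, 0] + w[2, 1]])
        expected = (kappa - kappa.mean()) / kappa.std()
        assert np.allclose(z[:3], expected, atol=1e-12)
        # module {3, 4}: both nodes have equal within-module degree
        assert np.allclose(z[3:], 0.0)

    def test_singleton_module_gets_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        z = within_module_zscore(w, np.array([0, 0, 1]))
        assert z[2] == 0.0


class TestParticipationCoefficient:
    def test_all_weight_in_own_module_gives_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 2.0
        p = participation_coefficient(w, np.array([0, 0, 1, 1]))
        assert p[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_equal_split_closed_form(self, m):
        # hub node 0 connects with equal positive weight to one node of
        # each of m modules -> P = 1 - 1/m
        n = m + 1
        w = np.zeros((n, n))
        for j in range(1, n):
            w[0, j] = w[j, 0] = 1.0
        part = np.array([0] + list(range(1, n)))
        # node 0 belongs to module 0 = module of first neighbor? use
        # separate module for the hub: splits are across m modules
        p = participation_coefficient(w, part)
        assert p[0] == pytest.approx(1.0 - 1.0 / m)

    def test_matches_bruteforce_oracle(self, rng):
        w = _sym(rng.standard_normal((8, 8)))
        part = np.array([0, 0, 1, 1, 2, 2, 2, 1])
        p = participation_coefficient(w, part)
        wp = np.where(w > 0, w, 0.0)
        for i in range(8):
            total = wp[i].sum()
            if total == 0:
                assert p[i] == 0.0
                continue
            acc = sum((wp[i, part == m].sum() / total) ** 2
                      for m in np.unique(part))
            assert p[i] == pytest.approx(1 - acc, abs=1e-12)

    def test_zero_positive_strength_gives_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -1.0
        w[1, 2] = w[2, 1] = 1.0
        p = participation_coefficient(w, np.array([0, 1, 2]))
        assert p[0] == 0.0

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=30, deadline=None)
    def test_bounded_by_module_count(self, seed):
        rng = np.random.default_rng(seed)
        w = _sym(rng.standard_normal((10, 10)))
        part = rng.integers(0, 3, 10)
        part[:3] = [0, 1, 2]             # ensure all three modules occur
        p = participation_coefficient(w, part)
        assert np.all(p >= 0.0)
        assert np.all(p <= 1.0 - 1.0 / 3 + 1e-12)
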