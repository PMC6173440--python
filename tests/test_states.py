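"""Network-state estimation, transitions, centroids, and contrasts."""

import numpy as np
import pytest

from netfluct.connectome import StructuralConnectome
from netfluct.errors import InsufficientDataError, InvalidInputError
from netfluct.fc import TimeResolvedFC, WindowSpec
from netfluct.metrics import CartographyProfile, Partition
from netfluct.states import (HIST_BINS, StateSequence, between_state_contrast,
                             estimate_seg_int_states, global_absolute_fc,
                             joint_histogram, modularity_period_labels,
                             sc_fc_similarity, state_centroids,
                             transition_stats)


def _profile(z, p):
    w, n = z.shape
    return CartographyProfile(modularity=np.zeros(w), zscores=z,
                              participation=p,
                              partitions=[Partition(np.zeros(n, int))] * w)


def _trfc(mats, step=3):
    spec = WindowSpec(rect_width_trs=9, gauss_sigma_trs=0.0, step_trs=step,
                      kernel_halfwidth_trs=0)
    centers = np.arange(len(mats)) * step + 4.0
    return TimeResolvedFC(matrices=np.asarray(mats, dtype=float),
                          window_centers_trs=centers, spec=spec)


class TestJointHistogram:
    def test_single_bin_holds_all_nodes(self):
        z = np.full((2, 30), 0.77)
        p = np.full((2, 30), 0.31)
        h = joint_histogram(_profile(z, p))
        assert h.shape == (2, 100, 100)
        for t in range(2):
            assert h[t].max() == 30

    def test_counts_sum_to_n_with_outliers_clipped(self, rng):
        z = rng.normal(0, 4, (3, 50))       # some values beyond +-5
        p = rng.uniform(-0.2, 1.2, (3, 50))  # some values outside (0, 1)
        h = joint_histogram(_profile(z, p))
        assert np.all(h.sum(axis=(1, 2)) == 50)

    def test_bin_index_matches_floor_oracle(self):
        z = np.array([[0.0]])
        p = np.array([[0.5]])
        h = joint_histogram(_profile(z, p))
        zi = int(np.floor((0.0 - (-5.0)) / 10.0 * HIST_BINS))
        pi = int(np.floor(0.5 * HIST_BINS))
        assert h[0, zi, pi] == 1


class TestSegIntEstimation:
    def test_separable_groups_recovered_with_correct_labels(self, rng):
        # low-P windows vs high-P windows, well separated histograms
        w, n = 40, 60
        z = rng.normal(0, 1, (w, n))
        p = np.empty((w, n))
        truth = np.array([0] * 20 + [1] * 20)
        p[truth == 0] = rng.uniform(0.02, 0.10, (20, n))
        p[truth == 1] = rng.uniform(0.60, 0.68, (20, n))
        prof = _profile(z, p)
        h = joint_histogram(prof)
        seq = estimate_seg_int_states(h, prof.participation, n_restarts=20,
                                      seed=0)
        pred = (seq.labels == "integrated").astype(int)
        assert np.array_equal(pred, truth)

    def test_deterministic_under_seed(self, rng):
        w, n = 20, 30
        z = rng.normal(0, 1, (w, n))
        p = rng.uniform(0, 1, (w, n))
        prof = _profile(z, p)
        h = joint_histogram(prof)
        a = estimate_seg_int_states(h, prof.participation, n_restarts=10, seed=3)
        b = estimate_seg_int_states(h, prof.participation, n_restarts=10, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_identical_windows_flagged_degenerate(self):
        z = np.zeros((5, 10))
        p = np.full((5, 10), 0.4)
        prof = _profile(z, p)
        h = joint_histogram(prof)
        with pytest.warns(RuntimeWarning):
            seq = estimate_seg_int_states(h, prof.participation, n_restarts=5,
                                          seed=0)
        assert seq.degenerate


class TestModularityPeriods:
    def test_nine_distinct_values_split_evenly(self):
        seq = modularity_period_labels(np.array([1, 2, 3, 4, 5, 6, 7, 8, 9.0]))
        counts = {s: (seq.labels == s).sum() for s in ("high", "middle", "low")}
        assert counts == {"high": 3, "middle": 3, "low": 3}

    def test_high_strictly_exceeds_others(self, rng):
        q = rng.standard_normal(60)
        seq = modularity_period_labels(q)
        hi = q[seq.labels == "high"]
        rest = q[seq.labels != "high"]
        assert hi.min() > rest.max()

    def test_boundary_ties_fall_into_middle(self):
        q = np.array([1.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 3.0, 4.0])
        seq = modularity_period_labels(q)
        # tercile boundaries land on the tied value 2.0; the strict
        # inequalities send every tied window to "middle"
        assert list(seq.labels[1:7]) == ["middle"] * 6

    def test_invariant_to_monotone_transform(self, rng):
        q = rng.uniform(0.1, 0.9, 45)
        a = modularity_period_labels(q)
        b = modularity_period_labels(np.exp(5 * q))
        assert np.array_equal(a.labels, b.labels)


class TestTransitionStats:
    def test_constant_sequence(self):
        seq = StateSequence(labels=np.array(["a"] * 12), step_seconds=2.16)
        summ = transition_stats(seq)
        assert summ.transition_matrix[0, 0] == 1.0
        assert summ.mean_dwell_windows["a"] == 12
        assert summ.mean_dwell_seconds["a"] == pytest.approx(12 * 2.16)

    def test_alternating_sequence(self):
        seq = StateSequence(labels=np.array(["a", "b"] * 6), step_seconds=2.16)
        summ = transition_stats(seq)
        i, j = summ.states.index("a"), summ.states.index("b")
        assert summ.transition_matrix[i, j] == 1.0
        assert summ.transition_matrix[j, i] == 1.0
        assert summ.mean_dwell_windows["a"] == 1.0
        assert summ.mean_dwell_seconds["a"] == pytest.approx(2.16)

    def test_hand_counted_sequence(self):
        seq = StateSequence(labels=np.array(list("aabbba")), step_seconds=2.16)
        summ = transition_stats(seq)
        i, j = summ.states.index("a"), summ.states.index("b")
        m = summ.transition_matrix
        assert m[i, i] == pytest.approx(0.5)
        assert m[i, j] == pytest.approx(0.5)
        assert m[j, j] == pytest.approx(2 / 3)
        assert m[j, i] == pytest.approx(1 / 3)
        assert summ.mean_dwell_windows["a"] == pytest.approx(1.5)
        assert summ.mean_dwell_windows["b"] == pytest.approx(3.0)

    def test_rows_stochastic_and_occupancy_sums_to_one(self, rng):
        labels = rng.choice(["x", "y", "z"], size=100)
        summ = transition_stats(StateSequence(labels=labels))
        assert np.allclose(summ.transition_matrix.sum(axis=1), 1.0, atol=1e-9)
        assert sum(summ.occupancy.values()) == pytest.approx(1.0)

    def test_unobserved_state_is_nan(self):
        seq = StateSequence(labels=np.array(["a", "a", "a"]))
        summ = transition_stats(seq, states=["a", "b"])
        assert np.isnan(summ.transition_matrix[1]).all()
        assert np.isnan(summ.mean_dwell_windows["b"])


class TestCentroids:
    def test_single_window_state_equals_that_window(self, rng):
        mats = rng.standard_normal((3, 4, 4))
        mats = (mats + np.transpose(mats, (0, 2, 1))) / 2
        trfc = _trfc(mats)
        seq = StateSequence(labels=np.array(["a", "b", "b"]))
        cents = state_centroids(trfc, seq)
        assert np.allclose(cents["a"].values, mats[0])

    def test_median_of_three(self):
        mats = np.zeros((3, 2, 2))
        mats[:, 0, 1] = mats[:, 1, 0] = [1.0, 2.0, 10.0]
        seq = StateSequence(labels=np.array(["s"] * 3))
        cents = state_centroids(_trfc(mats), seq)
        assert cents["s"].values[0, 1] == 2.0

    def test_matches_sort_based_median_oracle(self, rng):
        mats = rng.standard_normal((9, 5, 5))
        seq = StateSequence(labels=np.array(["a"] * 5 + ["b"] * 4))
        cents = state_centroids(_trfc(mats), seq)
        sel = mats[5:]
        expected = np.sort(sel, axis=0)[len(sel) // 2] if len(sel) % 2 else \
            np.sort(sel, axis=0)[1:3].mean(axis=0)
        assert np.allclose(cents["b"].values, expected)


class TestContrast:
    def _labels(self):
        return np.array(["CON"] * 4 + ["DMN"] * 4 + ["VIS"] * 4)

    def test_identical_states_nothing_significant(self, rng):
        cents = [rng.standard_normal((12, 12)) for _ in range(6)]
        cents = [(c + c.T) / 2 for c in cents]
        res = between_state_contrast(cents, cents, self._labels())
        assert not res.significant.any()

    def test_planted_shift_detected_with_sign(self, rng):
        labels = self._labels()
        first, second = [], []
        for _ in range(10):
            base = rng.standard_normal((12, 12)) * 0.1
            base = (base + base.T) / 2
            shifted = base.copy()
            # +delta within the CON block only, in the first state
            shifted[:4, :4] += 1.0
            np.fill_diagonal(shifted, 0.0)
            np.fill_diagonal(base, 0.0)
            first.append(shifted)
            second.append(base)
        res = between_state_contrast(first, second, labels)
        i = res.systems.index("CON")
        assert res.significant[i, i]
        assert res.t_scores[i, i] > 0          # larger in first-named state
        off = res.significant.copy()
        off[i, i] = False
        assert not off.any()

    def test_too_few_samples_rejected(self, rng):
        c = [(lambda m: (m + m.T) / 2)(rng.standard_normal((12, 12)))
             for _ in range(2)]
        with pytest.raises(InsufficientDataError):
            between_state_contrast(c, c, self._labels())


class TestScFcSimilarity:
    def _sc(self, rng, n=24):
        w = np.abs(rng.standard_normal((n, n)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        w[w < 0.8] = 0.0
        return StructuralConnectome(weights=w, lengths=np.where(w > 0, 10.0, 0))

    def test_identical_weights_give_one(self, rng):
        sc = self._sc(rng)
        assert sc_fc_similarity(sc, sc.weights.copy()) == pytest.approx(1.0)

    def test_negated_weights_give_minus_one(self, rng):
        sc = self._sc(rng)
        assert sc_fc_similarity(sc, -sc.weights) == pytest.approx(-1.0)

    def test_independent_fc_uncorrelated(self):
        hits = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            sc = self._sc(rng, n=32)
            n_edges = (np.triu(sc.weights, 1) > 0).sum()
            assert n_edges >= 100
            fc = rng.standard_normal((32, 32))
            fc = (fc + fc.T) / 2
            hits += abs(sc_fc_similarity(sc, fc)) < 0.2
        assert hits >= 36      # |corr| < 0.2 with probability >= 0.9


class TestGlobalAbsoluteFC:
    def test_constant_edges(self):
        mats = np.full((4, 3, 3), 0.3)
        for m in mats:
            np.fill_diagonal(m, 0.0)
        seq = StateSequence(labels=np.array(["s"] * 4))
        out = global_absolute_fc(_trfc(mats), seq)
        assert out["s"] == pytest.approx(0.3)

    def test_sign_flip_invariant_and_matches_hand_computation(self):
        mats = np.zeros((2, 3, 3))
        vals = [(0, 1, 0.5), (0, 2, -0.25), (1, 2, 0.75)]
        for i, j, v in vals:
            mats[:, i, j] = mats[:, j, i] = v
        seq = StateSequence(labels=np.array(["s", "s"]))
        out = global_absolute_fc(_trfc(mats), seq)
        assert out["s"] == pytest.approx((0.5 + 0.25 + 0.75) / 3)
        out_neg = global_absolute_fc(_trfc(-mats), seq)
        assert out_neg["s"] == pytest.approx(out["s"])
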