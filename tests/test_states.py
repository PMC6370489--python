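import numpy as np
import pytest

import braindyn as bd
from braindyn.errors import DegenerateInputError, InvalidArgumentError
from braindyn.states import StateModel, WindowedFCStack


class TestSlidingWindowFC:
    def test_window_count(self):
        rng = np.random.default_rng(0)
        stack = bd.sliding_window_fc(rng.normal(size=(4, 70)), window_trs=60)
        assert stack.windows.shape[0] == 11

    def test_clipped_perfect_correlation(self):
        base = np.sin(np.arange(80.0))
        x = np.vstack([base, base, np.random.default_rng(0).normal(size=80)])
        stack = bd.sliding_window_fc(x, window_trs=60)
        # entry (0,1) is first in the upper-triangle vectorization
        assert np.allclose(stack.windows[:, 0], np.arctanh(1 - 1e-6))

    def test_first_row_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(4, 80))
        stack = bd.sliding_window_fc(x, window_trs=60)
        seg = x[:, :60]
        iu = np.triu_indices(4, k=1)
        expected = np.arctanh(np.clip(np.corrcoef(seg)[iu], -(1 - 1e-6), 1 - 1e-6))
        assert np.allclose(stack.windows[0], expected, atol=1e-12)

    def test_constant_roi_in_window_names_window(self):
        x = np.random.default_rng(0).normal(size=(3, 70))
        x[1, :65] = 5.0
        with pytest.raises(DegenerateInputError, match="0"):
            bd.sliding_window_fc(x, window_trs=60)


def make_stack(windows, run_ids=None, tr=0.72):
    windows = np.asarray(windows, dtype=float)
    if run_ids is None:
        run_ids = np.zeros(len(windows), dtype=int)
    return WindowedFCStack(windows=windows, window_trs=60,
                           run_ids=np.asarray(run_ids), n_rois=4, tr=tr)


class TestClusterStates:
    def test_planted_blobs_recovered_exactly(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0, 0], [10, 0], [0, 10]], dtype=float)
        labels_true = np.repeat([0, 1, 2], 40)
        X = centers[labels_true] + rng.normal(scale=0.3, size=(120, 2))
        model = bd.cluster_states(make_stack(X), k=3, replicates=10, seed=0)
        # agreement up to permutation must be perfect
        for true_lab in range(3):
            got = model.labels[labels_true == true_lab]
            assert len(np.unique(got)) == 1
        assert len(np.unique(model.labels)) == 3

    def test_single_cluster_centroid_is_median(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        model = bd.cluster_states(make_stack(X), k=1, replicates=3, seed=0)
        assert np.allclose(model.centroids[0], np.median(X, axis=0))

    def test_duplicating_rows_keeps_centroids(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(size=(20, 3)), rng.normal(5, 1, size=(20, 3))])
        a = bd.cluster_states(make_stack(X), k=2, replicates=10, seed=1)
        b = bd.cluster_states(make_stack(np.vstack([X, X])), k=2, replicates=10, seed=1)
        order_a = np.argsort(a.centroids[:, 0])
        order_b = np.argsort(b.centroids[:, 0])
        assert np.allclose(a.centroids[order_a], b.centroids[order_b], atol=1e-9)

    def test_inertia_is_l1_distance_sum(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 3))
        model = bd.cluster_states(make_stack(X), k=2, replicates=5, seed=0)
        manual = sum(
            np.abs(X[i] - model.centroids[model.labels[i]]).sum()
            for i in range(len(X))
        )
        assert model.inertia == pytest.approx(manual)

    def test_k_larger_than_data_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bd.cluster_states(make_stack(np.zeros((3, 2))), k=5)


class TestStateStats:
    def _model(self, labels, k=3, d=2):
        centroids = np.zeros((k, d))
        centroids[:, 0] = np.arange(k, dtype=float)
        return StateModel(centroids=centroids, labels=np.asarray(labels),
                          k=k, inertia=0.0)

    def test_hand_counted_dwell(self):
        labels = [0, 0, 0, 1, 1]
        stats = bd.per_run_state_stats(self._model(labels),
                                       make_stack(np.zeros((5, 2))))
        assert stats.states_per_run[0] == 2
        assert stats.mean_dwell_s[0] == pytest.approx(2.5 * 0.72)

    def test_single_state_distance_is_missing(self):
        stats = bd.per_run_state_stats(self._model([1, 1, 1, 1]),
                                       make_stack(np.zeros((4, 2))))
        assert np.isnan(stats.centroid_distances[0])

    def test_axis_aligned_centroid_distance(self):
        model = StateModel(centroids=np.array([[1.0, 0.0], [3.0, 0.0]]),
                           labels=np.array([0, 0, 1, 1]), k=2, inertia=0.0)
        stats = bd.per_run_state_stats(model, make_stack(np.zeros((4, 2))))
        assert stats.centroid_distances[0] == pytest.approx(2.0)


class TestTransitions:
    def test_hand_enumerated_probabilities(self):
        model = self_model = StateModel(centroids=np.zeros((3, 2)),
                                        labels=np.array([0, 1, 1, 2, 0, 0]),
                                        k=3, inertia=0.0)
        trans, sparsity = bd.transition_analysis(model, make_stack(np.zeros((6, 2))))
        assert trans[0, 1] == pytest.approx(1 / 3)
        assert trans[1, 2] == pytest.approx(1 / 3)
        assert trans[2, 0] == pytest.approx(1 / 3)
        assert trans.sum() == pytest.approx(1.0)
        assert np.all(np.diag(trans) == 0)
        assert sparsity == pytest.approx(0.5)

    def test_constant_labels_give_zero_matrix(self):
        model = StateModel(centroids=np.zeros((3, 2)),
                           labels=np.zeros(5, dtype=int), k=3, inertia=0.0)
        trans, sparsity = bd.transition_analysis(model, make_stack(np.zeros((5, 2))))
        assert np.all(trans == 0)
        assert sparsity == 0.0

    def test_runs_do_not_leak_transitions(self):
        # last window of run 0 -> first of run 1 must not count
        model = StateModel(centroids=np.zeros((2, 2)),
                           labels=np.array([0, 0, 1, 1]), k=2, inertia=0.0)
        stack = make_stack(np.zeros((4, 2)), run_ids=[0, 0, 1, 1])
        trans, _ = bd.transition_analysis(model, stack)
        assert np.all(trans == 0)
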