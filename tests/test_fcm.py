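import numpy as np
import pytest

from adstage import (
    fcm_fit,
    fcm_predict,
    map_clusters_to_classes,
    membership_rows,
)
from adstage.fcm import ClusterModel, _memberships_from_centers


def reference_fcm(X, k, m, max_iter, tol, init_M):
    """Independently coded loop-based FCM oracle (same init protocol)."""
    X = np.asarray(X, float)
    n, d = X.shape
    M = init_M.copy()
    for _ in range(max_iter):
        centers = np.zeros((k, d))
        for j in range(k):
            w = M[:, j] ** m
            centers[j] = (w[:, None] * X).sum(axis=0) / max(w.sum(), 1e-12)
        M_new = np.zeros_like(M)
        for i in range(n):
            dists = np.array(
                [max(np.linalg.norm(X[i] - centers[j]), 1e-12) for j in range(k)]
            )
            if np.any(np.linalg.norm(X[i] - centers, axis=1) <= 1e-12):
                jz = int(np.argmax(np.linalg.norm(X[i] - centers, axis=1) <= 1e-12))
                M_new[i, jz] = 1.0
                continue
            for j in range(k):
                M_new[i, j] = 1.0 / np.sum((dists[j] / dists) ** (2.0 / (m - 1.0)))
        delta = np.abs(M_new - M).max()
        M = M_new
        if delta < tol:
            break
    return centers, M


def objective(X, centers, M, m):
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float((M**m * d2).sum())


class TestFit:
    def test_k1_unit_memberships_and_mean_center(self, rng):
        X = rng.random((10, 3))
        model, M = fcm_fit(X, k=1, seed=0)
        assert np.all(M == 1.0)
        np.testing.assert_allclose(model.centers[0], X.mean(axis=0), atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        X = rng.random((30, 4))
        _, M = fcm_fit(X, k=3, seed=1)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-9)
        assert M.min() >= 0.0 and M.max() <= 1.0

    def test_equidistant_point_gets_half_membership(self):
        centers = np.array([[0.0, 0.0], [2.0, 0.0]])
        M = _memberships_from_centers(np.array([[1.0, 0.0]]), centers, 2.0)
        np.testing.assert_allclose(M[0], [0.5, 0.5], atol=1e-12)

    def test_blob_center_recovery_and_reference_agreement(self):
        rng = np.random.default_rng(42)
        true = np.array([[0.0, 0.0], [10.0, 10.0]])
        X = np.vstack(
            [rng.normal(c, 0.5, size=(20, 2)) for c in true]
        )
        init = rng.random((40, 2))
        init /= init.sum(axis=1, keepdims=True)
        model, M = fcm_fit(X, k=2, max_iter=100, tol=1e-7, init_M=init)
        ref_c, ref_M = reference_fcm(X, 2, 2.0, 100, 1e-7, init)
        np.testing.assert_allclose(model.centers, ref_c, atol=1e-6)
        np.testing.assert_allclose(M, ref_M, atol=1e-6)
        err = min(
            np.abs(model.centers - true).max(),
            np.abs(model.centers[::-1] - true).max(),
        )
        assert err < 0.3

    def test_reference_agreement_on_random_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n, d, k = 12, 2, rng.integers(2, 4)
            X = rng.random((n, d)) * 4
            init = rng.random((n, k))
            init /= init.sum(axis=1, keepdims=True)
            model, M = fcm_fit(X, k=int(k), max_iter=40, tol=1e-9, init_M=init)
            ref_c, ref_M = reference_fcm(X, int(k), 2.0, 40, 1e-9, init)
            np.testing.assert_allclose(M, ref_M, atol=1e-6,
                                       err_msg=f"trial {trial}")
            np.testing.assert_allclose(model.centers, ref_c, atol=1e-6)

    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(3)
        X = rng.random((25, 3))
        init = rng.random((25, 3))
        init /= init.sum(axis=1, keepdims=True)
        M = init
        prev = np.inf
        for _ in range(15):
            model, M = fcm_fit(X, k=3, max_iter=1, tol=0.0, init_M=M)
            val = objective(X, model.centers, M, 2.0)
            assert val <= prev + 1e-9
            prev = val

    def test_invalid_inputs_rejected(self, rng):
        X = rng.random((5, 2))
        with pytest.raises(ValueError):
            fcm_fit(X, k=6)
        with pytest.raises(ValueError):
            fcm_fit(np.empty((0, 2)), k=1)
        with pytest.raises(ValueError):
            fcm_fit(X, k=2, m_exp=1.0)


class TestPredict:
    def _model(self):
        centers = np.array([[0.0, 0.0], [4.0, 4.0]])
        return ClusterModel(centers=centers,
                            cluster_to_class={0: "NAD", 1: "AD"})

    def test_center_hit_gives_hard_membership(self):
        row, label = fcm_predict(self._model(), np.array([4.0, 4.0]))
        np.testing.assert_allclose(row, [0.0, 1.0])
        assert label == "AD"

    def test_k1_always_same_class(self, rng):
        model = ClusterModel(centers=np.zeros((1, 2)),
                             cluster_to_class={0: "AD"})
        for _ in range(5):
            _, label = fcm_predict(model, rng.random(2))
            assert label == "AD"

    def test_tie_breaks_to_lower_cluster_index(self):
        row, label = fcm_predict(self._model(), np.array([2.0, 2.0]))
        np.testing.assert_allclose(row, [0.5, 0.5], atol=1e-12)
        assert label == "NAD"

    def test_unmapped_model_raises(self):
        model = ClusterModel(centers=np.zeros((1, 2)))
        with pytest.raises(ValueError, match="map_clusters_to_classes"):
            fcm_predict(model, np.zeros(2))


class TestClusterMapping:
    def test_separated_fit_is_bijection(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.2, (10, 2)), rng.normal(5, 0.2, (10, 2))])
        labels = ["NAD"] * 10 + ["AD"] * 10
        _, M = fcm_fit(X, k=2, seed=2)
        mapping = map_clusters_to_classes(M, labels)
        assert sorted(mapping.values()) == ["AD", "NAD"]

    def test_single_class_maps_everywhere(self, rng):
        M = rng.random((8, 3))
        M /= M.sum(axis=1, keepdims=True)
        mapping = map_clusters_to_classes(M, ["AD"] * 8)
        assert set(mapping.values()) == {"AD"}

    def test_majority_count_by_hand(self):
        # 6 samples argmax-assigned to cluster 0: 4 AD vs 2 NAD -> AD
        M = np.zeros((6, 2))
        M[:, 0] = 0.9
        M[:, 1] = 0.1
        labels = ["AD", "AD", "NAD", "AD", "NAD", "AD"]
        mapping = map_clusters_to_classes(M, labels)
        assert mapping[0] == "AD"
        assert mapping[1] == "AD"  # empty cluster -> global majority
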