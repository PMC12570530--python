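"""Fuzzy C-means clustering head replacing dense classification layers.

Soft clustering assigns every feature vector a membership in each of k
clusters; memberships lie in [0, 1] and each sample's row sums to 1.
The alternating updates are the canonical pair

    c_j = sum_i M_ij^m x_i / sum_i M_ij^m                (centers)
    M_ij = 1 / sum_l (||x_i - c_j|| / ||x_i - c_l||)^(2/(m-1))

with fuzzifier m > 1 (default 2). Iteration stops when the largest
membership change drops below ``tol`` or ``max_iter`` sweeps complete.
A sample coinciding with a center receives hard membership 1 there.

Cluster indices are anonymous; :func:`map_clusters_to_classes` turns a
fitted membership matrix plus training labels into a cluster -> class
map by majority vote over argmax assignments, after which
:func:`fcm_predict` yields both a membership row and a hard class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterModel",
    "fcm_fit",
    "fcm_predict",
    "membership_rows",
    "map_clusters_to_classes",
]

_DIST_FLOOR = 1e-12


@dataclass
class ClusterModel:
    """Fitted FCM centers with the fuzzifier and cluster->class map."""

    centers: np.ndarray  # (k, d)
    m_exp: float = 2.0
    max_iter: int = 100
    tol: float = 1e-5
    cluster_to_class: dict[int, str] | None = None
    n_iter_: int = 0

    @property
    def k(self) -> int:
        return self.centers.shape[0]


def _memberships_from_centers(X: np.ndarray, centers: np.ndarray,
                              m_exp: float) -> np.ndarray:
    """Membership matrix given frozen centers (zero-distance -> hard 1)."""
    # squared distances (n, k), floored before division
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero_rows = d2 <= _DIST_FLOOR**2
    d = np.sqrt(np.maximum(d2, _DIST_FLOOR**2))
    power = 2.0 / (m_exp - 1.0)
    inv = d ** (-power)
    M = inv / inv.sum(axis=1, keepdims=True)
    hit = zero_rows.any(axis=1)
    if hit.any():
        M[hit] = 0.0
        first = zero_rows[hit].argmax(axis=1)
        M[np.flatnonzero(hit), first] = 1.0
    return M


def fcm_fit(
    X: np.ndarray,
    k: int,
    m_exp: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-5,
    seed: int = 0,
    init_M: np.ndarray | None = None,
) -> tuple[ClusterModel, np.ndarray]:
    """Fit FCM on the rows of X; returns the model and final memberships.

    Initialization is a seeded random row-stochastic membership matrix
    (or ``init_M`` when supplied, e.g. to compare against a reference
    implementation from identical initialization).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D array (n_samples, n_features)")
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= n_samples, got k={k}, n={n}")
    if m_exp <= 1.0:
        raise ValueError("fuzzifier m_exp must be > 1")

    if init_M is not None:
        M = np.asarray(init_M, dtype=np.float64).copy()
        if M.shape != (n, k):
            raise ValueError("init_M has wrong shape")
    else:
        rng = np.random.default_rng(seed)
        M = rng.random((n, k))
        M /= M.sum(axis=1, keepdims=True)

    centers = np.empty((k, X.shape[1]))
    it = 0
    for it in range(1, max_iter + 1):
        Mm = M**m_exp
        centers = (Mm.T @ X) / np.maximum(Mm.sum(axis=0), _DIST_FLOOR)[:, None]
        M_new = _memberships_from_centers(X, centers, m_exp)
        delta = np.abs(M_new - M).max()
        M = M_new
        if delta < tol:
            break
    model = ClusterModel(centers=centers, m_exp=m_exp, max_iter=max_iter,
                         tol=tol, n_iter_=it)
    return model, M


def membership_rows(model: ClusterModel, X: np.ndarray) -> np.ndarray:
    """Membership rows for new samples against frozen centers."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.centers.shape[1]:
        raise ValueError("feature length does not match cluster centers")
    return _memberships_from_centers(X, model.centers, model.m_exp)


def fcm_predict(model: ClusterModel, x: np.ndarray) -> tuple[np.ndarray, str]:
    """Membership row and hard class label for one feature vector.

    The label is the class of the highest-membership cluster; ties break
    toward the lowest cluster index (argmax convention).
    """
    if model.cluster_to_class is None:
        raise ValueError(
            "cluster_to_class is unset; call map_clusters_to_classes first"
        )
    row = membership_rows(model, x)[0]
    j = int(row.argmax())
    if j not in model.cluster_to_class:
        raise ValueError(f"cluster {j} has no class mapping")
    return row, model.cluster_to_class[j]


def map_clusters_to_classes(M: np.ndarray, labels) -> dict[int, str]:
    """Majority-vote cluster -> class map from training memberships.

    Each cluster takes the majority class among samples whose argmax
    membership lands in it; a cluster that captures no samples takes the
    globally most frequent class. Ties break deterministically toward
    the lexicographically first class label.
    """
    M = np.asarray(M)
    labels = np.asarray(labels)
    if M.shape[0] != len(labels):
        raise ValueError("one label per membership row required")
    assign = M.argmax(axis=1)
    uniq, counts = np.unique(labels, return_counts=True)
    global_major = uniq[counts.argmax()]
    mapping: dict[int, str] = {}
    for j in range(M.shape[1]):
        in_j = labels[assign == j]
        if len(in_j) == 0:
            mapping[j] = str(global_major)
            continue
        u, c = np.unique(in_j, return_counts=True)
        mapping[j] = str(u[c.argmax()])
    return mapping
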