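"""Fuzzy c-means clustering of z-scored time-course profiles.

Soft clustering in the Mfuzz tradition: each profile receives a membership
in every cluster, controlled by the fuzzifier m (> 1; m -> 1 approaches hard
k-means assignment).  The objective minimised by alternating updates is

    J = sum_i sum_j  u_ij^m * ||x_i - c_j||^2

with memberships u_ij proportional to d_ij^(-2/(m-1)) and centroids the
u^m-weighted profile means.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, validate_data


def zscore_profiles(profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each row over its time points.

    Returns the z-scored rows and a boolean mask of rows that could be
    scored; zero-variance rows cannot be z-scored and are excluded.
    """
    X = np.asarray(profiles, dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    return Z[ok], ok


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means with fuzzifier ``m``.

    Parameters
    ----------
    n_clusters : number of clusters c (>= 1)
    m : fuzzifier (> 1); smaller values give harder assignments
    tol : stop when the objective decreases by less than this
    max_iter : iteration cap
    random_state : seeds the membership initialisation

    Attributes
    ----------
    cluster_centers_ : (c, n_features) centroids
    membership_ : (n_samples, c) memberships, rows sum to 1
    labels_ : argmax membership per sample
    objective_trace_ : objective value after each iteration (non-increasing)
    n_iter_ : iterations run
    """

    def __init__(self, n_clusters: int = 6, m: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 1000, random_state: int = 0):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore"):
            w = d2 ** (-1.0 / (self.m - 1.0))
        # profile coincides with >= 1 centroid: all membership on those
        hit = zero.any(axis=1)
        w[hit] = zero[hit].astype(float)
        return w / w.sum(axis=1, keepdims=True)

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)
        u = rng.random((n, self.n_clusters))
        u /= u.sum(axis=1, keepdims=True)
        trace: list[float] = []
        prev = np.inf
        for it in range(self.max_iter):
            um = u ** self.m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            u = self._memberships(X, centers)
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            obj = float(((u ** self.m) * d2).sum())
            trace.append(obj)
            if prev - obj < self.tol:
                break
            prev = obj
        self.cluster_centers_ = centers
        self.membership_ = u
        self.labels_ = np.argmax(u, axis=1)
        self.objective_trace_ = np.array(trace)
        self.n_iter_ = len(trace)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        return np.argmax(self._memberships(X, self.cluster_centers_), axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def fuzzy_cmeans(profiles_z, c: int, m: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 1000, seed: int = 0) -> FuzzyCMeans:
    """Functional wrapper over :class:`FuzzyCMeans` (already z-scored input)."""
    return FuzzyCMeans(n_clusters=c, m=m, tol=tol, max_iter=max_iter,
                       random_state=seed).fit(np.asarray(profiles_z, float))
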