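"""Tumour delineation by fuzzy C-means clustering of enhancement.

Segmentation runs on an early-enhancement volume (first postcontrast minus
precontrast): voxel intensities are clustered with FCM, the cluster with the
higher centroid is taken as lesion, and the mask is the 26-connected
component of that cluster containing the user-supplied seed voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["FcmResult", "FuzzyCMeans", "fcm_cluster", "extract_tumour_mask", "SeedOutsideLesionError"]


class SeedOutsideLesionError(ValueError):
    """The seed voxel does not fall inside a detectable lesion."""


@dataclass
class FcmResult:
    memberships: np.ndarray  # N x c, rows sum to 1
    centroids: np.ndarray  # c x d
    objective_trace: np.ndarray  # per-iteration objective (non-increasing)
    n_iter: int


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Standard fuzzy C-means with fuzzifier ``m``.

    Alternates membership updates u_ik proportional to d_ik^(-2/(m-1)) and
    membership-weighted centroid means, until the objective
    J = sum_ik u_ik^m d_ik^2 changes by less than ``tol``.  A data point
    coinciding with a centroid receives full membership to that centroid.
    """

    def __init__(self, n_clusters: int = 2, m: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 300, random_state: int = 0):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]  # a vector of scalars
        n, _ = X.shape
        c, m = int(self.n_clusters), float(self.m)
        if c < 1:
            raise ValueError("n_clusters must be >= 1")
        if m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if n < c:
            raise ValueError("need at least n_clusters data points")
        rng = np.random.default_rng(self.random_state)
        u = rng.dirichlet(np.ones(c), size=n)  # N x c
        trace = []
        centroids = None
        for it in range(self.max_iter):
            um = u**m
            centroids = (um.T @ X) / um.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)  # N x c
            obj = float(np.sum(um * d2))
            trace.append(obj)
            zero = d2 <= 1e-300
            with np.errstate(divide="ignore"):
                inv = d2 ** (-1.0 / (m - 1.0))
            u_new = np.where(zero.any(axis=1)[:, None], zero.astype(float), inv)
            u_new = u_new / u_new.sum(axis=1, keepdims=True)
            u = u_new
            if len(trace) > 1 and abs(trace[-2] - trace[-1]) < self.tol:
                break
        self.cluster_centers_ = centroids
        self.membership_ = u
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        self.labels_ = np.argmax(u, axis=1)
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def fcm_cluster(data, c: int, m: float = 2.0, tol: float = 1e-6,
                max_iter: int = 300, seed: int = 0) -> FcmResult:
    """Functional wrapper around :class:`FuzzyCMeans`."""
    est = FuzzyCMeans(n_clusters=c, m=m, tol=tol, max_iter=max_iter, random_state=seed).fit(data)
    return FcmResult(est.membership_, est.cluster_centers_, est.objective_trace_, est.n_iter_)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def extract_tumour_mask(
    enhancement_volume,
    seed_point,
    c: int = 2,
    min_size: int = 10,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> np.ndarray:
    """Extract the lesion mask containing ``seed_point`` (0-based x, y, z).

    FCM clusters voxel enhancement into ``c`` groups; the highest-centroid
    group is the lesion class and the returned mask is its 26-connected
    component containing the seed.  Raises :class:`SeedOutsideLesionError`
    if the volume has no contrast, the seed falls outside the lesion class,
    or the component is smaller than ``min_size``.
    """
    vol = np.asarray(enhancement_volume, dtype=float)
    seed_point = tuple(int(v) for v in seed_point)
    if len(seed_point) != vol.ndim or any(
        not 0 <= s < n for s, n in zip(seed_point, vol.shape)
    ):
        raise ValueError(f"seed_point {seed_point} outside volume of shape {vol.shape}")
    if vol.std() <= 1e-12 * max(1.0, abs(float(vol.mean()))):
        raise SeedOutsideLesionError("volume has no contrast; cannot separate lesion")
    flat = vol.reshape(-1, 1)
    est = FuzzyCMeans(n_clusters=c, m=m, tol=tol, max_iter=max_iter, random_state=seed).fit(flat)
    lesion_cluster = int(np.argmax(est.cluster_centers_[:, 0]))
    lesion = (est.labels_ == lesion_cluster).reshape(vol.shape)
    if not lesion[seed_point]:
        raise SeedOutsideLesionError("seed voxel falls in the background cluster")
    structure = _CONN26 if vol.ndim == 3 else np.ones((3,) * vol.ndim, dtype=bool)
    labelled, _ = ndimage.label(lesion, structure=structure)
    mask = labelled == labelled[seed_point]
    if int(mask.sum()) < min_size:
        raise SeedOutsideLesionError(
            f"lesion component has {int(mask.sum())} voxels, below min_size={min_size}"
        )
    return mask
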