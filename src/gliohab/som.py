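"""Batch-learning self-organizing map (SOM) on a rectangular grid.

The SOM quantizes the voxel feature space into ``grid_h x grid_w``
prototype vectors ("protoclusters") arranged on a 2-D lattice.  Batch
training alternates two steps per epoch: every input row is assigned its
best-matching unit (BMU, minimal Euclidean distance), then every prototype
is replaced by the neighborhood-weighted mean

    w_j = sum_i h(b(x_i), j) x_i / sum_i h(b(x_i), j),

with a Gaussian neighborhood h of radius sigma(t) on the lattice, decreasing
linearly from max(grid_h, grid_w)/2 to 0.5 over the epochs.  Following the
N = k_max^2 protocluster rule with k_max = 20, the default grid is 20 x 20
(400 prototypes).

Implemented as a scikit-learn estimator: ``fit`` trains the map,
``predict`` returns BMU indices, ``transform`` returns distances to all
prototypes.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

DEFAULT_K_MAX = 20


def grid_size_from_kmax(k_max: int = DEFAULT_K_MAX) -> tuple[int, int]:
    """Protocluster rule N = k_max^2, realized as a square k_max x k_max grid."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    return k_max, k_max


class BatchSOM(TransformerMixin, BaseEstimator):
    """Batch-learning SOM with a Gaussian neighborhood on a rectangular grid.

    Parameters
    ----------
    grid_h, grid_w : int
        Lattice dimensions; the prototype count is ``grid_h * grid_w``.
    n_epochs : int
        Number of batch epochs.
    sigma_start, sigma_end : float or None
        Neighborhood radius schedule (lattice units).  ``sigma_start=None``
        uses ``max(grid_h, grid_w) / 2``.  The radius decreases linearly to
        ``sigma_end`` (default 0.5) over the epochs.
    init : {"pca", "random"}
        "pca" lays the initial prototypes on the plane spanned by the first
        two principal components of the data (deterministic); "random" (also
        the fallback when the data have rank < 2) draws them from the data's
        Gaussian envelope under ``random_state``.
    random_state : int
        Seed for the random-init fallback; training itself is deterministic.

    Attributes
    ----------
    prototypes_ : ndarray of shape (grid_h * grid_w, n_features)
        Trained prototype ("weight") vectors, row-major over the grid.
    grid_coords_ : ndarray of shape (grid_h * grid_w, 2)
        Lattice coordinates of each node.
    quantization_errors_ : list of float
        Mean input-to-BMU distance after each epoch.
    """

    def __init__(self, grid_h: int = DEFAULT_K_MAX, grid_w: int = DEFAULT_K_MAX,
                 n_epochs: int = 50, sigma_start: float | None = None,
                 sigma_end: float = 0.5, init: str = "pca", random_state: int = 0):
        self.grid_h = grid_h
        self.grid_w = grid_w
        self.n_epochs = n_epochs
        self.sigma_start = sigma_start
        self.sigma_end = sigma_end
        self.init = init
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _grid_coords(self) -> np.ndarray:
        hh, ww = np.meshgrid(np.arange(self.grid_h), np.arange(self.grid_w),
                             indexing="ij")
        return np.column_stack([hh.ravel(), ww.ravel()]).astype(float)

    def _init_prototypes(self, X: np.ndarray) -> np.ndarray:
        n_nodes = self.grid_h * self.grid_w
        rng = np.random.default_rng(self.random_state)
        mean = X.mean(axis=0)
        if self.init == "pca" and min(X.shape) >= 2:
            Xc = X - mean
            u, s, vt = np.linalg.svd(Xc, full_matrices=False)
            if len(s) >= 2 and s[1] > 1e-12 * max(s[0], 1.0):
                # deterministic sign: largest-|.| entry of each PC positive
                for r in range(2):
                    j = int(np.argmax(np.abs(vt[r])))
                    if vt[r, j] < 0:
                        vt[r] = -vt[r]
                scale = s[:2] / np.sqrt(len(X))
                a = np.linspace(-2, 2, self.grid_h)
                b = np.linspace(-2, 2, self.grid_w)
                aa, bb = np.meshgrid(a, b, indexing="ij")
                return (mean
                        + aa.ravel()[:, None] * scale[0] * vt[0]
                        + bb.ravel()[:, None] * scale[1] * vt[1])
            logger.info("PCA init degenerate (rank < 2); falling back to random")
        sd = X.std(axis=0)
        return mean + rng.standard_normal((n_nodes, X.shape[1])) * sd

    @staticmethod
    def _bmu(X: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
        # argmin over squared distances; ties -> lowest node index
        d2 = (np.einsum("ij,ij->i", X, X)[:, None]
              - 2.0 * X @ prototypes.T
              + np.einsum("ij,ij->i", prototypes, prototypes)[None, :])
        return np.argmin(d2, axis=1)

    def _sigma(self, epoch: int) -> float:
        start = (max(self.grid_h, self.grid_w) / 2.0
                 if self.sigma_start is None else self.sigma_start)
        if self.n_epochs <= 1:
            return self.sigma_end
        frac = epoch / (self.n_epochs - 1)
        return start + (self.sigma_end - start) * frac

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None) -> "BatchSOM":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("X must be a non-empty 2-D array")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        n_nodes = self.grid_h * self.grid_w
        if len(X) < n_nodes:
            logger.warning("fewer rows (%d) than prototypes (%d); the map will "
                           "be underdetermined", len(X), n_nodes)

        coords = self._grid_coords()
        grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        prototypes = self._init_prototypes(X)
        x_sq = np.einsum("ij,ij->i", X, X)
        qe = []
        sse = []
        for epoch in range(self.n_epochs):
            d2 = (x_sq[:, None] - 2.0 * X @ prototypes.T
                  + np.einsum("ij,ij->i", prototypes, prototypes)[None, :])
            bmu = np.argmin(d2, axis=1)
            # diagnostics of the prototypes entering this epoch (one distance
            # pass per epoch); entries for the trained map are appended below
            min_d2 = np.maximum(d2[np.arange(len(X)), bmu], 0.0)
            qe.append(float(np.sqrt(min_d2).mean()))
            sse.append(float(min_d2.mean()))
            counts = np.bincount(bmu, minlength=n_nodes).astype(float)
            sums = np.zeros((n_nodes, X.shape[1]))
            np.add.at(sums, bmu, X)
            sigma = max(self._sigma(epoch), 1e-12)
            with np.errstate(under="ignore"):
                H = np.exp(-grid_d2 / (2.0 * sigma * sigma))
            num = H @ sums
            den = H @ counts
            ok = den > 0
            prototypes = np.where(ok[:, None], num / np.where(ok, den, 1.0)[:, None],
                                  prototypes)

        self.prototypes_ = prototypes
        self.grid_coords_ = coords
        d2 = (x_sq[:, None] - 2.0 * X @ prototypes.T
              + np.einsum("ij,ij->i", prototypes, prototypes)[None, :])
        min_d2 = np.maximum(d2.min(axis=1), 0.0)
        qe.append(float(np.sqrt(min_d2).mean()))
        sse.append(float(min_d2.mean()))
        self.quantization_errors_ = qe
        # mean squared input-to-BMU distance: the objective the batch update
        # descends in the sigma->0 (k-means) limit, hence monotone there
        self.squared_errors_ = sse
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Best-matching-unit (node) index per row; ties -> lowest index."""
        check_is_fitted(self, "prototypes_")
        X = np.asarray(X, dtype=float)
        return self._bmu(X, self.prototypes_)

    def transform(self, X) -> np.ndarray:
        """Euclidean distance from each row to every prototype."""
        check_is_fitted(self, "prototypes_")
        X = np.asarray(X, dtype=float)
        d2 = (np.einsum("ij,ij->i", X, X)[:, None]
              - 2.0 * X @ self.prototypes_.T
              + np.einsum("ij,ij->i", self.prototypes_, self.prototypes_)[None, :])
        return np.sqrt(np.maximum(d2, 0.0))

    def quantization_error(self, X) -> float:
        """Mean Euclidean distance from each row to its BMU."""
        X = np.asarray(X, dtype=float)
        if len(X) == 0:
            raise ValueError("X is empty")
        return float(self.transform(X).min(axis=1).mean())

    def component_planes(self) -> np.ndarray:
        """Per-channel weight planes, shape (n_features, grid_h, grid_w).

        Plane c holds weight component c of every node reshaped onto the
        lattice — the standard SOM visualization of how one imaging channel
        varies across the map.
        """
        check_is_fitted(self, "prototypes_")
        return (self.prototypes_.T
                .reshape(self.n_features_in_, self.grid_h, self.grid_w)
                .copy())
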