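"""Two-level clustering: K-means over SOM protoclusters, and label maps.

Level one quantizes the sampled voxel features into N = k_max^2 SOM
prototypes (:class:`~gliohab.som.BatchSOM`); level two partitions the N
prototype weight vectors into K classes with K-means.  Each tumor voxel then
inherits the K-class label of its nearest prototype, producing a per-subject
habitat label map.

Cluster numbering from K-means is arbitrary, so labels are renumbered
deterministically by ascending mean ADC component of each cluster's
prototypes; label identity is thereby reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .features import ADC_CHANNEL, N_CHANNELS, SubjectStack
from .som import DEFAULT_K_MAX, BatchSOM

logger = logging.getLogger(__name__)

#: K grid explored for model selection.
DEFAULT_K_GRID = (4, 6, 8, 10, 12, 16, 20)
#: K with the best classification performance in the source study.
DEFAULT_K = 10


@dataclass
class ProtoclusterLabeling:
    """K-class partition of the SOM nodes: ``node_labels[j]`` in 1..K."""

    n_clusters: int
    node_labels: np.ndarray
    inertia: float
    seed: int
    restarts: int

    def __post_init__(self) -> None:
        self.node_labels = np.asarray(self.node_labels, dtype=int)
        used = np.unique(self.node_labels)
        if used.min() < 1 or used.max() > self.n_clusters:
            raise ValueError("node labels must lie in 1..K")
        missing = set(range(1, self.n_clusters + 1)) - set(used.tolist())
        if missing:
            logger.warning("protocluster labeling: empty classes %s", sorted(missing))


@dataclass
class LabeledTumorVolume:
    """Per-voxel habitat labels 1..K inside the tumor mask; 0 = undefined."""

    subject_id: str
    labels: np.ndarray
    n_clusters: int

    @property
    def defined_mask(self) -> np.ndarray:
        return self.labels > 0

    def label_counts(self) -> np.ndarray:
        """Voxel count per label 1..K (length-K vector)."""
        return np.bincount(self.labels[self.defined_mask],
                           minlength=self.n_clusters + 1)[1:]


def kmeans_protoclusters(som: BatchSOM, n_clusters: int, seed: int = 0,
                         restarts: int = 10) -> ProtoclusterLabeling:
    """Partition the SOM prototype vectors into K classes with K-means.

    k-means++ initialization, best of ``restarts`` runs by inertia, then
    deterministic renumbering by ascending mean ADC component.
    """
    check_is_fitted(som, "prototypes_")
    W = som.prototypes_
    if n_clusters > len(W):
        raise ValueError(f"K={n_clusters} exceeds the {len(W)} prototypes")
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=restarts,
                random_state=seed)
    raw = km.fit_predict(W)
    # renumber: ascending mean ADC of each cluster's member prototypes
    adc_col = ADC_CHANNEL if W.shape[1] == N_CHANNELS else W.shape[1] - 1
    means = np.array([W[raw == c, adc_col].mean() if np.any(raw == c) else np.inf
                      for c in range(n_clusters)])
    order = np.argsort(means, kind="stable")
    remap = np.empty(n_clusters, dtype=int)
    remap[order] = np.arange(1, n_clusters + 1)
    return ProtoclusterLabeling(
        n_clusters=n_clusters,
        node_labels=remap[raw],
        inertia=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )


def assign_labels(stack: SubjectStack, som: BatchSOM,
                  labeling: ProtoclusterLabeling) -> LabeledTumorVolume:
    """Assign each tumor voxel the K-class label of its nearest prototype.

    The stack's channels must be normalized in the same space the SOM was
    trained in.  Nearest-prototype ties break to the lowest node index;
    voxels with a non-finite channel stay undefined (label 0).
    """
    labels = np.zeros(stack.shape, dtype=int)
    tm = stack.tumor_mask
    vox = stack.channels[:, tm].T  # (n_tumor, 4)
    finite = np.isfinite(vox).all(axis=1)
    n_undef = int((~finite).sum())
    if n_undef:
        logger.info("subject %s: %d tumor voxels left unlabeled (non-finite "
                    "channel)", stack.subject_id, n_undef)
    node = np.zeros(len(vox), dtype=int)
    if finite.any():
        node[finite] = som.predict(vox[finite])
    lab = np.where(finite, labeling.node_labels[node], 0)
    labels[tm] = lab
    return LabeledTumorVolume(stack.subject_id, labels, labeling.n_clusters)


class TwoLevelHabitatClustering(ClusterMixin, BaseEstimator):
    """SOM + K-means two-level clustering of voxel features.

    ``fit(X)`` trains the batch SOM on the feature rows and partitions its
    prototypes with K-means; ``predict(X)`` returns the K-class habitat
    label (1..K) of each row via its nearest prototype.

    Parameters
    ----------
    n_clusters : int
        Number of habitat classes K (level two).
    k_max : int
        Maximum K the protocluster budget is sized for; the SOM grid is
        ``k_max x k_max`` (N = k_max^2 prototypes).
    n_epochs : int
        SOM training epochs.
    n_restarts : int
        K-means restarts on the prototype vectors.
    random_state : int
        Seed for SOM init fallback and K-means.

    Attributes
    ----------
    som_ : BatchSOM
        The trained level-one map.
    labeling_ : ProtoclusterLabeling
        The level-two partition of its nodes.
    labels_ : ndarray
        Habitat labels (1..K) of the training rows.
    """

    def __init__(self, n_clusters: int = DEFAULT_K, k_max: int = DEFAULT_K_MAX,
                 n_epochs: int = 50, n_restarts: int = 10, random_state: int = 0):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.n_epochs = n_epochs
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None) -> "TwoLevelHabitatClustering":
        X = np.asarray(X, dtype=float)
        grid_h = grid_w = self.k_max
        if self.n_clusters > grid_h * grid_w:
            raise ValueError(
                f"K={self.n_clusters} exceeds the N={grid_h * grid_w} "
                f"protocluster budget (k_max={self.k_max})"
            )
        self.som_ = BatchSOM(grid_h=grid_h, grid_w=grid_w, n_epochs=self.n_epochs,
                             random_state=self.random_state).fit(X)
        self.labeling_ = kmeans_protoclusters(
            self.som_, self.n_clusters, seed=self.random_state,
            restarts=self.n_restarts)
        self.labels_ = self.predict(X)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "som_")
        return self.labeling_.node_labels[self.som_.predict(X)]

    def label_volume(self, stack: SubjectStack) -> LabeledTumorVolume:
        """Habitat label map of one subject's tumor (see :func:`assign_labels`)."""
        check_is_fitted(self, "som_")
        return assign_labels(stack, self.som_, self.labeling_)
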