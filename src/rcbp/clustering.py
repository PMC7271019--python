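"""Per-subject hard clustering of connectivity profiles.

k-means (best of ``n_init`` k-means++ starts by within-cluster sum of
squares) is the default; spectral and agglomerative clustering are drop-in
alternatives. Labels are 1..k and every label occurs at least once.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering

from .types import ConnectivityMatrix


@dataclass(frozen=True)
class ClusterParams:
    """Clustering method and hyperparameters.

    Defaults follow common parcellation practice: k-means++ with 256
    restarts and a 10,000-iteration cap, which makes the best-of-restarts
    solution effectively deterministic on well-structured data.
    """

    method: str = "kmeans"
    k: int = 2
    n_init: int = 256
    max_iter: int = 10000
    init_method: str = "k-means++"
    linkage: str = "complete"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("kmeans", "spectral", "agglomerative"):
            raise ValueError(f"unknown clustering method {self.method!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_init < 1 or self.max_iter < 1:
            raise ValueError("n_init and max_iter must be >= 1")


@dataclass
class Labeling:
    """A hard parcellation: one integer label in 1..k per ROI voxel."""

    labels: np.ndarray
    k: int
    subject_id: str = ""
    params: ClusterParams | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1D vector")
        present = np.unique(labels)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError(f"labels must lie in 1..{self.k}, got {present}")
        if len(present) != self.k:
            raise ValueError(f"all {self.k} labels must occur; found {present}")
        self.labels = labels

    @property
    def n_voxels(self) -> int:
        return len(self.labels)


def derive_seed(master_seed: int, subject_id: str, k: int) -> int:
    """Stable per-(subject, k) seed so partial re-runs reproduce exactly.

    SHA-256 of ``master:subject:k`` reduced below 2**31; independent of
    execution order and platform hash randomization.
    """
    digest = hashlib.sha256(f"{master_seed}:{subject_id}:{k}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def cluster_subject(matrix: ConnectivityMatrix, params: ClusterParams,
                    subject_id: str = "") -> Labeling:
    """Cluster one subject's connectivity profiles into k parcels.

    For k-means the returned labeling is the best of ``params.n_init``
    k-means++ runs by within-cluster sum of squared Euclidean distances,
    deterministic given the seed. Spectral clustering uses a
    nearest-neighbor affinity graph; agglomerative clustering uses
    ``params.linkage`` on Euclidean distances.
    """
    X = matrix.values
    k = params.k
    if not np.all(np.isfinite(X)):
        raise ValueError("connectivity matrix contains non-finite values")
    if X.shape[0] < k:
        raise ValueError(f"cannot form {k} clusters from {X.shape[0]} voxels")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"fewer than {k} distinct connectivity profiles")
    seed = derive_seed(params.seed, subject_id, k)
    if params.method == "kmeans":
        model = KMeans(n_clusters=k, init=params.init_method,
                       n_init=params.n_init, max_iter=params.max_iter,
                       random_state=seed)
        raw = model.fit_predict(X)
    elif params.method == "spectral":
        n_neighbors = min(10, X.shape[0] - 1)
        model = SpectralClustering(n_clusters=k, affinity="nearest_neighbors",
                                   n_neighbors=n_neighbors, random_state=seed,
                                   assign_labels="kmeans", n_init=min(params.n_init, 32))
        raw = model.fit_predict(X)
    else:  # agglomerative
        linkage = params.linkage if params.linkage != "weighted" else "average"
        model = AgglomerativeClustering(n_clusters=k, linkage=linkage)
        raw = model.fit_predict(X)
    # sklearn labels are 0-based and guaranteed nonempty for these estimators
    return Labeling(labels=raw + 1, k=k, subject_id=subject_id, params=params)


def wss(matrix: ConnectivityMatrix, labeling: Labeling) -> float:
    """Within-cluster sum of squared Euclidean distances to own centroid."""
    X = matrix.values
    labels = labeling.labels
    if len(labels) != X.shape[0]:
        raise ValueError("labeling length does not match matrix rows")
    total = 0.0
    for lab in range(1, labeling.k + 1):
        members = X[labels == lab]
        if members.size == 0:
            raise ValueError(f"label {lab} outside 1..{labeling.k} or empty")
        centroid = members.mean(axis=0)
        total += float(((members - centroid) ** 2).sum())
    return total
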