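"""Internal cluster-validity indices and partition-agreement metrics.

Internal indices (Silhouette, Calinski-Harabasz, Davies-Bouldin) score one
subject's clustering against that subject's own connectivity features,
using Euclidean distances in the (possibly transformed) feature space that
k-means optimizes; scores are never comparable across samples. Agreement
metrics (ARI, V-measure, AMI) compare two partitions and are invariant to
label permutations. Degenerate geometry (zero within-cluster scatter,
coincident centroids) yields a documented finite sentinel plus a warning,
so batch reports always complete.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn import metrics as skmetrics

from .clustering import Labeling
from .consensus import relabel
from .types import ConnectivityMatrix, MaskVolume

logger = logging.getLogger(__name__)

#: Reported when an index is infinite/undefined by its formula (e.g. zero
#: within-cluster scatter for Calinski-Harabasz, coincident centroids for
#: Davies-Bouldin).
DEGENERATE_SENTINEL = 1e12

SIMILARITY_FUNCS = {
    "ari": skmetrics.adjusted_rand_score,
    "v_measure": skmetrics.v_measure_score,
    "ami": skmetrics.adjusted_mutual_info_score,
}


def _check(matrix: ConnectivityMatrix, labeling: Labeling) -> tuple[np.ndarray, np.ndarray]:
    X = matrix.values
    labels = labeling.labels
    if len(labels) != X.shape[0]:
        raise ValueError("labeling length does not match matrix rows")
    if not (2 <= labeling.k < X.shape[0]):
        raise ValueError(f"need 2 <= k < n, got k={labeling.k}, n={X.shape[0]}")
    return X, labels


def silhouette(matrix: ConnectivityMatrix, labeling: Labeling) -> float:
    """Mean silhouette coefficient (b - a) / max(a, b) over all voxels."""
    X, labels = _check(matrix, labeling)
    return float(skmetrics.silhouette_score(X, labels, metric="euclidean"))


def calinski_harabasz(matrix: ConnectivityMatrix, labeling: Labeling) -> float:
    """Between/within dispersion ratio [B/(k-1)] / [W/(n-k)]; higher is better."""
    X, labels = _check(matrix, labeling)
    within = 0.0
    for lab in np.unique(labels):
        members = X[labels == lab]
        within += float(((members - members.mean(axis=0)) ** 2).sum())
    if within == 0.0:
        logger.warning("Calinski-Harabasz: zero within-cluster scatter; "
                       "reporting sentinel %.0e", DEGENERATE_SENTINEL)
        return DEGENERATE_SENTINEL
    return float(skmetrics.calinski_harabasz_score(X, labels))


def davies_bouldin(matrix: ConnectivityMatrix, labeling: Labeling) -> float:
    """Mean over clusters of the worst (s_i + s_j) / d_ij ratio; lower is better."""
    X, labels = _check(matrix, labeling)
    uniq = np.unique(labels)
    centroids = np.stack([X[labels == lab].mean(axis=0) for lab in uniq])
    dists = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
    off = ~np.eye(len(uniq), dtype=bool)
    if np.any(dists[off] == 0):
        logger.warning("Davies-Bouldin: coincident centroids; reporting "
                       "sentinel %.0e", DEGENERATE_SENTINEL)
        return DEGENERATE_SENTINEL
    # direct norms (not the dot-product distance shortcut) keep full precision
    spread = np.array([np.linalg.norm(X[labels == lab] - centroids[i], axis=1).mean()
                       for i, lab in enumerate(uniq)])
    ratio = (spread[:, None] + spread[None, :]) / np.where(off, dists, np.inf)
    return float(ratio.max(axis=1).mean())


def internal_validity(matrix: ConnectivityMatrix, labeling: Labeling,
                      which: list[str] | None = None) -> dict[str, float]:
    """Compute the selected internal indices for one subject's clustering."""
    funcs = {"silhouette": silhouette, "calinski_harabasz": calinski_harabasz,
             "davies_bouldin": davies_bouldin}
    which = which or list(funcs)
    return {name: funcs[name](matrix, labeling) for name in which}


# ---------------------------------------------------------------------------
# partition agreement

def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    return a, b


def ari(a, b) -> float:
    """Adjusted Rand index: chance-corrected pair-counting agreement."""
    a, b = _paired(a, b)
    return float(skmetrics.adjusted_rand_score(a, b))


def v_measure(a, b) -> float:
    """Harmonic mean of homogeneity and completeness (entropy-based)."""
    a, b = _paired(a, b)
    return float(skmetrics.v_measure_score(a, b))


def ami(a, b) -> float:
    """Adjusted mutual information; ~0 in expectation for independent labelings."""
    a, b = _paired(a, b)
    return float(skmetrics.adjusted_mutual_info_score(a, b))


# ---------------------------------------------------------------------------
# reports

@dataclass
class SimilarityTable:
    """Pairwise subject agreement plus per-subject agreement with the group."""

    metric: str
    pairwise: np.ndarray                 # subjects x subjects
    to_group: np.ndarray                 # per subject
    subject_ids: list[str] = field(default_factory=list)
    linkage: np.ndarray | None = None    # dendrogram over 1 - similarity
    caveat: str = ("group similarity is not independent of the individual "
                   "subject clusterings and may be inflated")

    def to_frame(self) -> pd.DataFrame:
        ids = self.subject_ids or [str(i) for i in range(len(self.to_group))]
        df = pd.DataFrame(self.pairwise, index=ids, columns=ids)
        df["to_group"] = self.to_group
        return df


def similarity_report(labelings: list[Labeling], group: np.ndarray,
                      metric: str = "ari",
                      figure_path: str | None = None) -> SimilarityTable:
    """Pairwise agreement between subjects, agreement with the group, and a
    dendrogram over 1 - similarity (optionally rendered to ``figure_path``)."""
    if len(labelings) < 2:
        raise ValueError("similarity report needs at least 2 subjects")
    if metric not in SIMILARITY_FUNCS:
        raise ValueError(f"unknown similarity metric {metric!r}")
    func = SIMILARITY_FUNCS[metric]
    S = len(labelings)
    pair = np.ones((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            pair[i, j] = pair[j, i] = func(labelings[i].labels, labelings[j].labels)
    to_group = np.array([func(lab.labels, group) for lab in labelings])
    # distances for the dendrogram; agreement can be negative (ARI), so shift-free
    # 1 - s stays a valid dissimilarity in [0, 2]
    dist = 1.0 - pair
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    table = SimilarityTable(metric=metric, pairwise=pair, to_group=to_group,
                            subject_ids=[lab.subject_id for lab in labelings],
                            linkage=Z)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(8, 4))
        hierarchy.dendrogram(Z, labels=table.subject_ids or None, ax=ax)
        ax.set_ylabel(f"1 - {metric}")
        ax.set_title(f"Subject clustering similarity ({metric})")
        fig.tight_layout()
        fig.savefig(figure_path)
        plt.close(fig)
    return table


@dataclass(frozen=True)
class ReferenceComparison:
    score: float
    metric: str
    n_voxels: int
    n_mismatched: int

    @property
    def percent_mismatched(self) -> float:
        return 100.0 * self.n_mismatched / self.n_voxels


def compare_labels(group: np.ndarray, reference: np.ndarray,
                   metric: str = "ari") -> ReferenceComparison:
    """Agreement between a group parcellation and reference labels.

    The similarity score is permutation-invariant by construction; the
    mismatched-voxel count is computed after optimally permuting the group
    ids onto the reference (an alignment-free count would be ill-defined).
    """
    group, reference = _paired(np.asarray(group, int), np.asarray(reference, int))
    if metric not in SIMILARITY_FUNCS:
        raise ValueError(f"unknown similarity metric {metric!r}")
    score = float(SIMILARITY_FUNCS[metric](group, reference))
    # map both to consecutive 1..k for the assignment
    k = max(len(np.unique(group)), len(np.unique(reference)))
    g = np.searchsorted(np.unique(group), group) + 1
    r = np.searchsorted(np.unique(reference), reference) + 1
    permuted, accuracy = relabel(g, r, k=k)
    n = len(group)
    mism = int(round((1.0 - accuracy) * n))
    return ReferenceComparison(score=score, metric=metric, n_voxels=n,
                               n_mismatched=mism)


def compare_reference(group: np.ndarray, roi: MaskVolume,
                      reference_image: np.ndarray,
                      metric: str = "ari") -> ReferenceComparison:
    """Compare group labels (per ROI voxel) against a reference label image.

    ``reference_image`` is a label volume on the same grid as the ROI mask;
    every ROI voxel must carry a nonzero reference label.
    """
    reference_image = np.asarray(reference_image)
    if reference_image.shape != roi.shape:
        raise ValueError("reference image grid does not match the ROI mask")
    idx = roi.voxel_index()
    ref = reference_image[idx[:, 0], idx[:, 1], idx[:, 2]].astype(int)
    if np.any(ref == 0):
        raise ValueError(f"{int((ref == 0).sum())} ROI voxel(s) missing from "
                         "the reference image")
    return compare_labels(np.asarray(group, int), ref, metric=metric)
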