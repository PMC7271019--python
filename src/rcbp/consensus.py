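"""Group-level consensus parcellation.

Individual cluster ids are arbitrary, so subjects cannot be averaged
directly. Instead: (1) a voxel-by-voxel Hamming distance over subjects —
the fraction of subjects in which two voxels carry different labels, which
is invariant to per-subject id permutations — feeds a hierarchical
clustering whose cut at k serves as a reference; (2) each subject's labels
are permuted to best match the reference (optimal assignment, with the
matched fraction reported as relabel accuracy); (3) the per-voxel mode of
the relabeled subjects is the group parcellation (or the reference itself,
when requested). Cophenetic correlation measures how faithfully the
dendrogram preserves the original Hamming distances.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .clustering import Labeling

logger = logging.getLogger(__name__)


@dataclass
class GroupResult:
    """Everything the group step produces for one value of k."""

    k: int
    reference_labels: np.ndarray          # voxel -> 1..k, hierarchical cut
    relabeled: np.ndarray                 # subjects x voxels, permuted to reference
    relabel_accuracy: np.ndarray          # per subject, in [0, 1]
    mode_labels: np.ndarray               # group parcellation
    cophenetic_r: float
    linkage: np.ndarray                   # scipy linkage table of the reference tree
    group_mode: str = "mode"
    subject_ids: list[str] = field(default_factory=list)

    @property
    def group_labels(self) -> np.ndarray:
        """The labeling to report as the group parcellation."""
        return self.reference_labels if self.group_mode == "hierarchical" else self.mode_labels


def _stack(labelings: list[Labeling]) -> np.ndarray:
    if not labelings:
        raise ValueError("no labelings given")
    k = labelings[0].k
    n = labelings[0].n_voxels
    for lab in labelings:
        if lab.k != k:
            raise ValueError("labelings have inconsistent k")
        if lab.n_voxels != n:
            raise ValueError("labelings have inconsistent voxel counts")
    return np.stack([lab.labels for lab in labelings])


def hamming_matrix(labelings: list[Labeling]) -> np.ndarray:
    """Voxel-by-voxel disagreement fraction across subjects.

    d(u, v) = fraction of subjects whose labels differ between voxels u and
    v. Symmetric, zero diagonal, values in [0, 1], and — because only
    *within-subject* equality is consulted — unchanged under any per-subject
    permutation of cluster ids.
    """
    L = _stack(labelings)                         # subjects x voxels
    S, V = L.shape
    D = np.zeros((V, V))
    for row in L:
        D += row[:, None] != row[None, :]
    return D / S


def reference_clustering(distance: np.ndarray, k: int,
                         linkage: str = "complete"
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative tree on a distance matrix, cut at k clusters.

    Returns (labels in 1..k, scipy linkage table). Default linkage is
    complete. The cut is by merge count (``cut_tree``), which always yields
    exactly k nonempty clusters even under tied merge heights.
    """
    distance = np.asarray(distance, float)
    n = distance.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of voxels ({n})")
    condensed = squareform(distance, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    labels = hierarchy.cut_tree(Z, n_clusters=k).ravel() + 1
    return labels.astype(int), Z


def exhaustive_relabel(subject_labels: np.ndarray, reference: np.ndarray,
                       k: int) -> tuple[np.ndarray, float]:
    """Brute-force search over all k! id permutations (test oracle).

    Independent of :func:`relabel`; feasible for small k only.
    """
    subject_labels = np.asarray(subject_labels)
    reference = np.asarray(reference)
    best_perm, best_matches = None, -1
    for perm in itertools.permutations(range(1, k + 1)):
        mapped = np.asarray(perm)[subject_labels - 1]
        matches = int((mapped == reference).sum())
        if matches > best_matches:
            best_matches, best_perm = matches, mapped
    return best_perm, best_matches / len(reference)


def relabel(subject: Labeling | np.ndarray, reference: np.ndarray,
            k: int | None = None) -> tuple[np.ndarray, float]:
    """Permute a subject's cluster ids to best match the reference.

    Solved as an optimal assignment on the k x k contingency table
    (maximizing the trace, i.e. the number of agreeing voxels), which is
    exactly equivalent to exhaustive search over all k! permutations.
    Returns (permuted labels, accuracy = matched fraction).
    """
    if isinstance(subject, Labeling):
        labels, k = subject.labels, subject.k
    else:
        labels = np.asarray(subject, int)
        if k is None:
            raise ValueError("k required when passing a raw label vector")
    reference = np.asarray(reference, int)
    if len(labels) != len(reference):
        raise ValueError("subject and reference voxel counts differ")
    ref_k = int(reference.max())
    if ref_k > k:
        raise ValueError(f"reference uses {ref_k} labels but k={k}")
    # contingency[i, j] = #voxels with subject label i+1 and reference label j+1
    contingency = np.zeros((k, k), dtype=int)
    np.add.at(contingency, (labels - 1, reference - 1), 1)
    rows, cols = linear_sum_assignment(-contingency)
    mapping = np.empty(k, dtype=int)
    mapping[rows] = cols + 1
    permuted = mapping[labels - 1]
    accuracy = float((permuted == reference).sum()) / len(reference)
    return permuted, accuracy


def mode_consensus(relabeled: np.ndarray) -> np.ndarray:
    """Per-voxel most frequent label over subjects; ties -> smallest id.

    Tie events are logged since the winner there is a convention, not data.
    """
    relabeled = np.atleast_2d(np.asarray(relabeled, int))
    if relabeled.size == 0:
        raise ValueError("empty relabeled matrix")
    S, V = relabeled.shape
    kmax = int(relabeled.max())
    counts = np.zeros((V, kmax), dtype=int)
    for row in relabeled:
        np.add.at(counts, (np.arange(V), row - 1), 1)
    # argmax returns the first (smallest-id) maximum, which is the tie rule
    modes = counts.argmax(axis=1) + 1
    top = counts.max(axis=1)
    ties = (counts == top[:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("mode consensus: %d voxel(s) tied; smallest label id kept",
                    int(ties.sum()))
    return modes


def cophenetic_r(linkage_table: np.ndarray, distance: np.ndarray) -> float:
    """Pearson correlation of original vs dendrogram (cophenetic) distances.

    NaN (with a warning) when either set of distances is constant.
    """
    distance = np.asarray(distance, float)
    if distance.shape[0] < 3:
        raise ValueError("need at least 3 voxels for a cophenetic correlation")
    condensed = squareform(distance, checks=False)
    coph = hierarchy.cophenet(linkage_table)
    if np.std(condensed) == 0 or np.std(coph) == 0:
        logger.warning("cophenetic correlation undefined (constant distances)")
        return float("nan")
    return float(np.corrcoef(condensed, coph)[0, 1])


def group_parcellation(labelings: list[Labeling], k: int,
                       linkage: str = "complete",
                       group_mode: str = "mode") -> GroupResult:
    """Run the full consensus chain for one k.

    hamming_matrix -> reference_clustering -> relabel every subject ->
    mode_consensus (or the hierarchical reference itself when
    ``group_mode='hierarchical'``).
    """
    if len(labelings) < 2:
        raise ValueError("group parcellation needs at least 2 subjects")
    if group_mode not in ("mode", "hierarchical"):
        raise ValueError("group_mode must be 'mode' or 'hierarchical'")
    D = hamming_matrix(labelings)
    reference, Z = reference_clustering(D, k, linkage=linkage)
    relabeled = np.empty((len(labelings), len(reference)), dtype=int)
    accuracy = np.empty(len(labelings))
    for i, lab in enumerate(labelings):
        relabeled[i], accuracy[i] = relabel(lab, reference)
    modes = mode_consensus(relabeled)
    r = cophenetic_r(Z, D)
    return GroupResult(k=k, reference_labels=reference, relabeled=relabeled,
                       relabel_accuracy=accuracy, mode_labels=modes,
                       cophenetic_r=r, linkage=Z, group_mode=group_mode,
                       subject_ids=[lab.subject_id for lab in labelings])
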