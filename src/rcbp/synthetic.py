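"""Synthetic cohorts with a planted parcellation.

Every generator is a pure function of its design (including the seed) and
writes nothing to disk; cohorts can be materialized into the exact on-disk
formats the readers consume, so fixtures double as format-conformance
checks. The planted structure is deliberately simple: spatially contiguous
axis-aligned parcel slabs, per-parcel connectivity prototypes (random unit
vectors scaled by a separation factor), i.i.d. Gaussian subject noise, and
— for the BOLD generator — band-limited latent signals shared within a
parcel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import Labeling
from .types import BoldSeries, ConfoundTable, ConnectivityMatrix, MaskVolume


@dataclass(frozen=True)
class PlantedDesign:
    """Ground-truth cohort description.

    Defaults give a 500-voxel ROI (10 x 10 x 5 box inside a padded grid)
    split into 3 contiguous slabs, 30 subjects, 200 connectivity targets,
    prototype separation 10 at unit subject noise (separation/noise = 10:
    parcel centers sit ~14 standard deviations apart, so recovery is clean
    but per-voxel features remain visibly noisy).
    """

    roi_shape: tuple[int, int, int] = (10, 10, 5)
    k_true: int = 3
    n_subjects: int = 30
    n_targets: int = 200
    prototype_separation: float = 10.0
    subject_noise_sd: float = 1.0
    label_flip_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.prototype_separation < 0 or self.subject_noise_sd < 0:
            raise ValueError("noise/separation parameters must be >= 0")
        if not (0 <= self.label_flip_rate < 1):
            raise ValueError("label_flip_rate must lie in [0, 1)")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.roi_shape))


def planted_mask_and_labels(design: PlantedDesign) -> tuple[MaskVolume, np.ndarray]:
    """ROI mask (box with a 1-voxel zero margin) and planted labels.

    Parcels are contiguous slabs along the first axis, sized as evenly as
    the voxel count allows; labels are returned in the mask's C-order voxel
    index order.
    """
    if design.k_true > design.roi_shape[0]:
        raise ValueError("k_true exceeds the slab axis length")
    grid = tuple(s + 2 for s in design.roi_shape)
    data = np.zeros(grid, dtype=np.uint8)
    data[1:-1, 1:-1, 1:-1] = 1
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    mask = MaskVolume(data=data, affine=affine)
    # slab boundaries along axis 0
    edges = np.linspace(0, design.roi_shape[0], design.k_true + 1).round().astype(int)
    slab_of_i = np.zeros(design.roi_shape[0], dtype=int)
    for parcel, (a, b) in enumerate(zip(edges, edges[1:]), start=1):
        slab_of_i[a:b] = parcel
    idx = mask.voxel_index()
    labels = slab_of_i[idx[:, 0] - 1]
    return mask, labels


def _prototypes(design: PlantedDesign, rng: np.random.Generator) -> np.ndarray:
    proto = rng.standard_normal((design.k_true, design.n_targets))
    proto /= np.linalg.norm(proto, axis=1, keepdims=True)
    return proto * design.prototype_separation


def make_connectivity_cohort(design: PlantedDesign
                             ) -> tuple[list[ConnectivityMatrix], MaskVolume, np.ndarray]:
    """Per-subject connectivity matrices around per-parcel prototypes.

    Each parcel's prototype row is a random unit vector scaled by
    ``prototype_separation``; each subject observes prototype + i.i.d.
    Gaussian noise of sd ``subject_noise_sd``. Deterministic in the seed.
    """
    if design.k_true > design.n_voxels:
        raise ValueError("k_true exceeds the ROI voxel count")
    rng = np.random.default_rng(design.seed)
    mask, labels = planted_mask_and_labels(design)
    proto = _prototypes(design, rng)
    base = proto[labels - 1]
    idx = mask.voxel_index()
    cohort = []
    for _ in range(design.n_subjects):
        noise = rng.normal(0.0, design.subject_noise_sd,
                           size=base.shape) if design.subject_noise_sd > 0 else 0.0
        cohort.append(ConnectivityMatrix(values=base + noise,
                                         voxel_index=idx.copy(),
                                         transform_log=["synthetic"]))
    return cohort, mask, labels


def make_noisy_labelings(design: PlantedDesign) -> tuple[list[Labeling], np.ndarray]:
    """Planted labels with per-subject id permutations and random flips.

    Each subject's labeling is the planted partition under a random
    permutation of cluster ids, with ``label_flip_rate`` of voxels flipped
    to a uniformly random *other* label. The flip rate must stay below
    0.5 * (k-1)/k so the mode over enough subjects still recovers the
    planted labels.
    """
    if design.label_flip_rate >= 0.5 * (design.k_true - 1) / design.k_true:
        raise ValueError("label_flip_rate too high for mode recovery")
    rng = np.random.default_rng(design.seed)
    _, planted = planted_mask_and_labels(design)
    n = len(planted)
    k = design.k_true
    out = []
    for s in range(design.n_subjects):
        perm = rng.permutation(k) + 1
        labels = perm[planted - 1]
        n_flip = int(round(design.label_flip_rate * n))
        if n_flip:
            flip_at = rng.choice(n, size=n_flip, replace=False)
            shift = rng.integers(1, k, size=n_flip)
            labels = labels.copy()
            labels[flip_at] = (labels[flip_at] - 1 + shift) % k + 1
        out.append(Labeling(labels=labels, k=k, subject_id=f"sub-{s:03d}"))
    return out, planted


@dataclass
class BoldCohort:
    """BOLD series for ROI+target grids with the planted parcellation."""

    roi_series: list[BoldSeries]
    roi_mask: MaskVolume
    target_mask: MaskVolume
    confounds: list[ConfoundTable] | None
    planted_labels: np.ndarray
    tr_seconds: float


def _band_limited_signals(n_signals: int, n_timepoints: int, tr: float,
                          rng: np.random.Generator,
                          low_hz: float = 0.015, high_hz: float = 0.07) -> np.ndarray:
    """Sums of random-phase sinusoids inside the resting-state band."""
    t = np.arange(n_timepoints) * tr
    freqs = rng.uniform(low_hz, high_hz, size=(n_signals, 6))
    phases = rng.uniform(0, 2 * np.pi, size=(n_signals, 6))
    sig = np.zeros((n_signals, n_timepoints))
    for j in range(freqs.shape[1]):
        sig += np.sin(2 * np.pi * freqs[:, j, None] * t[None, :] + phases[:, j, None])
    sig -= sig.mean(axis=1, keepdims=True)
    sig /= sig.std(axis=1, keepdims=True)
    return sig


def make_bold_cohort(design: PlantedDesign, n_timepoints: int = 200,
                     tr_seconds: float = 0.72,
                     inject_confounds: bool = False) -> BoldCohort:
    """4D BOLD cohort whose functional connectivity carries the planted parcels.

    One band-limited latent signal per parcel; every ROI voxel emits its
    parcel's signal plus Gaussian noise, and each target voxel is tied to
    one parcel (round-robin) so ROI-to-target correlation recovers the
    planted block structure. The single combined grid holds the ROI box and
    a disjoint target strip. With ``inject_confounds`` a known linear trend
    and slow sinusoid are added to every voxel and returned as a confound
    table, for nuisance-regression testing.
    """
    if n_timepoints < 50:
        raise ValueError("need at least 50 timepoints")
    rng = np.random.default_rng(design.seed)
    roi_mask, labels = planted_mask_and_labels(design)
    gi, gj, gk = roi_mask.shape

    # target voxels live in an appended slab along axis 0, disjoint from the ROI
    n_targets = design.n_targets
    tgt_cols = gj * gk
    tgt_rows = -(-n_targets // tgt_cols)
    full_shape = (gi + 1 + tgt_rows, gj, gk)
    roi_data = np.zeros(full_shape, dtype=np.uint8)
    roi_data[:gi] = roi_mask.data
    roi_full = MaskVolume(data=roi_data, affine=roi_mask.affine)
    tgt_data = np.zeros(full_shape, dtype=np.uint8)
    flat = np.zeros(tgt_rows * gj * gk, dtype=np.uint8)
    flat[:n_targets] = 1
    tgt_data[gi + 1:] = flat.reshape(tgt_rows, gj, gk)
    target_mask = MaskVolume(data=tgt_data, affine=roi_mask.affine)

    latent = _band_limited_signals(design.k_true, n_timepoints, tr_seconds, rng)
    # noise scale relative to unit-variance latent signals
    sd = design.subject_noise_sd / max(design.prototype_separation, 1e-12)
    roi_idx = roi_full.voxel_index()
    tgt_idx = target_mask.voxel_index()
    tgt_parcel = np.arange(n_targets) % design.k_true

    cohort, confs = [], []
    trend = np.linspace(-1, 1, n_timepoints)
    slow = np.sin(2 * np.pi * 0.005 * np.arange(n_timepoints) * tr_seconds)
    for _ in range(design.n_subjects):
        vol = np.zeros(full_shape + (n_timepoints,))
        roi_ts = latent[labels - 1]
        tgt_ts = latent[tgt_parcel]
        if sd > 0:
            roi_ts = roi_ts + rng.normal(0, sd, roi_ts.shape)
            tgt_ts = tgt_ts + rng.normal(0, sd, tgt_ts.shape)
        vol[roi_idx[:, 0], roi_idx[:, 1], roi_idx[:, 2]] = roi_ts
        vol[tgt_idx[:, 0], tgt_idx[:, 1], tgt_idx[:, 2]] = tgt_ts
        if inject_confounds:
            vol += (1.5 * trend + 0.8 * slow)[None, None, None, :]
            confs.append(ConfoundTable(column_names=["trend", "slow_drift"],
                                       values=np.column_stack([trend, slow])))
        cohort.append(BoldSeries(data=vol, affine=roi_mask.affine,
                                 tr_seconds=tr_seconds))
    return BoldCohort(roi_series=cohort, roi_mask=roi_full,
                      target_mask=target_mask,
                      confounds=confs if inject_confounds else None,
                      planted_labels=labels, tr_seconds=tr_seconds)


def materialize_connectivity_dataset(design: PlantedDesign, out_dir) -> dict:
    """Write a connectivity-modality input dataset to disk.

    Produces exactly what a precomputed-connectivity project consumes: the
    ROI mask (NIfTI), per-subject dense matrices (.npy), the shared voxel
    index (.npy), a participants TSV, and the planted labels (.npy, for
    evaluation only). Returns the path map.
    """
    from pathlib import Path

    import pandas as pd

    from . import io as rio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort, mask, labels = make_connectivity_cohort(design)
    paths = {
        "roi_mask": out_dir / "roi.nii.gz",
        "voxel_index": out_dir / "voxel_index.npy",
        "participants": out_dir / "participants.tsv",
        "planted_labels": out_dir / "planted_labels.npy",
    }
    rio.write_mask(mask, paths["roi_mask"])
    np.save(paths["voxel_index"], mask.voxel_index())
    np.save(paths["planted_labels"], labels)
    ids = [f"sub-{i:03d}" for i in range(design.n_subjects)]
    pd.DataFrame({"participant_id": ids}).to_csv(paths["participants"],
                                                 sep="\t", index=False)
    for pid, matrix in zip(ids, cohort):
        np.save(out_dir / f"{pid}_connectivity.npy", matrix.values)
    paths["connectivity_template"] = out_dir / "{participant_id}_connectivity.npy"
    return paths


def materialize_bold_dataset(design: PlantedDesign, out_dir,
                             n_timepoints: int = 120,
                             tr_seconds: float = 0.72,
                             inject_confounds: bool = True) -> dict:
    """Write a resting-state-modality input dataset to disk.

    Per-subject 4D BOLD NIfTIs (plus confound TSVs when injected), ROI and
    target masks, a participants TSV, and the planted labels.
    """
    from pathlib import Path

    import pandas as pd

    from . import io as rio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = make_bold_cohort(design, n_timepoints=n_timepoints,
                              tr_seconds=tr_seconds,
                              inject_confounds=inject_confounds)
    paths = {
        "roi_mask": out_dir / "roi.nii.gz",
        "target_mask": out_dir / "target.nii.gz",
        "participants": out_dir / "participants.tsv",
        "planted_labels": out_dir / "planted_labels.npy",
        "time_series_template": out_dir / "{participant_id}_bold.nii.gz",
    }
    rio.write_mask(cohort.roi_mask, paths["roi_mask"])
    rio.write_mask(cohort.target_mask, paths["target_mask"])
    np.save(paths["planted_labels"], cohort.planted_labels)
    ids = [f"sub-{i:03d}" for i in range(design.n_subjects)]
    pd.DataFrame({"participant_id": ids}).to_csv(paths["participants"],
                                                 sep="\t", index=False)
    for i, pid in enumerate(ids):
        rio.write_bold(cohort.roi_series[i], out_dir / f"{pid}_bold.nii.gz")
        if cohort.confounds is not None:
            rio.write_confounds(cohort.confounds[i],
                                out_dir / f"{pid}_confounds.tsv")
    if cohort.confounds is not None:
        paths["confounds_template"] = out_dir / "{participant_id}_confounds.tsv"
    return paths


def materialize_sparse_dataset(design: PlantedDesign, out_dir) -> dict:
    """Write a tractography-style sparse-connectivity input dataset.

    Per-subject coordinate-list text matrices of nonnegative streamline-like
    counts (prototype magnitudes shifted positive and rounded), plus the ROI
    mask, participants TSV and planted labels.
    """
    from pathlib import Path

    import pandas as pd

    from . import io as rio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort, mask, labels = make_connectivity_cohort(design)
    paths = {
        "roi_mask": out_dir / "roi.nii.gz",
        "participants": out_dir / "participants.tsv",
        "planted_labels": out_dir / "planted_labels.npy",
        "connectivity_template": out_dir / "{participant_id}_omat2.txt",
        "sparse_shape": [design.n_voxels, design.n_targets],
    }
    rio.write_mask(mask, paths["roi_mask"])
    np.save(paths["planted_labels"], labels)
    ids = [f"sub-{i:03d}" for i in range(design.n_subjects)]
    pd.DataFrame({"participant_id": ids}).to_csv(paths["participants"],
                                                 sep="\t", index=False)
    shift = max(0.0, -min(float(m.values.min()) for m in cohort))
    for pid, m in zip(ids, cohort):
        counts = np.round((m.values + shift) * 10).astype(int)
        rio.write_sparse_connectivity(counts, out_dir / f"{pid}_omat2.txt")
    return paths
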