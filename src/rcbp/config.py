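"""Project configuration: schema, YAML loading, validation, examples.

A project is fully described by one YAML file. Validation is structural and
returns (errors, warnings): errors block project creation, warnings are
logged but do not stop execution. File-existence checks happen at project
creation, not here, so shipped example configurations validate cleanly
before the user fills in their paths.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .types import ParticipantTable

MODALITIES = ("rsfmri", "dmri", "connectivity")
CLUSTER_METHODS = ("kmeans", "spectral", "agglomerative")
LINKAGES = ("complete", "average", "single", "ward", "weighted")
INTERNAL_METRICS = ("silhouette", "calinski_harabasz", "davies_bouldin")
SIMILARITY_METRICS = ("ari", "v_measure", "ami")
PLACEHOLDER = "{participant_id}"


@dataclass
class MaskingOptions:
    median_filter: bool = False
    subsample_target: bool = True
    remove_roi_from_target: bool = True
    border_mm: float = 0.0
    upsample_factor: int | None = None
    downsample_factor: int | None = None


@dataclass
class ConnectivityOptions:
    smoothing_fwhm_mm: float = 5.0
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.08
    fisher_z: bool = True
    cubic: bool = True          # dMRI path only
    pca: int | float | None = None
    confound_columns: list[str] | None = None
    expand_motion_confounds: bool = False


@dataclass
class ClusteringOptions:
    method: str = "kmeans"
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    n_init: int = 256
    max_iter: int = 10000
    init_method: str = "k-means++"
    linkage: str = "complete"
    group_linkage: str = "complete"
    group_mode: str = "mode"    # "mode" or "hierarchical"
    seed: int = 0


@dataclass
class ValidityOptions:
    internal: list[str] = field(default_factory=lambda: list(INTERNAL_METRICS))
    similarity: str = "ari"
    reference_images: list[str] = field(default_factory=list)


@dataclass
class ProjectConfig:
    """Everything needed to set up and run a parcellation project."""

    modality: str = "connectivity"
    participants: str = "participants.tsv"
    roi_mask: str = "roi.nii.gz"
    target_mask: str | None = None
    # subject-wise input templates (must contain {participant_id})
    time_series: str | None = None
    confounds: str | None = None
    connectivity: str | None = None
    voxel_index: str | None = None
    sparse_shape: list[int] | None = None   # [n_rows, n_cols] for sparse text input
    tr_seconds: float | None = None
    masking: MaskingOptions = field(default_factory=MaskingOptions)
    connectivity_options: ConnectivityOptions = field(default_factory=ConnectivityOptions)
    clustering: ClusteringOptions = field(default_factory=ClusteringOptions)
    validity: ValidityOptions = field(default_factory=ValidityOptions)
    figure_format: str = "png"

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ProjectConfig":
        d = dict(d)
        for key, sub in (("masking", MaskingOptions),
                         ("connectivity_options", ConnectivityOptions),
                         ("clustering", ClusteringOptions),
                         ("validity", ValidityOptions)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProjectConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return Path(path)


def _subject_templates(config: ProjectConfig) -> list[tuple[str, str]]:
    pairs = []
    for name in ("time_series", "confounds", "connectivity"):
        value = getattr(config, name)
        if value:
            pairs.append((name, value))
    return pairs


def validate_config(config: ProjectConfig,
                    participants: ParticipantTable | None = None
                    ) -> tuple[list[str], list[str]]:
    """Structural validation; returns (errors, warnings).

    Errors must be resolved before a project can be created; warnings are
    advisory only.
    """
    errors: list[str] = []
    warnings_: list[str] = []

    if config.modality not in MODALITIES:
        errors.append(f"modality must be one of {MODALITIES}, got {config.modality!r}")

    cl = config.clustering
    if cl.method not in CLUSTER_METHODS:
        errors.append(f"clustering.method must be one of {CLUSTER_METHODS}, got {cl.method!r}")
    if not cl.k_range:
        errors.append("clustering.k_range is empty")
    else:
        if any(int(k) < 2 for k in cl.k_range):
            errors.append(f"clustering.k_range entries must be >= 2, got {cl.k_range}")
        if any(b <= a for a, b in zip(cl.k_range, cl.k_range[1:])):
            errors.append(f"clustering.k_range must be strictly increasing, got {cl.k_range}")
    if cl.n_init < 1:
        errors.append(f"clustering.n_init must be >= 1, got {cl.n_init}")
    if cl.max_iter < 1:
        errors.append(f"clustering.max_iter must be >= 1, got {cl.max_iter}")
    if cl.linkage not in LINKAGES:
        errors.append(f"clustering.linkage must be one of {LINKAGES}, got {cl.linkage!r}")
    if cl.group_linkage not in LINKAGES:
        errors.append(f"clustering.group_linkage must be one of {LINKAGES}")
    if cl.group_mode not in ("mode", "hierarchical"):
        errors.append("clustering.group_mode must be 'mode' or 'hierarchical'")

    co = config.connectivity_options
    if config.modality == "rsfmri":
        if not config.time_series:
            errors.append("rsfmri modality requires a time_series path template")
        if co.smoothing_fwhm_mm < 0:
            errors.append("smoothing_fwhm_mm must be >= 0")
        if not (0 < co.bandpass_low_hz < co.bandpass_high_hz):
            errors.append("bandpass band must satisfy 0 < low < high")
        if config.tr_seconds is not None and co.bandpass_high_hz >= 1 / (2 * config.tr_seconds):
            errors.append("bandpass_high_hz must be below the Nyquist frequency 1/(2*TR)")
        if not config.confounds:
            warnings_.append("no confounds template given; nuisance regression is skipped")
    if config.modality in ("dmri", "connectivity"):
        if not config.connectivity:
            errors.append(f"{config.modality} modality requires a connectivity path template")
    if config.modality == "connectivity" and config.masking.median_filter:
        warnings_.append("median filtering the ROI with precomputed connectivity can "
                         "desynchronize the mask from the matrix voxel index")

    if isinstance(co.pca, float) and not (0 < co.pca < 1):
        errors.append("pca as a fraction must lie in (0, 1)")
    if isinstance(co.pca, int) and not isinstance(co.pca, bool) and co.pca < 1:
        errors.append("pca as a component count must be >= 1")

    mk = config.masking
    if mk.border_mm < 0:
        errors.append("masking.border_mm must be >= 0")
    for name in ("upsample_factor", "downsample_factor"):
        value = getattr(mk, name)
        if value is not None and value < 2:
            errors.append(f"masking.{name} must be >= 2")

    for metric in config.validity.internal:
        if metric not in INTERNAL_METRICS:
            errors.append(f"unknown internal validity metric {metric!r}")
    if config.validity.similarity not in SIMILARITY_METRICS:
        errors.append(f"validity.similarity must be one of {SIMILARITY_METRICS}")

    multi = participants is None or len(participants) > 1
    for name, template in _subject_templates(config):
        if multi and PLACEHOLDER not in template:
            errors.append(f"{name} template must contain {PLACEHOLDER!r} "
                          f"(it is replaced per subject)")
    return errors, warnings_


def example_config(data_type: str) -> ProjectConfig:
    """A complete, structurally valid example configuration per modality."""
    if data_type not in MODALITIES:
        raise ValueError(f"unknown data type {data_type!r}; valid types: {', '.join(MODALITIES)}")
    cfg = ProjectConfig(modality=data_type,
                        participants="/data/participants.tsv",
                        roi_mask="/data/masks/roi.nii.gz")
    if data_type == "rsfmri":
        cfg.time_series = "/data/{participant_id}/bold.nii.gz"
        cfg.confounds = "/data/{participant_id}/confounds.tsv"
        cfg.connectivity_options.cubic = False
    elif data_type == "dmri":
        cfg.connectivity = "/data/{participant_id}/omatrix2.txt"
        cfg.sparse_shape = [500, 10000]
        cfg.connectivity_options.fisher_z = False
        cfg.masking.subsample_target = False
    else:  # precomputed connectivity: time-series-only options omitted
        cfg.connectivity = "/data/{participant_id}/connectivity.npy"
        cfg.voxel_index = "/data/voxel_index.npy"
        cfg.connectivity_options.fisher_z = False
        cfg.connectivity_options.cubic = False
        cfg.masking = MaskingOptions(median_filter=False, subsample_target=False,
                                     remove_roi_from_target=False)
    return cfg
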