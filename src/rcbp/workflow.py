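"""Project lifecycle: create, run (resumable), report.

A project directory holds a snapshot of the configuration and participants
table plus one output file tree. Execution is an internal dependency graph:
masks -> per-subject connectivity -> per-(subject, k) clustering ->
per-k group consensus -> per-k validity reports. Each unit records a
checksum of its inputs (file digests + the relevant configuration section)
in ``state.json``; a unit re-runs only when its outputs are missing or its
checksum changed, so an interrupted run resumed later — or a run split
across workers — produces byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import connectivity as conn
from . import consensus as cons
from . import io as rio
from . import masks as mops
from . import validity as val
from .clustering import ClusterParams, Labeling, cluster_subject
from .config import PLACEHOLDER, ProjectConfig, validate_config
from .types import ConnectivityMatrix, MaskVolume

logger = logging.getLogger(__name__)

STATE_FILE = "state.json"


class ProjectError(RuntimeError):
    """Raised when a project cannot be created or run."""


@dataclass
class ProjectState:
    """On-disk project bookkeeping: completed units and their input checksums."""

    project_dir: Path
    completed: dict[str, str] = field(default_factory=dict)

    @classmethod
    def load(cls, project_dir: str | Path) -> "ProjectState":
        project_dir = Path(project_dir)
        state_path = project_dir / STATE_FILE
        completed = {}
        if state_path.exists():
            completed = json.loads(state_path.read_text())
        return cls(project_dir=project_dir, completed=completed)

    def save(self) -> None:
        (self.project_dir / STATE_FILE).write_text(
            json.dumps(self.completed, indent=1, sort_keys=True))

    def is_done(self, unit: str, checksum: str, outputs: list[Path]) -> bool:
        return (self.completed.get(unit) == checksum
                and all(p.exists() for p in outputs))

    def mark(self, unit: str, checksum: str) -> None:
        self.completed[unit] = checksum


def _digest(*parts: object) -> str:
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, Path):
            h.update(part.read_bytes() if part.exists() else b"<missing>")
        else:
            h.update(repr(part).encode())
    return h.hexdigest()[:16]


def subject_path(template: str, participant_id: str) -> Path:
    return Path(template.replace(PLACEHOLDER, participant_id))


def create_project(config_path: str | Path, out_dir: str | Path) -> ProjectState:
    """Validate the configuration and set up a fresh project directory.

    Errors (structural problems or missing input files) abort creation;
    warnings are logged and do not.
    """
    config = ProjectConfig.from_yaml(config_path)
    participants = rio.read_participants(config.participants)
    errors, warns = validate_config(config, participants)
    # input files must exist at creation time
    for label, path in (("participants", config.participants),
                        ("roi_mask", config.roi_mask),
                        ("target_mask", config.target_mask)):
        if path and not Path(path).exists():
            errors.append(f"{label} file not found: {path}")
    for name in ("time_series", "confounds", "connectivity"):
        template = getattr(config, name)
        if template:
            for pid in participants:
                p = subject_path(template, pid)
                if not p.exists():
                    errors.append(f"{name} missing for {pid}: {p}")
                    break
    if errors:
        raise ProjectError("configuration errors:\n  " + "\n  ".join(errors))
    for w in warns:
        logger.warning("config warning: %s", w)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    shutil.copy(config.participants, out_dir / "participants.tsv")
    for sub in ("masks", "connectivity", "clustering", "group", "validity"):
        (out_dir / sub).mkdir(exist_ok=True)
    state = ProjectState(project_dir=out_dir)
    state.save()
    logger.info("project created at %s (%d subjects)", out_dir, len(participants))
    return state


# ---------------------------------------------------------------------------
# stages

def _stage_masks(config: ProjectConfig, state: ProjectState) -> tuple[MaskVolume, MaskVolume | None]:
    d = state.project_dir / "masks"
    roi = rio.read_mask(config.roi_mask)
    target = rio.read_mask(config.target_mask) if config.target_mask else None
    mk = config.masking
    checksum = _digest(Path(config.roi_mask),
                       Path(config.target_mask) if config.target_mask else "none",
                       mk)
    outputs = [d / "roi.nii.gz", d / "voxel_index.npy"]
    if target is not None:
        outputs.append(d / "target.nii.gz")
    if state.is_done("masks", checksum, outputs):
        roi = rio.read_mask(d / "roi.nii.gz")
        target = rio.read_mask(d / "target.nii.gz") if target is not None else None
        return roi, target
    if mk.median_filter:
        roi = mops.median_filter_mask(roi)
    if target is not None:
        if mk.remove_roi_from_target:
            target = mops.remove_roi_from_target(target, roi, mk.border_mm)
        if mk.subsample_target:
            target = mops.subsample_target(target)
        if mk.downsample_factor:
            target = mops.downsample_target(target, mk.downsample_factor)
        rio.write_mask(target, d / "target.nii.gz")
    rio.write_mask(roi, d / "roi.nii.gz")
    np.save(d / "voxel_index.npy", roi.voxel_index())
    state.mark("masks", checksum)
    state.save()
    return roi, target


def _subject_connectivity(config: ProjectConfig, state_dir: Path, pid: str,
                          roi: MaskVolume, target: MaskVolume | None
                          ) -> ConnectivityMatrix:
    co = config.connectivity_options
    if config.modality == "connectivity":
        path = subject_path(config.connectivity, pid)
        matrix = rio.read_dense_connectivity(path, config.voxel_index)
        if co.pca is not None:
            matrix = conn.pca_reduce(matrix, co.pca)
        return matrix
    if config.modality == "dmri":
        path = subject_path(config.connectivity, pid)
        n_rows, n_cols = config.sparse_shape
        matrix = rio.read_sparse_connectivity(path, n_rows, n_cols)
        matrix = rio.attach_voxel_index(matrix, roi.voxel_index())
        if co.cubic:
            matrix = conn.cubic_transform(matrix)
        if co.pca is not None:
            matrix = conn.pca_reduce(matrix, co.pca)
        return matrix
    # rsfmri
    series = rio.read_bold(subject_path(config.time_series, pid),
                           tr_seconds=config.tr_seconds)
    confounds = None
    if config.confounds:
        confounds = rio.read_confounds(subject_path(config.confounds, pid),
                                       usecols=co.confound_columns)
        if co.expand_motion_confounds:
            confounds = conn.expand_motion_confounds(confounds)
    if target is None:
        raise ProjectError("rsfmri modality requires a target mask")
    return conn.rsfmri_connectivity(
        series, roi, target,
        smoothing=conn.SmoothingSpec(co.smoothing_fwhm_mm),
        confounds=confounds,
        band=conn.BandpassSpec(co.bandpass_low_hz, co.bandpass_high_hz),
        apply_fisher_z=co.fisher_z, pca=co.pca)


def _stage_connectivity(config: ProjectConfig, state: ProjectState,
                        participants: list[str], roi: MaskVolume,
                        target: MaskVolume | None, jobs: int) -> None:
    d = state.project_dir / "connectivity"

    def unit(pid: str) -> tuple[str, str, bool]:
        template = config.connectivity or config.time_series
        inputs = [subject_path(template, pid)]
        if config.modality == "rsfmri" and config.confounds:
            inputs.append(subject_path(config.confounds, pid))
        checksum = _digest(*inputs, config.connectivity_options, config.modality,
                           state.completed.get("masks", ""))
        out = d / f"{pid}.npy"
        if state.is_done(f"connectivity:{pid}", checksum, [out]):
            return pid, checksum, False
        matrix = _subject_connectivity(config, state.project_dir, pid, roi, target)
        rio.save_matrix(matrix, out)
        return pid, checksum, True

    results = Parallel(n_jobs=jobs)(delayed(unit)(pid) for pid in participants)
    for pid, checksum, ran in results:
        state.mark(f"connectivity:{pid}", checksum)
    state.save()


def _stage_clustering(config: ProjectConfig, state: ProjectState,
                      participants: list[str], jobs: int) -> None:
    cdir = state.project_dir / "connectivity"
    ldir = state.project_dir / "clustering"
    cl = config.clustering

    def unit(pid: str, k: int) -> tuple[str, str]:
        params = ClusterParams(method=cl.method, k=k, n_init=cl.n_init,
                               max_iter=cl.max_iter, init_method=cl.init_method,
                               linkage=cl.linkage, seed=cl.seed)
        checksum = _digest(cdir / f"{pid}.npy", params)
        out = ldir / f"{pid}_k{k}.npy"
        name = f"clustering:{pid}:k{k}"
        if state.is_done(name, checksum, [out]):
            return name, checksum
        matrix = rio.load_matrix(cdir / f"{pid}.npy")
        labeling = cluster_subject(matrix, params, subject_id=pid)
        np.save(out, labeling.labels)
        return name, checksum

    units = [(pid, k) for pid in participants for k in config.clustering.k_range]
    results = Parallel(n_jobs=jobs)(delayed(unit)(pid, k) for pid, k in units)
    for name, checksum in results:
        state.mark(name, checksum)
    state.save()


def _load_labelings(state: ProjectState, participants: list[str],
                    k: int) -> list[Labeling]:
    ldir = state.project_dir / "clustering"
    out = []
    for pid in participants:
        labels = np.load(ldir / f"{pid}_k{k}.npy")
        out.append(Labeling(labels=labels, k=k, subject_id=pid))
    return out


def _stage_group(config: ProjectConfig, state: ProjectState,
                 participants: list[str], roi: MaskVolume, jobs: int) -> None:
    gdir = state.project_dir / "group"
    cl = config.clustering

    def unit(k: int) -> tuple[str, str]:
        deps = [state.project_dir / "clustering" / f"{pid}_k{k}.npy"
                for pid in participants]
        checksum = _digest(*deps, cl.group_linkage, cl.group_mode)
        kdir = gdir / f"k{k}"
        outs = [kdir / "group_labels.npy", kdir / "group_labels.nii.gz",
                kdir / "relabel_accuracy.tsv"]
        name = f"group:k{k}"
        if state.is_done(name, checksum, outs):
            return name, checksum
        kdir.mkdir(exist_ok=True)
        labelings = _load_labelings(state, participants, k)
        result = cons.group_parcellation(labelings, k, linkage=cl.group_linkage,
                                         group_mode=cl.group_mode)
        np.save(kdir / "group_labels.npy", result.group_labels)
        np.save(kdir / "reference_labels.npy", result.reference_labels)
        np.save(kdir / "relabeled.npy", result.relabeled)
        np.save(kdir / "linkage.npy", result.linkage)
        rio.write_labels_nifti(result.group_labels, roi, kdir / "group_labels.nii.gz")
        pd.DataFrame({"participant_id": participants,
                      "relabel_accuracy": result.relabel_accuracy}).to_csv(
            kdir / "relabel_accuracy.tsv", sep="\t", index=False)
        pd.DataFrame({"k": [k], "cophenetic_r": [result.cophenetic_r]}).to_csv(
            kdir / "cophenetic.tsv", sep="\t", index=False)
        return name, checksum

    results = Parallel(n_jobs=jobs)(delayed(unit)(k) for k in cl.k_range)
    for name, checksum in results:
        state.mark(name, checksum)
    state.save()


def _stage_validity(config: ProjectConfig, state: ProjectState,
                    participants: list[str], roi: MaskVolume, jobs: int) -> None:
    vdir = state.project_dir / "validity"
    metric = config.validity.similarity

    def unit(k: int) -> tuple[str, str]:
        deps = [state.project_dir / "group" / f"k{k}" / "group_labels.npy"]
        checksum = _digest(*deps, config.validity, config.figure_format,
                           state.completed.get(f"group:k{k}", ""))
        outs = [vdir / f"internal_k{k}.tsv", vdir / f"similarity_k{k}.tsv"]
        name = f"validity:k{k}"
        if state.is_done(name, checksum, outs):
            return name, checksum
        labelings = _load_labelings(state, participants, k)
        rows = []
        for pid, lab in zip(participants, labelings):
            matrix = rio.load_matrix(state.project_dir / "connectivity" / f"{pid}.npy")
            scores = val.internal_validity(matrix, lab, config.validity.internal)
            rows.append({"participant_id": pid, "k": k, **scores})
        pd.DataFrame(rows).to_csv(vdir / f"internal_k{k}.tsv", sep="\t", index=False)
        group = np.load(deps[0])
        fig = vdir / f"similarity_dendrogram_k{k}.{config.figure_format}"
        table = val.similarity_report(labelings, group, metric=metric,
                                      figure_path=str(fig))
        table.to_frame().to_csv(vdir / f"similarity_k{k}.tsv", sep="\t")
        for ref_path in config.validity.reference_images:
            ref_img = np.asanyarray(nib.load(ref_path).dataobj)
            comp = val.compare_reference(group, roi, ref_img, metric=metric)
            pd.DataFrame([{"k": k, "reference": ref_path, "metric": metric,
                           "score": comp.score, "n_voxels": comp.n_voxels,
                           "n_mismatched": comp.n_mismatched,
                           "percent_mismatched": comp.percent_mismatched}]).to_csv(
                vdir / f"reference_k{k}.tsv", sep="\t", index=False)
        return name, checksum

    results = Parallel(n_jobs=jobs)(delayed(unit)(k) for k in config.clustering.k_range)
    for name, checksum in results:
        state.mark(name, checksum)
    state.save()


def run_project(project_dir: str | Path, jobs: int = 1,
                subjects: list[str] | None = None,
                k_values: list[int] | None = None) -> ProjectState:
    """Execute (or resume) all stages of a created project.

    ``jobs`` parallelizes independent (subject, k) units; outputs are a pure
    function of (inputs, config, master seed), so the worker count and any
    interruption history never change the results.
    """
    project_dir = Path(project_dir)
    if not (project_dir / "config.yaml").exists():
        raise ProjectError(f"{project_dir} is not a project (missing config.yaml)")
    config = ProjectConfig.from_yaml(project_dir / "config.yaml")
    participants = list(rio.read_participants(project_dir / "participants.tsv"))
    if subjects:
        unknown = set(subjects) - set(participants)
        if unknown:
            raise ProjectError(f"unknown subjects requested: {sorted(unknown)}")
        participants = [p for p in participants if p in set(subjects)]
    if k_values:
        config.clustering.k_range = [k for k in config.clustering.k_range
                                     if k in set(k_values)]
    state = ProjectState.load(project_dir)
    roi, target = _stage_masks(config, state)
    _stage_connectivity(config, state, participants, roi, target, jobs)
    _stage_clustering(config, state, participants, jobs)
    if len(participants) >= 2:
        _stage_group(config, state, participants, roi, jobs)
        _stage_validity(config, state, participants, roi, jobs)
    else:
        logger.info("single subject: group and similarity stages skipped")
    return state
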