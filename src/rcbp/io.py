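"""Readers and writers for every on-disk format the workflow touches.

Volumes are NIfTI-1 via nibabel; tables (participants, confounds, statistics)
are tab-separated text; dense interim arrays are NumPy ``.npy`` containers;
tractography-style sparse connectivity is a coordinate-list text format with
1-based indices (row, column, value per line).
"""
from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (BinarityError, BoldSeries, ConfoundTable,
                    ConnectivityMatrix, MaskVolume, ParticipantTable,
                    SpaceReport, TemplateSpace)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# masks and volumes

def read_mask(path: str | Path) -> MaskVolume:
    """Load a 3D binary NIfTI mask.

    Values must already be binary ({0, 1}); anything else raises
    :class:`BinarityError` rather than being silently thresholded, because a
    non-binary ROI usually signals an upstream mistake (probability map,
    unthresholded atlas) that the user should resolve explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim}D data")
    return MaskVolume(data=data, affine=img.affine)


def write_mask(mask: MaskVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))
    return path


def validate_space(mask: MaskVolume, space: TemplateSpace | None = None,
                   tol_mm: float = 1e-3) -> SpaceReport:
    """Check a mask's grid against a template space (default: 2 mm group grid).

    Reports, rather than raises: shape, voxel size and origin are each
    compared (sizes and origin within ``tol_mm`` millimetres).
    """
    space = space or TemplateSpace.default()
    msgs: list[str] = []
    shape_ok = tuple(mask.shape) == tuple(space.shape)
    if not shape_ok:
        msgs.append(f"shape {mask.shape} != expected {tuple(space.shape)}")
    vox = mask.voxel_size_mm()
    voxel_ok = bool(np.all(np.abs(vox - np.asarray(space.voxel_size_mm)) <= tol_mm))
    if not voxel_ok:
        msgs.append(f"voxel size {tuple(np.round(vox, 4))} != expected {space.voxel_size_mm}")
    origin = mask.affine[:3, 3]
    origin_ok = bool(np.all(np.abs(origin - np.asarray(space.origin_mm)) <= tol_mm))
    if not origin_ok:
        msgs.append(f"origin {tuple(origin)} != expected {space.origin_mm}")
    return SpaceReport(shape_ok=shape_ok, voxel_size_ok=voxel_ok,
                       origin_ok=origin_ok, messages=tuple(msgs))


def read_bold(path: str | Path, tr_seconds: float | None = None) -> BoldSeries:
    """Load a 4D BOLD NIfTI; TR is taken from the header unless overridden."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D time series, got {data.ndim}D")
    if tr_seconds is None:
        tr_seconds = float(img.header.get_zooms()[3])
    return BoldSeries(data=data, affine=img.affine, tr_seconds=tr_seconds)


def write_bold(series: BoldSeries, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = series.tr_seconds
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return path


def write_labels_nifti(labels: np.ndarray, mask: MaskVolume,
                       path: str | Path) -> Path:
    """Map a per-ROI-voxel label vector back onto the mask grid and save it."""
    labels = np.asarray(labels)
    idx = mask.voxel_index()
    if len(labels) != len(idx):
        raise ValueError("label count does not match mask voxel count")
    vol = np.zeros(mask.shape, dtype=np.int16)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = labels
    nib.save(nib.Nifti1Image(vol, mask.affine), str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# tables

def read_participants(path: str | Path) -> ParticipantTable:
    """Parse the participants TSV; requires a ``participant_id`` column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "participant_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'participant_id'")
    ids = df["participant_id"].dropna().tolist()
    if not ids:
        raise ValueError(f"{path}: no participants listed")
    return ParticipantTable(participant_ids=tuple(ids))


def read_confounds(path: str | Path, usecols: list[str] | None = None) -> ConfoundTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if usecols is not None:
        missing = [c for c in usecols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing confound columns {missing}")
        df = df[usecols]
    return ConfoundTable(column_names=list(df.columns), values=df.to_numpy(float))


def write_confounds(table: ConfoundTable, path: str | Path) -> Path:
    pd.DataFrame(table.values, columns=table.column_names).to_csv(
        path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# connectivity matrices

def read_sparse_connectivity(path: str | Path, n_rows: int,
                             n_cols: int) -> ConnectivityMatrix:
    """Densify a coordinate-list sparse matrix (1-based ``row col value`` lines).

    Unlisted cells are zero. The voxel index is filled with placeholder
    coordinates (row number on the i axis) when none is supplied; callers
    normally attach the real index via :func:`attach_voxel_index`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dense = np.zeros((n_rows, n_cols), dtype=float)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'row col value', got {line!r}")
            try:
                r, c = int(parts[0]), int(parts[1])
                v = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}") from exc
            if not (1 <= r <= n_rows and 1 <= c <= n_cols):
                raise ValueError(
                    f"{path}:{lineno}: index ({r},{c}) outside declared "
                    f"bounds {n_rows}x{n_cols} (indices are 1-based)")
            dense[r - 1, c - 1] = v
    placeholder = np.c_[np.arange(n_rows), np.zeros((n_rows, 2), dtype=int)]
    return ConnectivityMatrix(values=dense, voxel_index=placeholder,
                              transform_log=["densified"])


def write_sparse_connectivity(values: np.ndarray, path: str | Path) -> Path:
    """Write nonzero cells as 1-based ``row col value`` lines."""
    values = np.atleast_2d(np.asarray(values))
    path = Path(path)
    with open(path, "w") as fh:
        for r, c in zip(*np.nonzero(values)):
            v = values[r, c]
            v_repr = int(v) if float(v).is_integer() else repr(float(v))
            fh.write(f"{r + 1} {c + 1} {v_repr}\n")
    return path


def attach_voxel_index(matrix: ConnectivityMatrix,
                       voxel_index: np.ndarray) -> ConnectivityMatrix:
    """Replace the placeholder voxel index with real ROI coordinates."""
    return ConnectivityMatrix(values=matrix.values, voxel_index=voxel_index,
                              transform_log=list(matrix.transform_log))


def save_matrix(matrix: ConnectivityMatrix, path: str | Path) -> Path:
    """Persist a dense connectivity matrix (.npy) with sidecar index and log."""
    path = Path(path)
    np.save(path, matrix.values)
    base = path.with_suffix("") if path.suffix == ".npy" else path
    np.save(base.parent / (base.name + "_voxel_index.npy"), matrix.voxel_index)
    (base.parent / (base.name + "_transforms.txt")).write_text(
        "\n".join(matrix.transform_log) + ("\n" if matrix.transform_log else ""))
    return path


def load_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    values = np.load(path)
    base = path.with_suffix("") if path.suffix == ".npy" else path
    idx_path = base.parent / (base.name + "_voxel_index.npy")
    log_path = base.parent / (base.name + "_transforms.txt")
    if idx_path.exists():
        voxel_index = np.load(idx_path)
    else:
        voxel_index = np.c_[np.arange(values.shape[0]),
                            np.zeros((values.shape[0], 2), dtype=int)]
    log = [l for l in log_path.read_text().splitlines() if l] if log_path.exists() else []
    return ConnectivityMatrix(values=values, voxel_index=voxel_index, transform_log=log)


def read_dense_connectivity(path: str | Path,
                            voxel_index_path: str | Path | None = None) -> ConnectivityMatrix:
    """Load a user-supplied dense matrix (.npy) plus its voxel-coordinate array."""
    values = np.load(Path(path))
    if voxel_index_path is not None:
        voxel_index = np.load(Path(voxel_index_path))
    else:
        voxel_index = np.c_[np.arange(values.shape[0]),
                            np.zeros((values.shape[0], 2), dtype=int)]
    return ConnectivityMatrix(values=values, voxel_index=voxel_index)
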