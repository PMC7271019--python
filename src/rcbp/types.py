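"""Core in-memory data model for the parcellation workflow.

The types here mirror what travels between workflow stages: binary masks
with an affine, 4D BOLD series with a repetition time, dense ROI-by-target
connectivity matrices with an ordered voxel index, and the participants
roster. Invariants are enforced at construction so downstream stages can
assume them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class BinarityError(ValueError):
    """A volume expected to be a binary mask contains values outside {0, 1}."""


@dataclass
class MaskVolume:
    """A binary 3D voxel grid with a voxel-to-world (RAS, mm) affine.

    Parameters
    ----------
    data : ndarray of shape (i, j, k)
        Binary occupancy per voxel; stored as uint8 in {0, 1}.
    affine : ndarray of shape (4, 4)
        Invertible voxel-index -> mm transform.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask must be 3D, got {data.ndim}D")
        if any(s <= 0 for s in data.shape):
            raise ValueError(f"mask shape must be strictly positive, got {data.shape}")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise BinarityError(
                f"mask is not binary: found values {uniq[~np.isin(uniq, (0, 1))][:5]}"
            )
        self.data = data.astype(np.uint8)
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        self.affine = affine

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.data.sum())

    def voxel_index(self) -> np.ndarray:
        """Ordered (C-order) integer (i, j, k) coordinates of in-mask voxels."""
        return np.argwhere(self.data > 0)

    def voxel_size_mm(self) -> np.ndarray:
        """Column norms of the affine's linear part (mm per voxel step)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world mm coordinates."""
        ijk = np.atleast_2d(ijk)
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ hom.T).T[:, :3]


@dataclass(frozen=True)
class TemplateSpace:
    """A named voxel grid: shape, isotropy and world origin.

    The default instance is the 2 mm isotropic adult group template grid
    (91 x 109 x 91 voxels, origin at x=90, y=-126, z=-72 mm) that whole-brain
    gray-matter targets conventionally live in.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    @classmethod
    def default(cls) -> "TemplateSpace":
        return cls(shape=(91, 109, 91), voxel_size_mm=(2.0, 2.0, 2.0),
                   origin_mm=(90.0, -126.0, -72.0))

    @classmethod
    def from_mask(cls, mask: MaskVolume) -> "TemplateSpace":
        return cls(shape=mask.shape,
                   voxel_size_mm=tuple(mask.voxel_size_mm()),
                   origin_mm=tuple(mask.affine[:3, 3]))

    def affine(self) -> np.ndarray:
        """Canonical affine: -x voxel step (radiological-to-RAS flip on i)."""
        a = np.eye(4)
        a[0, 0] = -self.voxel_size_mm[0]
        a[1, 1] = self.voxel_size_mm[1]
        a[2, 2] = self.voxel_size_mm[2]
        a[:3, 3] = self.origin_mm
        return a


@dataclass(frozen=True)
class SpaceReport:
    """Result of checking a mask against a template space (report, not error)."""

    shape_ok: bool
    voxel_size_ok: bool
    origin_ok: bool
    messages: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return self.shape_ok and self.voxel_size_ok and self.origin_ok


@dataclass
class BoldSeries:
    """A 4D BOLD time-series grid with repetition time in seconds."""

    data: np.ndarray  # (i, j, k, t)
    affine: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"BOLD series must be 4D, got {data.ndim}D")
        if data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 timepoints")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.data = data
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])  # type: ignore[return-value]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class ConfoundTable:
    """Per-timepoint nuisance regressors (timepoints x confounds)."""

    column_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.shape[1] != len(self.column_names):
            raise ValueError("confound column count does not match column_names")
        self.values = values


@dataclass
class ConnectivityMatrix:
    """ROI-voxel by target-feature connectivity with an ordered voxel index.

    ``voxel_index`` carries the 0-based (i, j, k) grid coordinate of each row,
    in row order, so labels can be mapped back onto the ROI mask.
    ``transform_log`` records every transform applied, in order.
    """

    values: np.ndarray
    voxel_index: np.ndarray
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        voxel_index = np.asarray(self.voxel_index, dtype=int)
        if voxel_index.ndim != 2 or voxel_index.shape[1] != 3:
            raise ValueError("voxel_index must be an (n, 3) integer array")
        if values.shape[0] != voxel_index.shape[0]:
            raise ValueError(
                f"row count {values.shape[0]} != voxel_index length {voxel_index.shape[0]}"
            )
        if len(np.unique(voxel_index, axis=0)) != len(voxel_index):
            raise ValueError("voxel_index entries must be unique")
        self.values = values
        self.voxel_index = voxel_index

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, log_entry: str) -> "ConnectivityMatrix":
        """Copy with new values and an appended transform-log entry."""
        return ConnectivityMatrix(values=values,
                                  voxel_index=self.voxel_index.copy(),
                                  transform_log=[*self.transform_log, log_entry])


@dataclass(frozen=True)
class ParticipantTable:
    """Ordered roster of unique subject identifiers."""

    participant_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.participant_ids) == 0:
            raise ValueError("participants table is empty")
        seen: set[str] = set()
        for pid in self.participant_ids:
            if pid in seen:
                raise ValueError(f"duplicate participant_id: {pid!r}")
            seen.add(pid)

    def __len__(self) -> int:
        return len(self.participant_ids)

    def __iter__(self):
        return iter(self.participant_ids)
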