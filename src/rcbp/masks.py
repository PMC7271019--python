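"""ROI and target mask preprocessing.

All operations take and return :class:`~rcbp.types.MaskVolume` and are
optional steps before connectivity computation: median filtering to clean
stray voxels, target subsampling under spatial smoothness, ROI (+ border)
removal from the target, equidistant ROI upsampling for high-resolution
tractography seeds, and majority-rule target downsampling.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import MaskVolume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UpsampleMapping:
    """Bijection between original and upsampled ROI voxel coordinates."""

    source_index: np.ndarray      # (n, 3) coordinates in the original grid
    upsampled_index: np.ndarray   # (n, 3) coordinates in the upsampled grid
    factor: int

    def __post_init__(self) -> None:
        if len(self.source_index) != len(self.upsampled_index):
            raise ValueError("mapping index lists must have equal length")


def median_filter_mask(mask: MaskVolume) -> MaskVolume:
    """Median-filter a binary mask over the 3x3x3 neighborhood (zero-padded).

    Each voxel becomes the median of its 27-cell neighborhood: stray voxels
    with too few neighbors are removed, holes with many neighbors filled.
    """
    if mask.n_voxels == 0:
        logger.warning("median_filter_mask: mask is empty, returned unchanged")
        return MaskVolume(data=mask.data.copy(), affine=mask.affine.copy())
    filtered = ndimage.median_filter(mask.data, size=3, mode="constant", cval=0)
    return MaskVolume(data=filtered, affine=mask.affine.copy())


def subsample_target(target: MaskVolume) -> MaskVolume:
    """Keep only every second voxel per dimension (all-even index voxels).

    Under the spatial-smoothness assumption of smoothed BOLD data, adjacent
    voxels carry near-identical signal; dropping odd-index voxels cuts the
    feature count roughly 8-fold at little information cost. Grid and affine
    are unchanged (the survivors stay at their original coordinates).
    """
    keep = np.zeros_like(target.data)
    keep[::2, ::2, ::2] = target.data[::2, ::2, ::2]
    return MaskVolume(data=keep, affine=target.affine.copy())


def remove_roi_from_target(target: MaskVolume, roi: MaskVolume,
                           border_mm: float = 0.0) -> MaskVolume:
    """Remove ROI voxels (plus an optional mm border) from the target mask.

    Within-ROI connectivity is typically high through sheer proximity and can
    dominate the clustering; removing the ROI — and, with ``border_mm`` > 0,
    every target voxel within that Euclidean distance of the ROI — excludes
    it from the connectivity features.
    """
    if border_mm < 0:
        raise ValueError("border_mm must be >= 0")
    if target.shape != roi.shape or not np.allclose(target.affine, roi.affine):
        raise ValueError("target and ROI masks must share grid and affine")
    out = target.data.astype(bool) & ~roi.data.astype(bool)
    if border_mm > 0 and roi.n_voxels > 0:
        # distance (mm) from each voxel to the nearest ROI voxel
        sampling = roi.voxel_size_mm()
        dist = ndimage.distance_transform_edt(~roi.data.astype(bool),
                                              sampling=sampling)
        out &= dist > border_mm
    return MaskVolume(data=out.astype(np.uint8), affine=target.affine.copy())


def upsample_roi(roi: MaskVolume, factor: int) -> tuple[MaskVolume, UpsampleMapping]:
    """Spread ROI voxels equidistantly over a finer grid, count preserved.

    Each source voxel (i, j, k) maps to (f*i, f*j, f*k) on a grid with
    voxel size divided by ``factor``, so every voxel keeps its world
    position, no two voxels are 26-connected neighbors (f >= 2), and the
    returned mapping takes results back onto the original mask.
    """
    if factor < 2:
        raise ValueError("upsample factor must be >= 2")
    src = roi.voxel_index()
    up = src * factor
    shape = tuple(int((d - 1) * factor + 1) for d in roi.shape)
    data = np.zeros(shape, dtype=np.uint8)
    data[up[:, 0], up[:, 1], up[:, 2]] = 1
    affine = roi.affine.copy()
    affine[:3, :3] = affine[:3, :3] / factor
    mapping = UpsampleMapping(source_index=src, upsampled_index=up, factor=factor)
    return MaskVolume(data=data, affine=affine), mapping


def map_back(mapping: UpsampleMapping, upsampled: MaskVolume,
             original_shape: tuple[int, int, int],
             original_affine: np.ndarray) -> MaskVolume:
    """Invert :func:`upsample_roi`, restoring voxels to the original grid."""
    data = np.zeros(original_shape, dtype=np.uint8)
    up = mapping.upsampled_index
    present = upsampled.data[up[:, 0], up[:, 1], up[:, 2]] > 0
    src = mapping.source_index[present]
    data[src[:, 0], src[:, 1], src[:, 2]] = 1
    return MaskVolume(data=data, affine=np.asarray(original_affine, float))


def downsample_target(target: MaskVolume, factor: int) -> MaskVolume:
    """Aggregate f^3 blocks into single voxels by majority occupancy.

    An output voxel is on iff at least half of the in-grid cells of its
    block are on; output dimensions are ceil(d / f), voxel size multiplied
    by f (fewer, larger voxels over the same space).
    """
    if factor < 2:
        raise ValueError("downsample factor must be >= 2")
    d = target.data
    out_shape = tuple(-(-s // factor) for s in d.shape)
    pad = [(0, o * factor - s) for s, o in zip(d.shape, out_shape)]
    padded = np.pad(d, pad, mode="constant")
    valid = np.pad(np.ones_like(d), pad, mode="constant")
    blocks = padded.reshape(out_shape[0], factor, out_shape[1], factor,
                            out_shape[2], factor)
    counts = blocks.sum(axis=(1, 3, 5))
    in_grid = valid.reshape(out_shape[0], factor, out_shape[1], factor,
                            out_shape[2], factor).sum(axis=(1, 3, 5))
    out = (counts * 2 >= in_grid) & (in_grid > 0)
    affine = target.affine.copy()
    affine[:3, :3] = affine[:3, :3] * factor
    return MaskVolume(data=out.astype(np.uint8), affine=affine)
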