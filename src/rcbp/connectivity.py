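"""Per-subject connectivity computation.

The resting-state path runs smooth -> nuisance regression -> band-pass ->
voxelwise Pearson correlation (optionally Fisher-Z transformed, optionally
PCA-reduced). The diffusion path starts from an already-densified streamline
count matrix and applies the signed cube-root transform. Every transform is
recorded in the matrix's transform log.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from sklearn.decomposition import PCA

from .types import BoldSeries, ConfoundTable, ConnectivityMatrix, MaskVolume

logger = logging.getLogger(__name__)

# FWHM = sigma * 2*sqrt(2*ln 2) for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BandpassSpec:
    """Pass band in Hz; must sit strictly inside (0, Nyquist)."""

    low_hz: float
    high_hz: float

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0 < self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"band [{self.low_hz}, {self.high_hz}] Hz infeasible for "
                f"TR={tr_seconds}s (Nyquist {nyquist:.4g} Hz)")


@dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian smoothing kernel width as FWHM in mm; 0 disables smoothing."""

    fwhm_mm: float

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")


def smooth_bold(series: BoldSeries, spec: SmoothingSpec) -> BoldSeries:
    """Smooth each timepoint volume with a 3D Gaussian of the given FWHM.

    Sigma per axis is fwhm/(2*sqrt(2 ln 2)) divided by the voxel size from
    the affine. fwhm 0 returns the input unchanged.
    """
    if spec.fwhm_mm == 0:
        return series
    voxel_mm = series.voxel_size_mm()
    sigma_vox = (spec.fwhm_mm * FWHM_TO_SIGMA) / voxel_mm
    out = np.empty_like(series.data)
    for t in range(series.n_timepoints):
        ndimage.gaussian_filter(series.data[..., t], sigma=sigma_vox,
                                output=out[..., t], mode="nearest")
    return BoldSeries(data=out, affine=series.affine.copy(),
                      tr_seconds=series.tr_seconds)


def expand_motion_confounds(table: ConfoundTable) -> ConfoundTable:
    """Expand confound columns to the 24-parameter set.

    For each column x adds its temporal derivative dx (backward difference,
    first row zero), x^2 and dx^2 — turning 6 motion parameters into 24
    regressors. Provided as an explicitly logged convenience.
    """
    values, names = [table.values], list(table.column_names)
    deriv = np.diff(table.values, axis=0, prepend=table.values[:1])
    values += [deriv, table.values ** 2, deriv ** 2]
    for suffix in ("_derivative1", "_power2", "_derivative1_power2"):
        names += [c + suffix for c in table.column_names]
    logger.info("expanded %d confound columns to %d (derivatives and squares)",
                len(table.column_names), len(names))
    return ConfoundTable(column_names=names, values=np.hstack(values))


def regress_nuisance(series: BoldSeries, confounds: ConfoundTable) -> BoldSeries:
    """Replace every voxel series by its OLS residual against the confounds.

    An intercept column is always included, so the output is mean-centered
    in time. Rank-deficient designs fall back to the least-norm solution
    with a warning.
    """
    n_t = series.n_timepoints
    if confounds.values.shape[0] != n_t:
        raise ValueError(
            f"confound rows ({confounds.values.shape[0]}) != timepoints ({n_t})")
    design = np.column_stack([np.ones(n_t), confounds.values])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("confound design is rank-deficient; using least-norm fit")
    flat = series.data.reshape(-1, n_t).T            # time x voxels
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    out = resid.T.reshape(series.data.shape)
    return BoldSeries(data=out, affine=series.affine.copy(),
                      tr_seconds=series.tr_seconds)


def bandpass(series: BoldSeries, spec: BandpassSpec, order: int = 3) -> BoldSeries:
    """Zero-phase Butterworth band-pass along the time axis.

    A forward-backward (filtfilt) 3rd-order Butterworth keeps mid-band
    sinusoids within a few percent of unit gain and introduces no phase
    shift, so correlations downstream are unaffected by filter delay.
    """
    spec.validate(series.tr_seconds)
    fs = 1.0 / series.tr_seconds
    sos = signal.butter(order, [spec.low_hz, spec.high_hz], btype="bandpass",
                        fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, series.data, axis=-1)
    return BoldSeries(data=out, affine=series.affine.copy(),
                      tr_seconds=series.tr_seconds)


def extract_series(series: BoldSeries, mask: MaskVolume) -> np.ndarray:
    """Pull per-voxel time series (n_voxels x n_timepoints) in voxel_index order."""
    if series.shape != mask.shape:
        raise ValueError("series and mask grids differ")
    idx = mask.voxel_index()
    return series.data[idx[:, 0], idx[:, 1], idx[:, 2], :]


def compute_fc(roi_series: np.ndarray, target_series: np.ndarray,
               voxel_index: np.ndarray) -> ConnectivityMatrix:
    """Pearson correlation of every ROI voxel series with every target series.

    Zero-variance series produce r = 0 (with a warning) rather than NaN so
    clustering never encounters missing values.
    """
    roi_series = np.atleast_2d(np.asarray(roi_series, float))
    target_series = np.atleast_2d(np.asarray(target_series, float))
    if roi_series.shape[1] != target_series.shape[1]:
        raise ValueError("ROI and target series must have equal timepoint counts")
    if roi_series.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for correlation")

    def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xc = x - x.mean(axis=1, keepdims=True)
        sd = xc.std(axis=1)
        flat = sd == 0
        sd[flat] = 1.0
        return xc / sd[:, None], flat

    rz, roi_flat = _standardize(roi_series)
    tz, tgt_flat = _standardize(target_series)
    if roi_flat.any() or tgt_flat.any():
        logger.warning("zero-variance series: %d ROI, %d target voxels; "
                       "their correlations are set to 0",
                       int(roi_flat.sum()), int(tgt_flat.sum()))
    r = (rz @ tz.T) / roi_series.shape[1]
    r[roi_flat, :] = 0.0
    r[:, tgt_flat] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return ConnectivityMatrix(values=r, voxel_index=voxel_index,
                              transform_log=["pearson_correlation"])


def fisher_z(matrix: ConnectivityMatrix, clip: float = 1e-15) -> ConnectivityMatrix:
    """Variance-stabilizing artanh of correlations, |r| clipped below 1.

    Values must lie in [-1, 1]; +/-1 are clipped to 1 - ``clip`` so the
    output stays finite.
    """
    v = matrix.values
    if np.any(np.abs(v) > 1):
        raise ValueError("fisher_z input must lie in [-1, 1]")
    clipped = np.clip(v, -1 + clip, 1 - clip)
    return matrix.with_values(np.arctanh(clipped), "fisher_z")


def cubic_transform(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Signed cube root, sign(x)*|x|^(1/3) — variance stabilization for
    streamline counts."""
    v = matrix.values
    return matrix.with_values(np.sign(v) * np.abs(v) ** (1.0 / 3.0), "cubic")


def pca_reduce(matrix: ConnectivityMatrix,
               components: int | float) -> ConnectivityMatrix:
    """Project rows onto leading principal components (fitted per subject).

    ``components`` is either an explicit count or a variance fraction in
    (0, 1); explained-variance ratios are logged.
    """
    n, p = matrix.values.shape
    if isinstance(components, float):
        if not (0 < components < 1):
            raise ValueError("variance fraction must lie in (0, 1)")
        n_comp: int | float = components
    else:
        if not (1 <= components <= min(n, p)):
            raise ValueError(
                f"component count {components} infeasible for {n}x{p} matrix")
        n_comp = components
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(matrix.values)
    logger.info("PCA kept %d components, explained variance %s",
                pca.n_components_, np.round(pca.explained_variance_ratio_, 4))
    return matrix.with_values(scores, f"pca({pca.n_components_})")


def rsfmri_connectivity(series: BoldSeries, roi: MaskVolume, target: MaskVolume,
                        smoothing: SmoothingSpec | None = None,
                        confounds: ConfoundTable | None = None,
                        band: BandpassSpec | None = None,
                        apply_fisher_z: bool = True,
                        pca: int | float | None = None) -> ConnectivityMatrix:
    """Full resting-state pipeline in the canonical order:
    smooth -> regress -> band-pass -> correlate -> Fisher-Z -> PCA."""
    log: list[str] = []
    if smoothing is not None and smoothing.fwhm_mm > 0:
        series = smooth_bold(series, smoothing)
        log.append(f"smooth({smoothing.fwhm_mm}mm)")
    if confounds is not None:
        series = regress_nuisance(series, confounds)
        log.append("nuisance_regression")
    if band is not None:
        series = bandpass(series, band)
        log.append(f"bandpass({band.low_hz}-{band.high_hz}Hz)")
    matrix = compute_fc(extract_series(series, roi),
                        extract_series(series, target),
                        roi.voxel_index())
    matrix.transform_log = log + matrix.transform_log
    if apply_fisher_z:
        matrix = fisher_z(matrix)
    if pca is not None:
        matrix = pca_reduce(matrix, pca)
    return matrix
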