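"""Nuisance regression, temporal filtering, and ROI extraction.

The conditioning chain mirrors standard event-locked BOLD practice: drop
the first volumes of each run (T1 equilibration), two-stage nuisance
regression (stage 1: intercept + linear/quadratic trends + six motion
parameters per run; stage 2: five noise components estimated by PCA of
white-matter/ventricle voxel signals, the CompCor approach), then zero-
phase low-pass filtering at 0.1 Hz.  All steps operate per run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .regions import RegionTable
from .series import RoiSeries

__all__ = [
    "ConfoundSet",
    "drop_initial_volumes",
    "compcor_components",
    "two_stage_nuisance_regression",
    "lowpass_filter",
    "extract_roi_series",
]

log = logging.getLogger(__name__)


@dataclass
class ConfoundSet:
    """Nuisance regressors aligned with a (possibly trimmed) series.

    motion: (T, 6) translations (mm) and rotations (rad), or None.
    noise_roi_series: (T, V) voxel series from noise masks, or None.
    """

    motion: np.ndarray | None = None
    noise_roi_series: np.ndarray | None = None
    trend_order: int = 2
    n_compcor: int = 5

    def validate_against(self, series: RoiSeries) -> None:
        for name, arr in (("motion", self.motion),
                          ("noise_roi_series", self.noise_roi_series)):
            if arr is not None and arr.shape[0] != series.n_volumes:
                raise ValueError(
                    f"{name} has {arr.shape[0]} rows for a series of "
                    f"{series.n_volumes} volumes"
                )


def drop_initial_volumes(series: RoiSeries, n: int = 3) -> RoiSeries:
    """Remove the first ``n`` volumes of each run and re-index runs.

    Event-onset re-indexing is the caller's contract
    (:func:`dynconn.events.shift_after_initial_drop`).
    """
    if n == 0:
        return series.with_values(series.values.copy())
    keep = []
    new_bounds = []
    cursor = 0
    for start, stop in series.run_boundaries:
        if stop - start <= n:
            raise ValueError(
                f"run [{start}, {stop}) has {stop - start} volumes, "
                f"cannot drop {n}"
            )
        keep.append(np.arange(start + n, stop))
        new_bounds.append((cursor, cursor + (stop - start - n)))
        cursor += stop - start - n
    idx = np.concatenate(keep)
    return RoiSeries(
        values=series.values[idx],
        tr_seconds=series.tr_seconds,
        run_boundaries=new_bounds,
        region_ids=list(series.region_ids),
        subject_id=series.subject_id,
    )


def compcor_components(
    noise_roi_series: np.ndarray, n_components: int = 5
) -> np.ndarray:
    """Top principal-component scores of the column-standardized noise
    matrix, scaled to unit (population) variance.

    Constant voxel columns are dropped before standardization; the sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    X = np.asarray(noise_roi_series, dtype=float)
    if X.ndim != 2:
        raise ValueError("noise matrix must be 2-D (volumes x voxels)")
    T = X.shape[0]
    sd = X.std(axis=0)
    keep = sd > 0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        log.warning("dropped %d constant noise voxels", n_dropped)
    X = X[:, keep]
    if X.shape[1] < n_components or T < n_components:
        raise ValueError(
            f"need at least {n_components} non-constant voxels and volumes, "
            f"have {X.shape[1]} voxels, {T} volumes"
        )
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :n_components] * np.sqrt(T)
    # deterministic sign: largest-|loading| voxel loads positively
    for j in range(n_components):
        v = Vt[j]
        if v[np.argmax(np.abs(v))] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def _trend_design(n: int, order: int) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, n)
    return np.column_stack([t**k for k in range(order + 1)])


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of Y on X (least-norm solution if rank deficient)."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        log.warning("collinear nuisance design (rank %d < %d); "
                    "least-norm solution used",
                    np.linalg.matrix_rank(X), X.shape[1])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def two_stage_nuisance_regression(
    series: RoiSeries,
    confounds: ConfoundSet | None = None,
    stage1: bool = True,
    stage2: bool = True,
) -> RoiSeries:
    """Two-step nuisance regression, per run.

    Stage 1 regresses out an intercept, linear and quadratic trends, and
    the six motion parameters (when provided).  Stage 2 regresses out the
    noise-PCA components (when noise voxels are provided).  Residuals are
    exactly orthogonal to every regressor.
    """
    confounds = confounds or ConfoundSet()
    confounds.validate_against(series)
    out = series.values.copy()
    for start, stop in series.run_boundaries:
        Y = out[start:stop]
        x1 = None
        if stage1:
            cols = [_trend_design(stop - start, confounds.trend_order)]
            if confounds.motion is not None:
                cols.append(confounds.motion[start:stop])
            x1 = np.column_stack(cols)
            Y = _residualize(Y, x1)
        if stage2 and confounds.noise_roi_series is not None:
            comps = compcor_components(
                confounds.noise_roi_series[start:stop], confounds.n_compcor
            )
            # stage-1 columns ride along so the final residuals stay
            # orthogonal to every regressor of both stages
            cols2 = [np.ones((stop - start, 1)), comps]
            if x1 is not None:
                cols2.append(x1)
            Y = _residualize(Y, np.column_stack(cols2))
        out[start:stop] = Y
    return series.with_values(out)


def lowpass_filter(series: RoiSeries, cutoff_hz: float = 0.1) -> RoiSeries:
    """Zero-phase 4th-order Butterworth low-pass, per run per region."""
    fs = 1.0 / series.tr_seconds
    if cutoff_hz >= fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is not below the Nyquist frequency "
            f"{fs / 2} Hz"
        )
    sos = sps.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    out = series.values.copy()
    for start, stop in series.run_boundaries:
        out[start:stop] = sps.sosfiltfilt(sos, out[start:stop], axis=0)
    return series.with_values(out)


def extract_roi_series(
    bold_img,
    region_table: RegionTable,
    mask_img,
    k: int = 30,
    tr_seconds: float | None = None,
    subject_id: str = "sub-01",
) -> RoiSeries:
    """Mean time course of the ``k`` mask voxels nearest each region peak.

    ``bold_img`` is a 4-D NIfTI image (nibabel), ``mask_img`` a 3-D mask on
    the same grid.  Distances are Euclidean in world (mm) space through the
    NIfTI affine; ties are broken by ascending (x, y, z) voxel index.  If a
    region has fewer than ``k`` eligible voxels, all are used with a
    warning.  A peak falling outside the image grid raises.
    """
    import nibabel  # noqa: F401  (format handled by nibabel)

    data = np.asanyarray(bold_img.dataobj, dtype=float)
    mask = np.asanyarray(mask_img.dataobj) > 0
    if data.shape[:3] != mask.shape:
        raise ValueError(
            f"BOLD grid {data.shape[:3]} and mask grid {mask.shape} differ"
        )
    if not np.allclose(bold_img.affine, mask_img.affine, atol=1e-4):
        raise ValueError("BOLD and mask affines differ")
    affine = bold_img.affine
    inv = np.linalg.inv(affine)
    vox = np.array(np.nonzero(mask)).T  # (V, 3) integer indices
    vox_mm = vox @ affine[:3, :3].T + affine[:3, 3]
    T = data.shape[3]
    cols = np.empty((T, len(region_table)))
    for r in range(len(region_table)):
        peak = region_table.mni_xyz[r]
        peak_vox = inv[:3, :3] @ peak + inv[:3, 3]
        rounded = np.round(peak_vox).astype(int)
        if np.any(rounded < 0) or np.any(rounded >= np.array(mask.shape)):
            raise ValueError(
                f"peak {peak} mm of region {region_table.region_ids[r]} "
                "lies outside the image grid"
            )
        d = np.linalg.norm(vox_mm - peak, axis=1)
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0], d))
        if len(order) < k:
            warnings.warn(
                f"region {region_table.region_ids[r]}: only {len(order)} "
                f"mask voxels available (< {k}); using all"
            )
        chosen = vox[order[:k]]
        cols[:, r] = data[chosen[:, 0], chosen[:, 1], chosen[:, 2], :].mean(axis=0)
    return RoiSeries(
        values=cols,
        tr_seconds=tr_seconds if tr_seconds is not None
        else float(bold_img.header.get_zooms()[3]) or 1.0,
        run_boundaries=[(0, T)],
        region_ids=region_table.region_ids,
        subject_id=subject_id,
    )
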