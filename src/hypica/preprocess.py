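"""BOLD preprocessing: grand-mean scaling, high-pass filtering, smoothing,
masking and multi-subject concatenation.

The temporal high-pass filter is implemented as projection onto a discrete
cosine basis spanning all frequencies below the cutoff, with the temporal
mean re-added — a deterministic, closed-form operation that is idempotent on
the retained subspace.  Spatial smoothing is a per-volume 3D Gaussian with
FWHM given in mm (reflect boundary).  Whole-brain analyses conventionally
use smoothed data; small-ROI analyses use unsmoothed data.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import MaskedMatrix, VolumeSeries

__all__ = [
    "grand_mean_scale",
    "highpass_filter",
    "gaussian_smooth",
    "mask_and_concatenate",
    "dct_basis",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def grand_mean_scale(
    run: VolumeSeries,
    target_mean: float = 10000.0,
    brain_mask: np.ndarray | None = None,
) -> VolumeSeries:
    """Scale a 4D run so its global (4D) mean over in-brain voxels equals
    ``target_mean``.  A single multiplicative factor is applied everywhere.
    """
    data = run.data
    if brain_mask is not None:
        gmean = float(data[brain_mask].mean())
    else:
        gmean = float(data.mean())
    if gmean <= 0:
        raise ValueError(f"global mean must be positive, got {gmean}")
    factor = target_mean / gmean
    return run.copy_with((data * factor).astype(data.dtype, copy=False))


def dct_basis(n: int, n_basis: int) -> np.ndarray:
    """Unit-norm DCT-II basis vectors k = 1..n_basis (no constant term).

    Basis k has frequency k / (2 n TR) cycles per second.
    """
    t = np.arange(n)
    ks = np.arange(1, n_basis + 1)
    basis = np.cos(np.pi * np.outer(t + 0.5, ks) / n)
    basis *= np.sqrt(2.0 / n)
    return basis


def n_highpass_regressors(n_vols: int, tr_s: float, cutoff_hz: float) -> int:
    """Number of DCT components with frequency strictly below the cutoff."""
    return int(np.floor(2.0 * n_vols * tr_s * cutoff_hz))


def highpass_filter(run: VolumeSeries, cutoff_hz: float = 0.005) -> VolumeSeries:
    """Remove fluctuations slower than ``cutoff_hz`` voxelwise.

    Projects each voxel's series onto the DCT components below the cutoff
    and subtracts them; the temporal mean is preserved.
    """
    nyquist = 1.0 / (2.0 * run.tr_s)
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency "
            f"{nyquist:.4f} Hz"
        )
    n_t = run.n_volumes
    n_k = n_highpass_regressors(n_t, run.tr_s, cutoff_hz)
    if n_k == 0:
        return run.copy_with(run.data.copy())
    basis = dct_basis(n_t, n_k)  # (T, K), orthonormal
    if run.data.dtype == np.float32:
        basis = basis.astype(np.float32)
    flat = run.data.reshape(-1, n_t)
    coefs = flat @ basis  # (V, K)
    out = flat - coefs @ basis.T
    return run.copy_with(
        out.reshape(run.data.shape).astype(run.data.dtype, copy=False)
    )


def gaussian_smooth(run: VolumeSeries, fwhm_mm: float = 5.0) -> VolumeSeries:
    """Volumewise 3D Gaussian smoothing, FWHM in mm, reflect boundary."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_mm = fwhm_mm * _FWHM_TO_SIGMA
    sigma_vox = tuple(sigma_mm / v for v in run.voxel_size_mm)
    out = gaussian_filter(
        run.data, sigma=sigma_vox + (0.0,), mode="reflect"
    ).astype(run.data.dtype, copy=False)
    return run.copy_with(out)


def mask_and_concatenate(
    runs_by_subject: list[list[VolumeSeries]],
    mask: np.ndarray,
    variance_normalize: bool = True,
    demean: bool = True,
) -> MaskedMatrix:
    """Stack masked voxel time series across subjects and runs.

    Rows are stacked subject-major then run-major.  Within each
    (subject, run) block every voxel's series is demeaned, and scaled to
    unit variance when ``variance_normalize`` (zero-variance series are left
    at zero).  The block row ranges are recorded so the stacking is lossless.

    ``demean=False`` skips both per-block operations and stacks the raw
    masked series: the form dual regression consumes, where between-run
    signal levels must survive.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    voxel_index = np.argwhere(mask)
    blocks = []
    bounds = []
    row = 0
    tr_s = None
    for s, runs in enumerate(runs_by_subject):
        for r, run in enumerate(runs):
            if run.grid_shape != mask.shape:
                raise ValueError(
                    f"subject {s} run {r} grid {run.grid_shape} does not "
                    f"match mask grid {mask.shape}"
                )
            tr_s = run.tr_s if tr_s is None else tr_s
            block = run.data[mask].T.astype(
                np.promote_types(run.data.dtype, np.float32)
            )  # (T, V)
            if demean:
                block = block - block.mean(axis=0, keepdims=True)
                if variance_normalize:
                    sd = block.std(axis=0, keepdims=True)
                    sd[sd == 0] = 1.0
                    block = block / sd
            blocks.append(block)
            bounds.append(((s, r), (row, row + block.shape[0])))
            row += block.shape[0]
    if not blocks:
        raise ValueError("no runs provided")
    return MaskedMatrix(
        values=np.vstack(blocks),
        voxel_index=voxel_index,
        block_bounds=bounds,
        grid_shape=tuple(mask.shape),
        tr_s=float(tr_s),
    )
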