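"""NIfTI and CSV I/O helpers (nibabel-backed)."""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import SerumSeries, VolumeSeries

__all__ = [
    "save_volume_series",
    "load_volume_series",
    "save_volume",
    "load_volume",
    "save_serum_csv",
    "load_serum_csv",
]


def save_volume_series(run: VolumeSeries, path: str) -> None:
    """Write a 4D run as NIfTI-1, storing the TR in the time pixdim."""
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float32), run.affine)
    img.header.set_zooms(tuple(run.voxel_size_mm) + (run.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)


def load_volume_series(path: str) -> VolumeSeries:
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4D NIfTI")
    tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ValueError(f"{path} has no valid TR in its header")
    return VolumeSeries(data=data, affine=np.asarray(img.affine), tr_s=tr)


def save_volume(data: np.ndarray, affine: np.ndarray, path: str) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)


def load_volume(path: str) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(path)
    return np.asanyarray(img.dataobj).astype(np.float32), np.asarray(img.affine)


def load_binary_mask(path: str, tol: float = 1e-6) -> np.ndarray:
    """Load a mask NIfTI and check it is binary (values in {0, 1})."""
    data, _ = load_volume(path)
    off = np.minimum(np.abs(data), np.abs(data - 1.0))
    if np.any(off > tol):
        raise ValueError(f"mask {path} is not binary (values outside {{0,1}})")
    return data > 0.5


def save_serum_csv(series: SerumSeries, path: str) -> None:
    pd.DataFrame(
        {
            "time_min": series.times_min,
            "tnf_pg_ml": series.tnf_pg_ml,
            "acth_pg_ml": series.acth_pg_ml,
        }
    ).to_csv(path, index=False)


def load_serum_csv(path: str, sampling_interval_s: float = 30.0) -> SerumSeries:
    if not os.path.exists(path):
        raise FileNotFoundError(f"serum CSV not found: {path}")
    df = pd.read_csv(path)
    for col in ("time_min", "tnf_pg_ml", "acth_pg_ml"):
        if col not in df.columns:
            raise ValueError(f"serum CSV {path} missing column {col!r}")
    return SerumSeries(
        times_min=df["time_min"].to_numpy(),
        tnf_pg_ml=df["tnf_pg_ml"].to_numpy(),
        acth_pg_ml=df["acth_pg_ml"].to_numpy(),
        sampling_interval_s=sampling_interval_s,
    )
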