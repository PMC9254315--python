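"""Core data containers shared across the pipeline stages.

The containers are deliberately thin: plain dataclasses around numpy arrays,
with ``validate()`` methods that enforce the structural invariants each stage
relies on (shared grids, monotone times, partitioning block bounds).  Heavier
derived objects (ICA results, permutation results, reports) live here too so
that every stage exchanges typed objects rather than bare arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VolumeSeries",
    "TissuePhantom",
    "RunSpec",
    "SerumSeries",
    "GroundTruth",
    "MaskedMatrix",
    "ComponentSet",
    "SubjectComponentMaps",
    "SpecificityReport",
    "TfceParams",
    "PermutationResult",
    "SimilarityMatrix",
]

@dataclass
class VolumeSeries:
    """A 4D BOLD acquisition: ``data[x, y, z, t]`` plus geometry and timing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
        Scalar field over space and time, arbitrary BOLD units.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (RAS+) affine; voxel sizes in mm are taken from it.
    tr_s : float
        Repetition time (volume-to-volume spacing) in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"VolumeSeries expects 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("VolumeSeries needs at least 2 volumes")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.data.shape[:3])

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def copy_with(self, data: np.ndarray) -> "VolumeSeries":
        return VolumeSeries(data=data, affine=self.affine.copy(), tr_s=self.tr_s)


@dataclass
class TissuePhantom:
    """ROI mask plus probabilistic GM/WM/CSF maps on a shared grid."""

    voxel_size_mm: tuple[float, float, float]
    roi_mask: np.ndarray
    gm_prob: np.ndarray
    wm_prob: np.ndarray
    csf_prob: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.roi_mask = np.asarray(self.roi_mask).astype(bool)
        for name in ("gm_prob", "wm_prob", "csf_prob"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.affine is None:
            aff = np.eye(4)
            aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
            self.affine = aff
        self.validate()

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.roi_mask.shape)

    @property
    def tissue_total(self) -> np.ndarray:
        return self.gm_prob + self.wm_prob + self.csf_prob

    @property
    def brain_mask(self) -> np.ndarray:
        """Voxels with any tissue content; the whole-brain analysis mask."""
        return self.tissue_total > 0.05

    def validate(self) -> None:
        shp = self.roi_mask.shape
        for name in ("gm_prob", "wm_prob", "csf_prob"):
            arr = getattr(self, name)
            if arr.shape != shp:
                raise ValueError(f"{name} shape {arr.shape} != roi_mask shape {shp}")
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.tissue_total > 1 + 1e-6):
            raise ValueError("gm+wm+csf must be <= 1 at every voxel")
        n_roi = int(self.roi_mask.sum())
        if n_roi < 50:
            raise ValueError(f"ROI mask has {n_roi} voxels; needs >= 50")
        if np.any(self.tissue_total[self.roi_mask] <= 0):
            raise ValueError("ROI mask must lie wholly inside nonzero-tissue voxels")


@dataclass
class RunSpec:
    """Acquisition layout: one baseline run plus post-injection runs.

    Defaults mirror the endotoxemia study design: 450 baseline volumes and
    three 900-volume post-injection runs at TR 1.18 s, starting at −30, 0,
    30 and 80 minutes relative to the endotoxin injection.
    """

    n_volumes: tuple[int, ...] = (450, 900, 900, 900)
    tr_s: float = 1.18
    run_start_min: tuple[float, ...] = (-30.0, 0.0, 30.0, 80.0)

    def __post_init__(self) -> None:
        self.n_volumes = tuple(int(n) for n in self.n_volumes)
        self.run_start_min = tuple(float(t) for t in self.run_start_min)
        if len(self.n_volumes) != len(self.run_start_min):
            raise ValueError("n_volumes and run_start_min must have equal length")
        if len(self.n_volumes) < 2:
            raise ValueError("need a baseline run plus at least one post run")
        if any(n < 2 for n in self.n_volumes):
            raise ValueError("each run needs >= 2 volumes")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        starts = np.asarray(self.run_start_min)
        if np.any(np.diff(starts) <= 0):
            raise ValueError("run starts must be strictly increasing")

    @property
    def n_runs(self) -> int:
        return len(self.n_volumes)

    @property
    def total_volumes(self) -> int:
        return int(sum(self.n_volumes))

    def run_duration_min(self, run: int) -> float:
        return self.n_volumes[run] * self.tr_s / 60.0

    def volume_times_min(self, run: int) -> np.ndarray:
        """Acquisition time (minutes) of each volume centre in a run."""
        t0 = self.run_start_min[run]
        return t0 + (np.arange(self.n_volumes[run]) + 0.5) * self.tr_s / 60.0

    def run_slices(self) -> list[slice]:
        """Row slices of each run in the time-concatenated data."""
        edges = np.cumsum((0,) + self.n_volumes)
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class SerumSeries:
    """Timestamped serum biomarker concentrations (TNF and ACTH, pg/mL)."""

    times_min: np.ndarray
    tnf_pg_ml: np.ndarray
    acth_pg_ml: np.ndarray
    sampling_interval_s: float = 30.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.tnf_pg_ml = np.asarray(self.tnf_pg_ml, dtype=float)
        self.acth_pg_ml = np.asarray(self.acth_pg_ml, dtype=float)
        if not (len(self.times_min) == len(self.tnf_pg_ml) == len(self.acth_pg_ml)):
            raise ValueError("times and concentration arrays must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times_min must be strictly increasing")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")
        if np.any(self.tnf_pg_ml < -1e-9) or np.any(self.acth_pg_ml < -1e-9):
            raise ValueError("concentrations must be nonnegative")

    def marker(self, name: str) -> np.ndarray:
        name = name.lower()
        if name == "tnf":
            return self.tnf_pg_ml
        if name == "acth":
            return self.acth_pg_ml
        raise KeyError(f"unknown marker {name!r}; expected 'tnf' or 'acth'")

    def value_at(self, marker: str, t_min: float) -> float:
        """Linearly interpolated concentration at a given time."""
        return float(np.interp(t_min, self.times_min, self.marker(marker)))


@dataclass
class GroundTruth:
    """Embedded sources of a simulated dataset, with coupling labels.

    ``source_maps`` are nonnegative, unit-peak 3D fields (K of them);
    ``source_timecourses`` are the shared group-level time courses on the
    concatenated volume grid; ``coupling_labels`` name the serum marker each
    source tracks ('tnf', 'acth' or 'none'), ``coupling_sign`` its direction,
    and ``run_amplitudes`` the per-run multiplier of the fast fluctuation
    component (run-modulated sources have non-constant rows).
    """

    source_maps: np.ndarray  # (K, nx, ny, nz)
    source_timecourses: np.ndarray  # (K, T_total)
    coupling_labels: tuple[str, ...]
    coupling_sign: tuple[int, ...]
    coupling_target_r: float
    run_amplitudes: np.ndarray  # (K, n_runs)
    in_wm: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        self.source_maps = np.asarray(self.source_maps, dtype=float)
        self.source_timecourses = np.asarray(self.source_timecourses, dtype=float)
        self.run_amplitudes = np.asarray(self.run_amplitudes, dtype=float)
        k = self.source_maps.shape[0]
        if not self.in_wm:
            self.in_wm = tuple(False for _ in range(k))
        if len(self.coupling_labels) != k or len(self.coupling_sign) != k:
            raise ValueError("labels/signs must match number of sources")
        if np.any(self.source_maps < -1e-9):
            raise ValueError("source maps must be nonnegative")
        peaks = self.source_maps.reshape(k, -1).max(axis=1)
        if np.any(np.abs(peaks - 1.0) > 1e-6):
            raise ValueError("source maps must be unit-peak")

    @property
    def n_sources(self) -> int:
        return int(self.source_maps.shape[0])

    def is_run_modulated(self, k: int) -> bool:
        amps = self.run_amplitudes[k]
        return bool(np.ptp(amps) > 1e-9)


@dataclass
class MaskedMatrix:
    """Time-by-voxel matrix of masked, concatenated multi-subject data.

    ``block_bounds`` maps each (subject, run) pair to its half-open row range;
    the blocks partition the rows exactly, subject-major then run-major.
    """

    values: np.ndarray  # (T_total, V)
    voxel_index: np.ndarray  # (V, 3) integer grid coordinates
    block_bounds: list[tuple[tuple[int, int], tuple[int, int]]]
    grid_shape: tuple[int, int, int]
    tr_s: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)  # dtype preserved (float32 ok)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (time x voxels)")
        if self.voxel_index.shape != (self.values.shape[1], 3):
            raise ValueError("voxel_index must be (V, 3)")
        rows = 0
        for (_subj_run, (a, b)) in self.block_bounds:
            if a != rows or b <= a:
                raise ValueError("block_bounds must partition rows exactly, in order")
            rows = b
        if rows != self.values.shape[0]:
            raise ValueError("block_bounds do not cover all rows")

    @property
    def n_voxels(self) -> int:
        return int(self.values.shape[1])

    @property
    def n_rows(self) -> int:
        return int(self.values.shape[0])

    def block(self, subject: int, run: int) -> np.ndarray:
        for (sr, (a, b)) in self.block_bounds:
            if sr == (subject, run):
                return self.values[a:b]
        raise KeyError(f"no block for subject {subject}, run {run}")

    def unstack(self) -> dict[tuple[int, int], np.ndarray]:
        return {sr: self.values[a:b] for (sr, (a, b)) in self.block_bounds}


@dataclass
class ComponentSet:
    """Spatial ICA result over mask voxels.

    ``maps_z`` are z-scaled spatial maps (d × V, positive-skew orientation,
    ordered by explained variance), ``mixing`` the group-level time courses
    (T_total × d), ``threshold_maps`` the mixture-model thresholded binary
    maps, ``noise_flags`` a per-component exclusion flag populated by the
    specificity stage (or a manual flag file).
    """

    maps_z: np.ndarray
    mixing: np.ndarray
    voxel_index: np.ndarray
    grid_shape: tuple[int, int, int]
    threshold_maps: np.ndarray = field(default=None)  # type: ignore[assignment]
    noise_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged: bool = True
    explained_variance: np.ndarray = field(default=None)  # type: ignore[assignment]
    threshold_fallback: np.ndarray = field(default=None)  # type: ignore[assignment]
    maps_raw: np.ndarray = field(default=None)  # type: ignore[assignment]
    # unit-variance ICA maps before z-scaling; mixing @ maps_raw
    # reconstructs the rank-d reduction of the data exactly

    def __post_init__(self) -> None:
        self.maps_z = np.asarray(self.maps_z, dtype=float)
        self.mixing = np.asarray(self.mixing, dtype=float)
        d = self.maps_z.shape[0]
        if self.mixing.shape[1] != d:
            raise ValueError("mixing columns must match number of maps")
        if self.threshold_maps is None:
            self.threshold_maps = np.zeros_like(self.maps_z, dtype=bool)
        if self.noise_flags is None:
            self.noise_flags = np.zeros(d, dtype=bool)
        if self.threshold_fallback is None:
            self.threshold_fallback = np.zeros(d, dtype=bool)

    @property
    def n_components(self) -> int:
        return int(self.maps_z.shape[0])

    @property
    def n_voxels(self) -> int:
        return int(self.maps_z.shape[1])

    def map_volume(self, k: int) -> np.ndarray:
        """Write component k's map back into a full 3D volume (zeros outside)."""
        vol = np.zeros(self.grid_shape, dtype=float)
        vol[tuple(self.voxel_index.T)] = self.maps_z[k]
        return vol

    def label_volume(self) -> np.ndarray:
        """Winner-take-all labelling of mask voxels (1-based; 0 = outside)."""
        vol = np.zeros(self.grid_shape, dtype=np.int32)
        winners = np.argmax(np.abs(self.maps_z), axis=0) + 1
        vol[tuple(self.voxel_index.T)] = winners
        return vol


@dataclass
class SubjectComponentMaps:
    """Dual-regression output: per-subject (optionally per-run) maps.

    ``timecourses[s]`` is the stage-1 time course matrix (T × d) of subject s
    on the full concatenated rows.  ``beta_maps`` / ``z_maps`` are dicts keyed
    by subject (per_run=False) or (subject, run) (per_run=True), each d × V
    over the target-mask voxels.
    """

    timecourses: dict[int, np.ndarray]
    beta_maps: dict
    z_maps: dict
    target_voxel_index: np.ndarray
    target_grid_shape: tuple[int, int, int]
    per_run: bool = False

    @property
    def n_components(self) -> int:
        first = next(iter(self.beta_maps.values()))
        return int(first.shape[0])

    def group_mean_timecourse(self) -> np.ndarray:
        """Average stage-1 time courses across subjects (T × d)."""
        stacked = np.stack([self.timecourses[s] for s in sorted(self.timecourses)])
        return stacked.mean(axis=0)

    def group_mean_z(self) -> np.ndarray:
        """Average z maps across subjects (and runs, if per_run)."""
        stacked = np.stack([self.z_maps[k] for k in sorted(self.z_maps)])
        return stacked.mean(axis=0)


@dataclass
class SpecificityReport:
    """Tissue-specificity quotients and the 1-SD exclusion decision."""

    quotients: np.ndarray
    mean_q: float
    sd_q: float
    excluded: np.ndarray
    denominator_zero: np.ndarray

    @property
    def cutoff(self) -> float:
        return self.mean_q - self.sd_q

    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.excluded)


@dataclass
class TfceParams:
    """Threshold-free cluster enhancement parameters (standard defaults)."""

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None  # None -> max statistic / 100 per map
    connectivity: int = 26
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class PermutationResult:
    """Permutation-test output with max-statistic FWE-corrected p-values."""

    stat_map: np.ndarray
    tfce_map: np.ndarray
    fwe_p_map: np.ndarray
    n_permutations: int
    seed: int
    exhaustive: bool
    alpha: float | None = None
    threshold_map: np.ndarray | None = None

    @property
    def min_p(self) -> float:
        return float(np.min(self.fwe_p_map))

    def summary(self) -> dict:
        return {
            "n_permutations": int(self.n_permutations),
            "exhaustive": bool(self.exhaustive),
            "max_stat": float(np.max(self.stat_map)),
            "max_tfce": float(np.max(self.tfce_map)),
            "min_fwe_p": self.min_p,
            "seed": int(self.seed),
        }


@dataclass
class SimilarityMatrix:
    """Spatial correlation matrix of maps plus complete-linkage structure."""

    labels: tuple[str, ...]
    r_matrix: np.ndarray
    linkage: np.ndarray | None = None  # scipy linkage matrix
    leaf_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r_matrix = np.asarray(self.r_matrix, dtype=float)
        m = len(self.labels)
        if self.r_matrix.shape != (m, m):
            raise ValueError("r_matrix must be square and match labels")
        if not np.allclose(self.r_matrix, self.r_matrix.T, atol=1e-10):
            raise ValueError("r_matrix must be symmetric")
        if not np.allclose(np.diag(self.r_matrix), 1.0, atol=1e-8):
            raise ValueError("r_matrix must have unit diagonal")

    @property
    def n_maps(self) -> int:
        return len(self.labels)


def as_tuple3(x: Sequence[float]) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError("expected a length-3 sequence")
    return t  # type: ignore[return-value]
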