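"""Phantom anatomy, endotoxemia-like serum kinetics and BOLD simulation.

Every downstream stage of the pipeline is exercised against data from this
module, which embeds a known set of compact sources inside a small ROI of a
tissue phantom and couples a subset of their time courses to simulated serum
TNF / ACTH kinetics.  All generators are pure functions of their parameters
and an integer seed.

The default acquisition layout follows the endotoxemia study design: one
450-volume baseline run and three 900-volume post-injection runs at
TR = 1.18 s, starting at −30, 0, 30 and 80 minutes relative to injection.
Serum is sampled every 30 s during the post-injection runs, every 10 min in
the gaps, and sparsely afterwards out to 240 min.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.optimize import brentq

from .containers import (
    GroundTruth,
    RunSpec,
    SerumSeries,
    TissuePhantom,
    VolumeSeries,
)
from . import io as hio

__all__ = [
    "SerumKinetics",
    "MarkerPulse",
    "make_phantom_anatomy",
    "default_serum_times",
    "simulate_serum_curves",
    "simulate_cohort_serum",
    "default_source_layout",
    "build_ground_truth",
    "simulate_subject_bold",
    "simulate_dataset",
    "write_dataset",
    "SyntheticDataset",
]


# --------------------------------------------------------------------------
# Serum kinetics
# --------------------------------------------------------------------------

@dataclass
class MarkerPulse:
    """Gamma-density pulse for one serum marker.

    The pulse is ``a * x**k * exp(k * (1 - x))`` with
    ``x = (t - onset) / (peak - onset) * k_scale`` parameterised so the
    maximum (value ``amplitude``) sits exactly at ``peak_min`` and the curve
    is identically zero up to ``onset_min``.  ``shape`` (k) controls the
    width; larger k gives a broader normalised rise but a faster relative
    decay, which is what brings the delayed ACTH pulse back near baseline by
    240 min.
    """

    onset_min: float
    peak_min: float
    amplitude: float
    shape: float = 3.0

    def __post_init__(self) -> None:
        if self.onset_min >= self.peak_min:
            raise ValueError("onset must precede peak")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.shape <= 0:
            raise ValueError("shape must be positive")

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        x = (t - self.onset_min) / (self.peak_min - self.onset_min)
        out = np.zeros_like(x)
        pos = x > 0
        k = self.shape
        out[pos] = self.amplitude * x[pos] ** k * np.exp(k * (1.0 - x[pos]))
        return out


@dataclass
class SerumKinetics:
    """TNF and ACTH pulse parameters.

    Defaults emulate the observed endotoxemia kinetics: TNF near zero at
    baseline, rising after 20–30 min and peaking at 60–70 min; ACTH delayed
    by ~25 min, peaking between 100 and 180 min and back near baseline at
    240 min.
    """

    tnf: MarkerPulse = field(
        default_factory=lambda: MarkerPulse(onset_min=25.0, peak_min=65.0,
                                            amplitude=250.0, shape=3.0)
    )
    acth: MarkerPulse = field(
        default_factory=lambda: MarkerPulse(onset_min=50.0, peak_min=130.0,
                                            amplitude=55.0, shape=6.0)
    )

    def pulse(self, marker: str) -> MarkerPulse:
        marker = marker.lower()
        if marker == "tnf":
            return self.tnf
        if marker == "acth":
            return self.acth
        raise KeyError(f"unknown marker {marker!r}")

    @property
    def acth_delay_min(self) -> float:
        return self.acth.onset_min - self.tnf.onset_min


def default_serum_times(
    run_spec: RunSpec | None = None,
    interval_s: float = 30.0,
    block_multiple: int = 12,
) -> np.ndarray:
    """Blood-sampling schedule matched to an acquisition layout.

    Pre-injection samples at −30, −20, −10 and −0.5 min (the last is the
    baseline sample); samples every ``interval_s`` during each post-injection
    run (padded up to a multiple of ``block_multiple`` samples so downstream
    block averaging divides evenly); every 10 min in the inter-run gaps; and
    sparse samples out to 240 min including the 120-min comparison point and
    the ACTH peak region.
    """
    if run_spec is None:
        run_spec = RunSpec()
    times = [-30.0, -20.0, -10.0, -0.5]
    step = interval_s / 60.0
    for r in range(1, run_spec.n_runs):
        start = run_spec.run_start_min[r]
        dur = run_spec.run_duration_min(r)
        n = int(np.ceil(dur * 60.0 / interval_s))
        n = int(np.ceil(n / block_multiple) * block_multiple)
        times.extend(start + np.arange(n) * step)
        # gap samples every 10 min until the next run (or for 30 min after
        # the last run)
        gap_end = (
            run_spec.run_start_min[r + 1]
            if r + 1 < run_spec.n_runs
            else start + dur + 30.0
        )
        t = start + n * step
        t = np.ceil(t / 10.0) * 10.0
        while t < gap_end - 1e-9:
            times.append(float(t))
            t += 10.0
    times.extend([100.0, 110.0, 120.0, 130.0, 180.0, 240.0])
    arr = np.unique(np.round(np.asarray(times), 6))
    return arr


def simulate_serum_curves(
    times_min: np.ndarray | None = None,
    params: SerumKinetics | None = None,
    run_spec: RunSpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SerumSeries:
    """Sample the TNF and ACTH pulses on a blood-sampling schedule.

    With defaults the TNF argmax lies in [60, 70] min, the ACTH argmax in
    [100, 180] min, and both are ≤ 10 % of peak at 240 min.  Optional
    measurement noise is additive Gaussian, clipped at zero.
    """
    if params is None:
        params = SerumKinetics()
    if times_min is None:
        times_min = default_serum_times(run_spec)
    times_min = np.asarray(times_min, dtype=float)
    if times_min.ndim != 1 or len(times_min) < 2:
        raise ValueError("times_min must be a 1D array with >= 2 samples")
    if np.any(np.diff(times_min) <= 0):
        raise ValueError("times_min must be strictly increasing")
    tnf = params.tnf(times_min)
    acth = params.acth(times_min)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tnf = np.clip(tnf + rng.normal(0, noise_sd, tnf.shape), 0, None)
        acth = np.clip(acth + rng.normal(0, noise_sd, acth.shape), 0, None)
    return SerumSeries(times_min=times_min, tnf_pg_ml=tnf, acth_pg_ml=acth)


def simulate_cohort_serum(
    n_subjects: int,
    times_min: np.ndarray | None = None,
    params: SerumKinetics | None = None,
    run_spec: RunSpec | None = None,
    amplitude_cv: float = 0.15,
    noise_sd_frac: float = 0.02,
    seed: int = 0,
) -> tuple[list[SerumSeries], SerumSeries]:
    """Per-subject serum curves (amplitude jitter + sampling noise) and
    their group mean series."""
    if params is None:
        params = SerumKinetics()
    if times_min is None:
        times_min = default_serum_times(run_spec)
    rng = np.random.default_rng(seed)
    subjects = []
    for _s in range(n_subjects):
        scale_t = max(0.2, 1.0 + amplitude_cv * rng.standard_normal())
        scale_a = max(0.2, 1.0 + amplitude_cv * rng.standard_normal())
        p = SerumKinetics(
            tnf=MarkerPulse(params.tnf.onset_min, params.tnf.peak_min,
                            params.tnf.amplitude * scale_t, params.tnf.shape),
            acth=MarkerPulse(params.acth.onset_min, params.acth.peak_min,
                             params.acth.amplitude * scale_a, params.acth.shape),
        )
        noise = noise_sd_frac * params.tnf.amplitude
        subjects.append(
            simulate_serum_curves(times_min, p, noise_sd=noise,
                                  seed=int(rng.integers(2**31 - 1)))
        )
    group = SerumSeries(
        times_min=np.asarray(times_min, dtype=float),
        tnf_pg_ml=np.mean([s.tnf_pg_ml for s in subjects], axis=0),
        acth_pg_ml=np.mean([s.acth_pg_ml for s in subjects], axis=0),
    )
    return subjects, group


# --------------------------------------------------------------------------
# Phantom anatomy
# --------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


def make_phantom_anatomy(
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    seed: int = 0,
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> TissuePhantom:
    """Ellipsoidal phantom brain with GM shell, WM core, CSF pockets and a
    compact ROI near the volume centre.

    The ROI straddles a deliberate WM pocket on its +x side so that
    WM-embedded negative-control sources can be placed inside the ROI.
    Deterministic given ``seed`` (the seed only jitters the ROI centre by
    up to half a voxel).
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 24 for s in grid_shape):
        raise ValueError(
            f"grid {grid_shape} too small to contain all phantom compartments; "
            "need at least (24, 24, 24)"
        )
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_shape
    centre = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
    radii = 0.45 * np.array(grid_shape)
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    r = np.sqrt(
        ((ii - centre[0]) / radii[0]) ** 2
        + ((jj - centre[1]) / radii[1]) ** 2
        + ((kk - centre[2]) / radii[2]) ** 2
    )
    brain = _sigmoid((1.0 - r) / 0.04)
    wm = brain * _sigmoid((0.55 - r) / 0.05)
    # CSF: ventricle blob above the ROI plus a thin subarachnoid rim
    vent_c = centre + np.array([0.0, 0.0, 2.5])
    d_vent = np.sqrt(
        (ii - vent_c[0]) ** 2 + (jj - vent_c[1]) ** 2 + (kk - vent_c[2]) ** 2
    )
    vent = 0.9 * np.exp(-0.5 * (d_vent / 1.2) ** 2)
    rim = _sigmoid((r - 0.90) / 0.03) * brain
    csf = np.clip(vent + 0.8 * rim, 0, None)
    csf = np.minimum(csf, np.clip(brain - wm, 0, None))
    gm = np.clip(brain - wm - csf, 0, None)

    # ROI: compact ellipsoid slightly below centre, jittered by the seed
    roi_c = centre + np.array([0.0, 0.0, -2.0]) + rng.uniform(-0.5, 0.5, 3)
    # ~360 voxels: comparable to an anatomical hypothalamus mask at study
    # resolution; small masks also inflate the dual-regression self-noise
    # bias (weight ~ 1/V per voxel)
    roi_radii = np.array([5.0, 4.4, 3.9])
    d_roi = np.sqrt(
        ((ii - roi_c[0]) / roi_radii[0]) ** 2
        + ((jj - roi_c[1]) / roi_radii[1]) ** 2
        + ((kk - roi_c[2]) / roi_radii[2]) ** 2
    )
    roi = d_roi <= 1.0

    # tissue override around the ROI: deep grey matter with a WM pocket on
    # the +x side (negative-control territory)
    near = d_roi <= 1.25
    pocket_c = roi_c + np.array([3.4, 0.0, 0.0])
    d_pocket = np.sqrt(
        (ii - pocket_c[0]) ** 2 + (jj - pocket_c[1]) ** 2 + (kk - pocket_c[2]) ** 2
    )
    pocket = (d_pocket <= 2.2) & near
    gm[near] = 0.90
    wm[near] = 0.03
    csf[near] = 0.03
    gm[pocket] = 0.04
    wm[pocket] = 0.92

    phantom = TissuePhantom(
        voxel_size_mm=tuple(float(v) for v in voxel_size_mm),
        roi_mask=roi,
        gm_prob=gm,
        wm_prob=wm,
        csf_prob=csf,
    )
    phantom.roi_centre_vox = roi_c  # type: ignore[attr-defined]
    phantom.wm_pocket_centre_vox = pocket_c  # type: ignore[attr-defined]
    return phantom


# --------------------------------------------------------------------------
# Ground-truth sources
# --------------------------------------------------------------------------

@dataclass
class SourceSpec:
    """Placement and coupling description of one embedded source."""

    label: str  # 'tnf' | 'acth' | 'none'
    sign: int
    offset_vox: tuple[float, float, float]  # relative to the ROI centre
    run_amplitudes: tuple[float, ...]
    in_wm: bool = False
    satellite_dir: tuple[float, float, float] | None = None  # unit direction


def default_source_layout(n_runs: int = 4) -> list[SourceSpec]:
    """The five canonical phantom sources.

    1. TNF-coupled, run-modulated GM source (with a cortical satellite).
    2. ACTH-coupled, run-modulated GM source (opposite satellite).
    3. Uncoupled GM source.
    4. WM-embedded uncoupled source (specificity negative control).
    5. TNF-coupled but not run-modulated GM source.

    Run-amplitude rows multiply the fast fluctuation component per run;
    modulation is placed within the post-injection runs, matching the
    paired run comparison.
    """
    flat = tuple(1.0 for _ in range(n_runs))

    def modulated(high_runs: tuple[int, ...]) -> tuple[float, ...]:
        return tuple(3.0 if r in high_runs else 1.0 for r in range(n_runs))

    return [
        SourceSpec("tnf", -1, (-3.4, 1.2, 0.4), modulated((2, 3)),
                   satellite_dir=(0.0, 0.0, 1.0)),
        SourceSpec("acth", -1, (0.0, -2.8, 1.2), modulated((3,)),
                   satellite_dir=(0.0, 0.0, -1.0)),
        SourceSpec("none", 1, (0.0, 2.8, -1.2), flat),
        SourceSpec("none", 1, (3.4, 0.0, 0.0), flat, in_wm=True),
        SourceSpec("tnf", 1, (-1.2, -0.4, -2.4), flat),
    ]


def _source_map(
    phantom: TissuePhantom,
    spec: SourceSpec,
    blob_sigma_vox: float = 1.0,
    blob_radius_vox: float = 2.2,
) -> np.ndarray:
    """Compact Gaussian blob at the source position (unit peak), with an
    optional cortical satellite blob outside the ROI."""
    roi_c = getattr(phantom, "roi_centre_vox", None)
    if roi_c is None:
        idx = np.argwhere(phantom.roi_mask)
        roi_c = idx.mean(axis=0)
    shape = phantom.grid_shape
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij",
    )
    c = np.asarray(roi_c) + np.asarray(spec.offset_vox)
    d = np.sqrt((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2)
    blob = np.where(d <= blob_radius_vox,
                    np.exp(-0.5 * (d / blob_sigma_vox) ** 2), 0.0)
    if spec.satellite_dir is not None:
        centre = (np.asarray(shape) - 1) / 2
        direction = np.asarray(spec.satellite_dir, dtype=float)
        direction = direction / np.linalg.norm(direction)
        # place the satellite in the GM shell, ~72 % of the brain radius out
        sat_c = centre + direction * 0.72 * 0.45 * np.asarray(shape)
        ds = np.sqrt(
            (ii - sat_c[0]) ** 2 + (jj - sat_c[1]) ** 2 + (kk - sat_c[2]) ** 2
        )
        sat = np.where(ds <= 2.6, 0.8 * np.exp(-0.5 * (ds / 1.3) ** 2), 0.0)
        blob = np.maximum(blob, sat)
    peak = blob.max()
    if peak <= 0:
        raise ValueError("source blob fell outside the grid")
    return blob / peak


def _smooth_noise(rng: np.random.Generator, n: int, sigma_vols: float = 4.0) -> np.ndarray:
    x = gaussian_filter1d(rng.standard_normal(n), sigma_vols)
    sd = x.std()
    return x / sd if sd > 0 else x


def build_ground_truth(
    phantom: TissuePhantom,
    serum: SerumSeries,
    run_spec: RunSpec,
    seed: int = 0,
    sources: list[SourceSpec] | None = None,
    target_r: float = 0.92,
    block_volumes: int = 300,
    samples_per_block: int = 12,
    run_offset_sd: float = 0.8,
) -> GroundTruth:
    """Construct source maps and group-level time courses.

    Coupled sources are built as a z-scored resampling of the named serum
    curve at the volume acquisition times plus seeded noise, with the noise
    scale solved (root finding on the realised correlation) so that the
    block-downsampled time course correlates with the downsampled serum
    curve at ``±target_r``.  The noise term is a smooth fast fluctuation
    carrying the per-run amplitude multipliers (unit sd per run, so the
    fluctuation amplitude profile is exact).  Uncoupled sources get the
    same fast fluctuation plus slow drift of relative sd ``run_offset_sd``
    (orthogonalised per run so the per-run sd stays on the amplitude
    profile), giving their block means realistic slow variability of their
    own without creating spurious run-to-run amplitude changes.
    """
    from .coupling import downsample_bold, downsample_serum  # late import

    if sources is None:
        sources = default_source_layout(run_spec.n_runs)
    rng = np.random.default_rng(seed)
    vol_times = np.concatenate(
        [run_spec.volume_times_min(r) for r in range(run_spec.n_runs)]
    )
    run_slices = run_spec.run_slices()
    t_total = run_spec.total_volumes

    serum_points = {
        m: np.asarray(
            downsample_serum(serum, run_spec,
                             samples_per_block=samples_per_block, marker=m)
        )
        for m in ("tnf", "acth")
    }

    drift_sigma_vols = max(block_volumes // 2, 25)
    k_sources = len(sources)

    # Per run, draw white fast-fluctuation vectors for all sources and
    # mutually orthogonalise them (zero-mean, unit sd, zero pairwise
    # correlation), then slow drift vectors (block-scale correlation time,
    # demeaned per run) orthogonalised against every fast vector and each
    # other.  Exact per-run decorrelation matters: with a handful of
    # effective degrees of freedom, *sample* correlations between source
    # time courses fluctuate from run to run, are shared by every subject,
    # and masquerade as run-dependent connectivity changes downstream.
    fast_rows = np.zeros((k_sources, t_total))
    drift_rows = np.zeros((k_sources, t_total))
    for r, sl in enumerate(run_slices):
        n_r = sl.stop - sl.start
        basis: list[np.ndarray] = []
        f_run = rng.standard_normal((k_sources, n_r))
        for i in range(k_sources):
            v = f_run[i] - f_run[i].mean()
            for b in basis:
                v = v - (float(v @ b) / float(b @ b)) * b
            v = v / max(v.std(), 1e-12)
            basis.append(v)
            fast_rows[i, sl] = sources[i].run_amplitudes[r] * v
        for i in range(k_sources):
            d = gaussian_filter1d(rng.standard_normal(n_r), drift_sigma_vols)
            d = d - d.mean()
            for b in basis:
                d = d - (float(d @ b) / float(b @ b)) * b
            d = d / max(d.std(), 1e-12)
            basis.append(d)
            drift_rows[i, sl] = d

    maps = []
    tcs = []
    for ki, spec in enumerate(sources):
        maps.append(_source_map(phantom, spec))
        if spec.label == "none":
            tc = fast_rows[ki] + run_offset_sd * drift_rows[ki]
        else:
            raw = np.interp(vol_times, serum.times_min, serum.marker(spec.label))
            slow = spec.sign * (raw - raw.mean()) / max(raw.std(), 1e-12)
            s_b = np.asarray(downsample_bold(slow, run_spec, block_volumes))
            p = serum_points[spec.label]
            fast = fast_rows[ki]
            f_b = np.asarray(downsample_bold(fast, run_spec, block_volumes))

            def realised(beta: float) -> float:
                return abs(np.corrcoef(s_b + beta * f_b, p)[0, 1])

            if realised(0.0) <= target_r:
                beta = 0.0  # resampling alone is already at/below target
            else:
                grid = np.geomspace(1e-3, 256.0, 160)
                vals = np.array([realised(g) for g in grid])
                below = np.flatnonzero(vals <= target_r)
                if len(below) > 0:
                    hi = grid[below[0]]
                    lo = grid[below[0] - 1] if below[0] > 0 else 0.0
                    beta = brentq(lambda b: realised(b) - target_r, lo, hi,
                                  xtol=1e-5)
                else:  # cannot dilute below target; take the closest point
                    beta = float(grid[np.argmin(np.abs(vals - target_r))])
            tc = slow + beta * fast
        tc = tc / tc.std()
        tcs.append(tc)

    return GroundTruth(
        source_maps=np.stack(maps),
        source_timecourses=np.stack(tcs),
        coupling_labels=tuple(s.label for s in sources),
        coupling_sign=tuple(s.sign for s in sources),
        coupling_target_r=target_r,
        run_amplitudes=np.array([s.run_amplitudes for s in sources]),
        in_wm=tuple(s.in_wm for s in sources),
    )


# --------------------------------------------------------------------------
# BOLD simulation
# --------------------------------------------------------------------------

def simulate_subject_bold(
    phantom: TissuePhantom,
    truth: GroundTruth,
    serum: SerumSeries,
    run_spec: RunSpec,
    noise_sd: float = 10.0,
    drift_amp: float = 5.0,
    seed: int = 0,
    signal_amplitude: float = 10.0,
    tc_jitter_sd: float = 0.1,
    run_amp_jitter_sd: float = 0.0,
    map_jitter_sd: float = 0.0,
    baseline: float = 1000.0,
) -> list[VolumeSeries]:
    """One subject's multi-run 4D data.

    ``data = baseline + signal_amplitude * Σ_k map_k ⊗ tc_k + drift + noise``
    where the per-subject time courses are the shared group time courses
    plus seeded smooth Gaussian jitter of relative amplitude
    ``tc_jitter_sd``, and the per-subject source maps are the shared maps
    modulated voxelwise by ``1 + map_jitter_sd`` times a smooth spatial
    noise field (inter-subject variability of connectivity topography; the
    group-average map stays the shared map).  A scalar per-run gain
    (``run_amp_jitter_sd``, off by default) is also available but is a
    rank-one effect across voxels, which small-sample sign-flip tests
    handle badly.  Drift is a spatially smooth field times a slow cosine;
    noise is white Gaussian.  Deterministic given the seed.
    """
    if truth.source_maps.shape[1:] != phantom.grid_shape:
        raise ValueError("ground-truth maps and phantom are on different grids")
    rng = np.random.default_rng(seed)
    shape = phantom.grid_shape
    n_vox = int(np.prod(shape))
    k = truth.n_sources
    flat_maps = truth.source_maps.reshape(k, n_vox).astype(np.float32)
    if map_jitter_sd > 0:
        jittered = np.empty_like(flat_maps)
        for ki in range(k):
            xi = gaussian_filter(rng.standard_normal(shape), 1.0)
            xi /= max(xi.std(), 1e-12)
            gain = np.clip(1.0 + map_jitter_sd * xi.ravel(), 0.0, None)
            jittered[ki] = flat_maps[ki] * gain.astype(np.float32)
        flat_maps = jittered

    affine = phantom.affine
    runs = []
    for r, sl in enumerate(run_spec.run_slices()):
        t_r = sl.stop - sl.start
        tc = truth.source_timecourses[:, sl].copy()
        if tc_jitter_sd > 0:
            for ki in range(k):
                tc[ki] += tc_jitter_sd * tc[ki].std() * _smooth_noise(rng, t_r)
        if run_amp_jitter_sd > 0:
            gains = 1.0 + run_amp_jitter_sd * rng.standard_normal(k)
            tc *= np.clip(gains, 0.3, None)[:, None]
        data = np.asarray(
            signal_amplitude * (flat_maps.T @ tc.astype(np.float32)),
            dtype=np.float32,
        )
        data += np.float32(baseline)
        if drift_amp > 0:
            fld = gaussian_filter(rng.standard_normal(shape), 3.0).ravel()
            fld /= max(np.abs(fld).max(), 1e-12)
            tt = np.arange(t_r) / t_r
            c = (rng.standard_normal() * np.cos(np.pi * tt)
                 + rng.standard_normal() * np.cos(2 * np.pi * tt))
            c = c / max(np.abs(c).max(), 1e-12)
            data += np.float32(drift_amp) * np.outer(fld, c).astype(np.float32)
        if noise_sd > 0:
            data += noise_sd * rng.standard_normal((n_vox, t_r),
                                                   dtype=np.float32)
        runs.append(
            VolumeSeries(data=data.reshape(shape + (t_r,)), affine=affine,
                         tr_s=run_spec.tr_s)
        )
    return runs


# --------------------------------------------------------------------------
# Dataset assembly and on-disk format
# --------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """In-memory synthetic study: phantom, truth, serum and per-subject runs."""

    phantom: TissuePhantom
    truth: GroundTruth
    serum_group: SerumSeries
    serum_subjects: list[SerumSeries]
    runs_by_subject: list[list[VolumeSeries]]
    run_spec: RunSpec
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.runs_by_subject)


def simulate_dataset(
    n_subjects: int = 6,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    run_spec: RunSpec | None = None,
    kinetics: SerumKinetics | None = None,
    sources: list[SourceSpec] | None = None,
    noise_sd: float = 10.0,
    drift_amp: float = 5.0,
    signal_amplitude: float = 10.0,
    target_r: float = 0.92,
    block_volumes: int = 300,
    samples_per_block: int = 12,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a full multi-subject study with known ground truth."""
    if run_spec is None:
        run_spec = RunSpec()
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(3 + n_subjects) % (2**31 - 1)
    phantom = make_phantom_anatomy(grid_shape, seed=int(child[0]))
    times = default_serum_times(run_spec, block_multiple=samples_per_block)
    serum_subjects, serum_group = simulate_cohort_serum(
        n_subjects, times, kinetics, seed=int(child[1])
    )
    truth = build_ground_truth(
        phantom, serum_group, run_spec, seed=int(child[2]), sources=sources,
        target_r=target_r, block_volumes=block_volumes,
        samples_per_block=samples_per_block,
    )
    runs_by_subject = [
        simulate_subject_bold(
            phantom, truth, serum_group, run_spec, noise_sd=noise_sd,
            drift_amp=drift_amp, seed=int(child[3 + s]),
            signal_amplitude=signal_amplitude,
        )
        for s in range(n_subjects)
    ]
    return SyntheticDataset(
        phantom=phantom,
        truth=truth,
        serum_group=serum_group,
        serum_subjects=serum_subjects,
        runs_by_subject=runs_by_subject,
        run_spec=run_spec,
        seed=seed,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str) -> dict:
    """Write a dataset to disk (NIfTI + CSV + JSON manifest).

    Returns the manifest dict, which is also written as
    ``ground_truth.json`` / ``manifest.json`` under ``out_dir``.
    """
    try:
        os.makedirs(out_dir, exist_ok=True)
        probe = os.path.join(out_dir, ".write_probe")
        with open(probe, "w") as fh:
            fh.write("ok")
        os.remove(probe)
    except OSError as exc:
        raise OSError(f"output directory {out_dir!r} is not writable: {exc}")

    ph = dataset.phantom
    files: dict[str, object] = {}

    def _vol(name: str, data: np.ndarray) -> str:
        path = os.path.join(out_dir, name)
        hio.save_volume(data, ph.affine, path)
        return name

    files["roi_mask"] = _vol("roi_mask.nii.gz", ph.roi_mask.astype(np.float32))
    files["gm_prob"] = _vol("gm_prob.nii.gz", ph.gm_prob)
    files["wm_prob"] = _vol("wm_prob.nii.gz", ph.wm_prob)
    files["csf_prob"] = _vol("csf_prob.nii.gz", ph.csf_prob)

    src4d = np.moveaxis(dataset.truth.source_maps, 0, -1)
    files["source_maps"] = _vol("source_maps.nii.gz", src4d)

    runs = {}
    for s, subj_runs in enumerate(dataset.runs_by_subject):
        names = []
        for r, run in enumerate(subj_runs):
            # uncompressed: 4D noise barely compresses and gzip dominates
            name = f"sub-{s:02d}_run-{r}.nii"
            hio.save_volume_series(run, os.path.join(out_dir, name))
            names.append(name)
        runs[f"sub-{s:02d}"] = names
    files["runs"] = runs

    hio.save_serum_csv(dataset.serum_group, os.path.join(out_dir, "serum.csv"))
    files["serum"] = "serum.csv"
    subj_csvs = []
    for s, series in enumerate(dataset.serum_subjects):
        name = f"serum_sub-{s:02d}.csv"
        hio.save_serum_csv(series, os.path.join(out_dir, name))
        subj_csvs.append(name)
    files["serum_subjects"] = subj_csvs

    np.savetxt(
        os.path.join(out_dir, "source_timecourses.csv"),
        dataset.truth.source_timecourses.T,
        delimiter=",",
        header=",".join(
            f"source_{k}" for k in range(dataset.truth.n_sources)
        ),
        comments="",
    )
    files["source_timecourses"] = "source_timecourses.csv"

    manifest = {
        "seed": int(dataset.seed),
        "n_subjects": dataset.n_subjects,
        "run_spec": {
            "n_volumes": list(dataset.run_spec.n_volumes),
            "tr_s": dataset.run_spec.tr_s,
            "run_start_min": list(dataset.run_spec.run_start_min),
        },
        "sources": [
            {
                "index": k,
                "label": dataset.truth.coupling_labels[k],
                "sign": int(dataset.truth.coupling_sign[k]),
                "run_amplitudes": [float(a) for a in dataset.truth.run_amplitudes[k]],
                "run_modulated": dataset.truth.is_run_modulated(k),
                "in_wm": bool(dataset.truth.in_wm[k]),
            }
            for k in range(dataset.truth.n_sources)
        ],
        "coupling_target_r": float(dataset.truth.coupling_target_r),
        "files": files,
    }
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
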