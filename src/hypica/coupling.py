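"""BOLD–serum coupling: block downsampling, correlation, Bonferroni
selection, the combined two-criteria region decision, and the serum change
test.

Component time courses and serum curves are reduced to a common coarse grid
(10 points for the default acquisition): the mean of the final baseline-run
block and the single baseline blood sample form the first point; consecutive
non-overlapping block means of each post-injection run (300 volumes ≈ 354 s
of BOLD; 12 raw 30-s blood samples ≈ 360 s) form the rest.  Pearson
correlation on the paired points, with a two-tailed t-transform p-value at
n − 2 degrees of freedom and Bonferroni correction over
(components × markers), gives criterion 1.  Criterion 2 (a significant
within-ROI connectivity change between post-injection runs) comes from the
inference module; a component is inflammation-associated when it satisfies
both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RunSpec, SerumSeries

__all__ = [
    "downsample_bold",
    "downsample_serum",
    "downsample_point_times",
    "pool_sample_pairs",
    "correlate_with_serum",
    "critical_r",
    "select_inflammation_regions",
    "serum_change_test",
    "CouplingResult",
]


def downsample_bold(
    timecourse: np.ndarray,
    run_spec: RunSpec,
    block_volumes: int = 300,
) -> np.ndarray:
    """Block-average a concatenated time course onto the coarse grid.

    Point 1 is the mean of the final ``block_volumes`` volumes of the
    baseline run; subsequent points are consecutive non-overlapping
    ``block_volumes``-volume means of each post-injection run in order.
    Every post-injection run length must divide evenly; the baseline run
    must contain at least one block.
    """
    tc = np.asarray(timecourse, dtype=float)
    if tc.ndim != 1:
        raise ValueError("timecourse must be 1D (concatenated over runs)")
    if tc.size != run_spec.total_volumes:
        raise ValueError(
            f"timecourse length {tc.size} does not match the run spec "
            f"total of {run_spec.total_volumes} volumes"
        )
    slices = run_spec.run_slices()
    n_base = run_spec.n_volumes[0]
    if n_base < block_volumes:
        raise ValueError(
            f"baseline run has {n_base} volumes; needs >= {block_volumes}"
        )
    points = [tc[slices[0]][-block_volumes:].mean()]
    for r in range(1, run_spec.n_runs):
        n_r = run_spec.n_volumes[r]
        if n_r % block_volumes != 0:
            raise ValueError(
                f"run {r} has {n_r} volumes, not divisible by "
                f"{block_volumes}-volume blocks"
            )
        blocks = tc[slices[r]].reshape(n_r // block_volumes, block_volumes)
        points.extend(blocks.mean(axis=1))
    return np.asarray(points)


def downsample_point_times(
    run_spec: RunSpec, block_volumes: int = 300
) -> np.ndarray:
    """Centre time (minutes) of each downsampled point."""
    times = []
    base_times = run_spec.volume_times_min(0)[-block_volumes:]
    times.append(base_times.mean())
    for r in range(1, run_spec.n_runs):
        vt = run_spec.volume_times_min(r)
        n_blocks = run_spec.n_volumes[r] // block_volumes
        for b in range(n_blocks):
            times.append(vt[b * block_volumes:(b + 1) * block_volumes].mean())
    return np.asarray(times)


def downsample_serum(
    series: SerumSeries,
    run_spec: RunSpec,
    samples_per_block: int = 12,
    marker: str = "tnf",
) -> np.ndarray:
    """Reduce a serum series to the coarse grid matching ``downsample_bold``.

    The first point is the single baseline sample (the last sample at or
    before the injection).  For each post-injection run, the raw samples
    from the run's start onward are averaged in consecutive non-overlapping
    blocks of ``samples_per_block``, one block per BOLD block of that run.
    """
    return _downsample_serum_marker(series, run_spec, samples_per_block, marker)


def _downsample_serum_marker(
    series: SerumSeries,
    run_spec: RunSpec,
    samples_per_block: int,
    marker: str = "tnf",
) -> np.ndarray:
    t = series.times_min
    values = series.marker(marker)
    inj = run_spec.run_start_min[1]
    baseline_idx = np.flatnonzero(t < inj - 1e-9)
    if len(baseline_idx) == 0:  # allow a sample exactly at the injection
        baseline_idx = np.flatnonzero(t <= inj + 1e-9)
    if len(baseline_idx) == 0:
        raise ValueError("serum series has no baseline sample (t <= injection)")
    points = [values[baseline_idx[-1]]]
    for r in range(1, run_spec.n_runs):
        # one serum block of samples_per_block raw samples spans the same
        # wall-clock stretch as one BOLD block of this run
        n_blocks = _blocks_in_run(run_spec, r, samples_per_block, series)
        start = run_spec.run_start_min[r]
        idx = np.flatnonzero(t >= start - 1e-9)
        needed = n_blocks * samples_per_block
        if len(idx) < needed:
            raise ValueError(
                f"run {r} needs {needed} serum samples from its start; "
                f"only {len(idx)} available"
            )
        sel = values[idx[:needed]].reshape(n_blocks, samples_per_block)
        points.extend(sel.mean(axis=1))
    return np.asarray(points)


def _blocks_in_run(
    run_spec: RunSpec, run: int, samples_per_block: int, series: SerumSeries
) -> int:
    """Blocks in a post-injection run: one serum block per BOLD block.

    One serum block spans ``samples_per_block`` × sampling interval of wall
    clock; the matching BOLD block count is the run duration divided by that
    stretch, rounded to the nearest integer (the 354 s vs 360 s residual
    misalignment of the default design is accepted).
    """
    block_min = samples_per_block * series.sampling_interval_s / 60.0
    n = int(round(run_spec.run_duration_min(run) / block_min))
    return max(n, 1)


def pool_sample_pairs(series: SerumSeries) -> SerumSeries:
    """Average consecutive pairs of raw samples (two 30-s vials poured
    together), halving the sampling rate to 1 per minute.

    Only strictly consecutive samples (spacing equal to the sampling
    interval) are pooled; isolated samples are kept as they are.
    """
    t = series.times_min
    step = series.sampling_interval_s / 60.0
    out_t, out_tnf, out_acth = [], [], []
    i = 0
    n = len(t)
    while i < n:
        if i + 1 < n and abs((t[i + 1] - t[i]) - step) < 1e-6:
            out_t.append(0.5 * (t[i] + t[i + 1]))
            out_tnf.append(0.5 * (series.tnf_pg_ml[i] + series.tnf_pg_ml[i + 1]))
            out_acth.append(0.5 * (series.acth_pg_ml[i] + series.acth_pg_ml[i + 1]))
            i += 2
        else:
            out_t.append(t[i])
            out_tnf.append(series.tnf_pg_ml[i])
            out_acth.append(series.acth_pg_ml[i])
            i += 1
    return SerumSeries(
        times_min=np.asarray(out_t),
        tnf_pg_ml=np.asarray(out_tnf),
        acth_pg_ml=np.asarray(out_acth),
        sampling_interval_s=series.sampling_interval_s * 2,
    )


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Pearson r and two-tailed t-transform p; flags zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan, True
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_c * np.sqrt((n - 2) / (1 - r_c**2))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, p, False


def critical_r(n: int, alpha: float) -> float:
    """|r| threshold for two-tailed significance at ``alpha`` with n points."""
    t_crit = stats.t.isf(alpha / 2, df=n - 2)
    return float(t_crit / np.sqrt(t_crit**2 + n - 2))


def correlate_with_serum(
    component_timecourses: np.ndarray,
    serum: SerumSeries,
    run_spec: RunSpec,
    alpha: float = 0.05,
    block_volumes: int = 300,
    samples_per_block: int = 12,
    component_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Criterion 1: correlate downsampled component time courses with the
    downsampled TNF and ACTH curves.

    ``component_timecourses`` is (K, T_total) on the concatenated volume
    grid.  Bonferroni correction uses the family of all tested components
    times the two markers.  Returns the long-format coupling table (one row
    per component × marker) with the per-component ``criterion1`` flag.
    """
    tcs = np.atleast_2d(np.asarray(component_timecourses, dtype=float))
    k = tcs.shape[0]
    ids = list(range(k)) if component_ids is None else list(component_ids)
    if len(ids) != k:
        raise ValueError("component_ids length must match the time courses")
    markers = ("tnf", "acth")
    bonf = alpha / (k * len(markers))
    serum_points = {
        m: _downsample_serum_marker(serum, run_spec, samples_per_block, m)
        for m in markers
    }
    rows = []
    for ki, cid in enumerate(ids):
        bold_points = downsample_bold(tcs[ki], run_spec, block_volumes)
        for m in markers:
            r, p, degenerate = _pearson_with_p(bold_points, serum_points[m])
            sig = (not degenerate) and p < bonf
            rows.append(
                {
                    "component": cid,
                    "marker": m,
                    "r": r,
                    "p_uncorrected": p,
                    "bonferroni_significant": bool(sig),
                    "degenerate": bool(degenerate),
                }
            )
    df = pd.DataFrame(rows)
    crit1 = df.groupby("component")["bonferroni_significant"].any()
    df["criterion1"] = df["component"].map(crit1)
    df.attrs["alpha"] = alpha
    df.attrs["bonferroni_alpha"] = bonf
    df.attrs["n_points"] = len(next(iter(serum_points.values())))
    return df


@dataclass
class CouplingResult:
    """Final two-criteria decision with a full trace."""

    table: pd.DataFrame
    criterion2: dict[int, bool]
    criterion2_detail: dict[int, dict]
    selected: list[int] = field(default_factory=list)

    def decision_frame(self) -> pd.DataFrame:
        comps = sorted(self.table["component"].unique())
        crit1 = self.table.groupby("component")["criterion1"].first()
        return pd.DataFrame(
            {
                "component": comps,
                "criterion1": [bool(crit1[c]) for c in comps],
                "criterion2": [self.criterion2.get(c, False) for c in comps],
                "selected": [c in self.selected for c in comps],
            }
        )


def select_inflammation_regions(
    coupling_table: pd.DataFrame,
    run_comparisons: dict[int, dict],
) -> CouplingResult:
    """Conjunction of the two criteria on the same retained component set.

    ``run_comparisons`` maps component id → {(run_a, run_b): min FWE p}
    (or → bool).  A component satisfies criterion 2 when any run pair shows
    a suprathreshold voxel at FWE p < 0.05.  The component sets of both
    criteria must match.
    """
    comps1 = set(int(c) for c in coupling_table["component"].unique())
    comps2 = set(int(c) for c in run_comparisons)
    if comps1 != comps2:
        raise ValueError(
            f"criterion component sets differ: {sorted(comps1)} vs {sorted(comps2)}"
        )
    crit1 = coupling_table.groupby("component")["criterion1"].first()
    crit2: dict[int, bool] = {}
    detail: dict[int, dict] = {}
    for c, entry in run_comparisons.items():
        if isinstance(entry, dict):
            alpha = entry.get("alpha", 0.05)
            pair_ps = entry.get("pair_min_p", entry)
            pair_ps = {k: v for k, v in pair_ps.items() if isinstance(k, tuple)}
            crit2[c] = any(p < alpha for p in pair_ps.values())
            detail[c] = {"pair_min_p": pair_ps, "alpha": alpha}
        else:
            crit2[c] = bool(entry)
            detail[c] = {}
    selected = sorted(c for c in comps1 if bool(crit1[c]) and crit2[c])
    return CouplingResult(
        table=coupling_table,
        criterion2=crit2,
        criterion2_detail=detail,
        selected=selected,
    )


def serum_change_test(
    baseline_values: np.ndarray, t120_values: np.ndarray
) -> dict:
    """Two-tailed paired t test of serum levels, baseline vs 120 min.

    Returns the t statistic, two-tailed p, and the mean ± sample-SD of the
    paired differences.
    """
    a = np.asarray(baseline_values, dtype=float)
    b = np.asarray(t120_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired value arrays must be 1D and equally long")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return {
                "t": 0.0,
                "p": 1.0,
                "mean_diff": 0.0,
                "sd_diff": 0.0,
                "n": len(d),
            }
        raise ValueError("zero variance of nonzero differences")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return {
        "t": float(t),
        "p": p,
        "mean_diff": float(d.mean()),
        "sd_diff": float(sd),
        "n": n,
    }
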