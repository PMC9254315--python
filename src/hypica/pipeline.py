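"""End-to-end orchestration: configuration, stage wiring and the full chain.

``run_all`` executes the whole analysis on an in-memory dataset: preprocess
(grand-mean scaling, high-pass, smoothing for the whole-brain stream only),
masked ICA of the ROI, whole-brain dual regression, tissue-specificity
filtering, the two inflammation-association criteria (serum coupling and
the paired run comparison over the post-injection runs), whole-brain
one-sample inference for the selected components, and network similarity
clustering.  The CLI wraps these stages with on-disk inputs and outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import coupling as cpl
from . import dualreg, ica, inference, networks, preprocess, specificity
from .containers import (
    ComponentSet,
    MaskedMatrix,
    PermutationResult,
    RunSpec,
    SimilarityMatrix,
    SpecificityReport,
    TfceParams,
)
from .synthetic import SyntheticDataset, simulate_dataset

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "default_config",
    "scaled_config",
    "run_all",
    "PipelineResult",
    "match_components_to_sources",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the field path."""


@dataclass
class SimulateConfig:
    n_subjects: int = 6
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_volumes: tuple[int, ...] = (450, 900, 900, 900)
    tr_s: float = 1.18
    run_start_min: tuple[float, ...] = (-30.0, 0.0, 30.0, 80.0)
    noise_sd: float = 10.0
    drift_amp: float = 5.0
    signal_amplitude: float = 10.0
    target_r: float = 0.92

    def run_spec(self) -> RunSpec:
        return RunSpec(self.n_volumes, self.tr_s, self.run_start_min)


@dataclass
class PreprocessConfig:
    highpass_hz: float = 0.005
    fwhm_mm: float = 5.0
    grand_mean: float = 10000.0
    variance_normalize: bool = True


@dataclass
class IcaConfig:
    dim: int = 5
    d_range: tuple[int, ...] | None = None
    seed: int = 101
    restarts: int = 3
    max_iter: int = 500
    tol: float = 1e-5


@dataclass
class InferenceConfig:
    n_perm: int = 5000
    alpha_roi: float = 0.05
    alpha_wb: float = 0.01
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    tfce_dh: float | None = None
    connectivity: int = 26

    def tfce_params(self) -> TfceParams:
        return TfceParams(E=self.tfce_e, H=self.tfce_h, dh=self.tfce_dh,
                          connectivity=self.connectivity)


@dataclass
class CouplingConfig:
    block_volumes: int = 300
    samples_per_block: int = 12
    alpha: float = 0.05


@dataclass
class PathsConfig:
    data_dir: str = "dataset"
    out_dir: str = "out"


@dataclass
class PipelineConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ica: IcaConfig = field(default_factory=IcaConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    seed: int = 0

    def validate(self) -> None:
        def check(cond: bool, path: str, msg: str) -> None:
            if not cond:
                raise ConfigError(f"{path}: {msg}")

        sim = self.simulate
        check(sim.n_subjects >= 2, "simulate.n_subjects", "must be >= 2")
        check(len(sim.grid_shape) == 3 and all(s >= 24 for s in sim.grid_shape),
              "simulate.grid_shape", "must be a triple with every dim >= 24")
        check(len(sim.n_volumes) >= 2, "simulate.n_volumes",
              "need baseline plus post-injection runs")
        check(sim.tr_s > 0, "simulate.tr_s", "must be positive")
        check(sim.noise_sd >= 0, "simulate.noise_sd", "must be nonnegative")
        pre = self.preprocess
        check(0 < pre.highpass_hz < 1.0 / (2 * sim.tr_s),
              "preprocess.highpass_hz", "must be in (0, Nyquist)")
        check(pre.fwhm_mm > 0, "preprocess.fwhm_mm", "must be positive")
        check(pre.grand_mean > 0, "preprocess.grand_mean", "must be positive")
        check(self.ica.dim >= 2, "ica.dim", "must be >= 2")
        check(self.ica.restarts >= 1, "ica.restarts", "must be >= 1")
        inf = self.inference
        check(inf.n_perm >= 2, "inference.n_perm", "must be >= 2")
        check(0 < inf.alpha_roi < 1, "inference.alpha_roi", "must be in (0, 1)")
        check(0 < inf.alpha_wb < 1, "inference.alpha_wb", "must be in (0, 1)")
        check(inf.connectivity in (6, 18, 26), "inference.connectivity",
              "must be one of 6, 18, 26")
        cp = self.coupling
        check(cp.block_volumes >= 1, "coupling.block_volumes", "must be >= 1")
        check(cp.samples_per_block >= 1, "coupling.samples_per_block",
              "must be >= 1")
        check(0 < cp.alpha < 1, "coupling.alpha", "must be in (0, 1)")
        for r in range(1, len(sim.n_volumes)):
            check(sim.n_volumes[r] % cp.block_volumes == 0,
                  f"simulate.n_volumes[{r}]",
                  f"must be divisible by coupling.block_volumes={cp.block_volumes}")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub: dict, path: str):
            valid = {f for f in klass.__dataclass_fields__}
            for key in sub:
                if key not in valid:
                    raise ConfigError(f"{path}.{key}: unknown field")
            kwargs = dict(sub)
            for key, val in kwargs.items():
                if isinstance(val, list):
                    kwargs[key] = tuple(val)
            return klass(**kwargs)

        cfg = cls(
            paths=build(PathsConfig, d.get("paths", {}), "paths"),
            simulate=build(SimulateConfig, d.get("simulate", {}), "simulate"),
            preprocess=build(PreprocessConfig, d.get("preprocess", {}),
                             "preprocess"),
            ica=build(IcaConfig, d.get("ica", {}), "ica"),
            inference=build(InferenceConfig, d.get("inference", {}),
                            "inference"),
            coupling=build(CouplingConfig, d.get("coupling", {}), "coupling"),
            seed=int(d.get("seed", 0)),
        )
        extra = set(d) - {"paths", "simulate", "preprocess", "ica",
                          "inference", "coupling", "seed"}
        if extra:
            raise ConfigError(f"unknown top-level config fields: {sorted(extra)}")
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)


def default_config(seed: int = 0) -> PipelineConfig:
    """Study-scale conditions: 6 subjects, [450, 900, 900, 900] volumes at
    TR 1.18 s, 300-volume / 12-sample downsampling blocks."""
    cfg = PipelineConfig(seed=seed)
    cfg.validate()
    return cfg


def scaled_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale conditions preserving the design's structure.

    Runs of [150, 300, 300, 300] volumes with 100-volume BOLD blocks and
    4-sample serum blocks reproduce the same 10-point downsampling grid and
    the same 3-blocks-per-run layout as the full design, at a fraction of
    the cost.
    """
    cfg = PipelineConfig(
        simulate=SimulateConfig(n_volumes=(150, 300, 300, 300)),
        coupling=CouplingConfig(block_volumes=100, samples_per_block=4),
        seed=seed,
    )
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# Stage helpers
# --------------------------------------------------------------------------

def preprocess_dataset(
    dataset: SyntheticDataset, cfg: PreprocessConfig
) -> tuple[MaskedMatrix, MaskedMatrix, MaskedMatrix]:
    """Produce the three matrices the analysis consumes.

    Each run is grand-mean scaled and high-pass filtered; the whole-brain
    stream is additionally smoothed (ROI analyses use unsmoothed data).
    Returns ``(roi_ica, roi_reg, wb_reg)``: the ICA input (ROI voxels,
    demeaned and optionally variance-normalised per subject-run block) and
    the two dual-regression inputs (ROI and whole brain, *not* demeaned —
    between-run signal levels carry the serum coupling and must survive).
    """
    brain = dataset.phantom.brain_mask
    roi_runs = []
    wb_runs = []
    for runs in dataset.runs_by_subject:
        roi_subj = []
        wb_subj = []
        for run in runs:
            v = preprocess.grand_mean_scale(run, cfg.grand_mean, brain)
            v = preprocess.highpass_filter(v, cfg.highpass_hz)
            roi_subj.append(v)
            wb_subj.append(preprocess.gaussian_smooth(v, cfg.fwhm_mm))
        roi_runs.append(roi_subj)
        wb_runs.append(wb_subj)
    roi_ica = preprocess.mask_and_concatenate(
        roi_runs, dataset.phantom.roi_mask, cfg.variance_normalize
    )
    roi_reg = preprocess.mask_and_concatenate(
        roi_runs, dataset.phantom.roi_mask, demean=False
    )
    wb_reg = preprocess.mask_and_concatenate(wb_runs, brain, demean=False)
    return roi_ica, roi_reg, wb_reg


def _maps_to_volumes(
    flat_maps: np.ndarray, voxel_index: np.ndarray, grid_shape: tuple[int, int, int]
) -> np.ndarray:
    """(d, V) flat maps -> (d, nx, ny, nz) volumes (zeros outside)."""
    d = flat_maps.shape[0]
    out = np.zeros((d,) + tuple(grid_shape))
    out[(slice(None),) + tuple(voxel_index.T)] = flat_maps
    return out


def _bbox(mask: np.ndarray, pad: int = 1) -> tuple[slice, slice, slice]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def run_pair_comparisons(
    roi_maps_per_run: dict,
    roi_mask: np.ndarray,
    voxel_index: np.ndarray,
    component_ids: list[int],
    n_subjects: int,
    post_runs: list[int],
    n_perm: int,
    seed: int,
    tfce_params: TfceParams,
    alpha: float,
) -> dict[int, dict]:
    """Criterion 2: paired permutation tests per component over run pairs.

    Compares the per-run within-ROI dual-regression z maps between every
    unordered pair of post-injection runs, with a single max-statistic FWE
    correction across voxels and run pairs per component (shared sign
    flips), so alpha controls the family-wise error of the whole comparison
    set.  Returns, per component, the family-corrected minimum p of each
    pair plus the alpha used.
    """
    box = _bbox(roi_mask)
    mask_c = roi_mask[box]
    results: dict[int, dict] = {}
    pairs = list(itertools.combinations(post_runs, 2))

    def _stack(run: int, comp_pos: int) -> np.ndarray:
        return np.stack([
            _maps_to_volumes(
                roi_maps_per_run[(s, run)][comp_pos:comp_pos + 1],
                voxel_index, roi_mask.shape,
            )[0][box]
            for s in range(n_subjects)
        ])

    for comp_pos, comp_id in enumerate(component_ids):
        fam = inference.permutation_paired_family(
            {
                (ra, rb): (_stack(ra, comp_pos), _stack(rb, comp_pos))
                for ra, rb in pairs
            },
            n_perm=n_perm, seed=seed + 97 * comp_id,
            tfce_params=tfce_params, alpha=alpha, mask=mask_c,
        )
        pair_min_p = {key: res.min_p for key, res in fam.items()}
        results[comp_id] = {"pair_min_p": pair_min_p, "alpha": alpha}
    return results


# --------------------------------------------------------------------------
# Full chain
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything the full chain computes, for inspection and export."""

    config: PipelineConfig
    dataset: SyntheticDataset
    components: ComponentSet
    specificity: SpecificityReport
    retained: list[int]
    coupling_table: object  # pandas DataFrame
    run_comparisons: dict[int, dict]
    selection: cpl.CouplingResult
    wholebrain_group_z: np.ndarray  # (d, V_brain)
    brain_voxel_index: np.ndarray
    final_inference: dict[int, PermutationResult]
    similarity: SimilarityMatrix | None
    serum_tests: dict[str, dict]
    group_timecourses: np.ndarray  # (T_total, d)

    @property
    def selected(self) -> list[int]:
        return self.selection.selected

    def manifest(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "seed": int(self.config.seed),
            "n_components": self.components.n_components,
            "specificity_excluded": [int(i) for i in
                                     np.flatnonzero(self.specificity.excluded)],
            "retained": [int(i) for i in self.retained],
            "criterion1": {
                int(c): bool(v)
                for c, v in self.coupling_table.groupby("component")["criterion1"]
                .first().items()
            },
            "criterion2": {int(c): bool(v)
                           for c, v in self.selection.criterion2.items()},
            "selected": [int(i) for i in self.selected],
            "serum_tests": self.serum_tests,
        }


def run_all(
    config: PipelineConfig,
    dataset: SyntheticDataset | None = None,
) -> PipelineResult:
    """Execute the full analysis chain on (or after simulating) a dataset."""
    config.validate()
    sim = config.simulate
    if dataset is None:
        dataset = simulate_dataset(
            n_subjects=sim.n_subjects,
            grid_shape=sim.grid_shape,
            run_spec=sim.run_spec(),
            noise_sd=sim.noise_sd,
            drift_amp=sim.drift_amp,
            signal_amplitude=sim.signal_amplitude,
            target_r=sim.target_r,
            block_volumes=config.coupling.block_volumes,
            samples_per_block=config.coupling.samples_per_block,
            seed=config.seed,
        )
    run_spec = dataset.run_spec
    phantom = dataset.phantom

    roi_ica, roi_reg, wb_matrix = preprocess_dataset(dataset, config.preprocess)

    whitened = ica.reduce_and_whiten(roi_ica, config.ica.dim)
    comps = ica.estimate_components(
        whitened, config.ica.dim, seed=config.ica.seed,
        max_iter=config.ica.max_iter, tol=config.ica.tol,
        restarts=config.ica.restarts,
    )

    # whole-brain connectivity profiles (stage 2 on the smoothed stream)
    wb_maps = dualreg.dual_regress(roi_reg, comps, wb_matrix, per_run=False)
    group_z = wb_maps.group_mean_z()  # (d, V_brain)

    # tissue specificity on the group-level whole-brain |z| maps
    quotients = np.array([
        specificity.tissue_quotient(group_z[k], phantom)
        for k in range(comps.n_components)
    ])
    spec_report = specificity.flag_unspecific(quotients)
    comps.noise_flags = spec_report.excluded.copy()
    retained = [int(i) for i in spec_report.retained_indices()]

    # criterion 1: serum coupling of the group-mean stage-1 time courses
    group_tc = wb_maps.group_mean_timecourse()  # (T, d)
    coupling_table = cpl.correlate_with_serum(
        group_tc.T[retained], dataset.serum_group, run_spec,
        alpha=config.coupling.alpha,
        block_volumes=config.coupling.block_volumes,
        samples_per_block=config.coupling.samples_per_block,
        component_ids=retained,
    )

    # criterion 2: paired run comparison of within-ROI connectivity,
    # post-injection runs only
    roi_per_run = dualreg.dual_regress(roi_reg, comps, None, per_run=True)
    roi_maps_sel = {
        key: zmaps[retained] for key, zmaps in roi_per_run.z_maps.items()
    }
    post_runs = list(range(1, run_spec.n_runs))
    run_comparisons = run_pair_comparisons(
        roi_maps_sel, phantom.roi_mask, roi_reg.voxel_index,
        retained, dataset.n_subjects, post_runs,
        config.inference.n_perm, config.seed + 7919,
        config.inference.tfce_params(), config.inference.alpha_roi,
    )

    selection = cpl.select_inflammation_regions(coupling_table, run_comparisons)

    # final analysis: whole-brain one-sample inference per selected component
    brain = phantom.brain_mask
    box = _bbox(brain)
    final: dict[int, PermutationResult] = {}
    for c in selection.selected:
        subj_stack = np.stack([
            _maps_to_volumes(wb_maps.z_maps[s][c:c + 1],
                             wb_matrix.voxel_index, brain.shape)[0][box]
            for s in range(dataset.n_subjects)
        ])
        final[c] = inference.permutation_onesample_ttest(
            subj_stack, n_perm=config.inference.n_perm,
            seed=config.seed + 104729 + c,
            tfce_params=config.inference.tfce_params(),
            alpha=config.inference.alpha_wb, mask=brain[box],
        )

    # network similarity of the selected components' unthresholded maps
    similarity = None
    if len(selection.selected) >= 2:
        sel_maps = group_z[selection.selected]
        sim_mat = networks.spatial_correlation_matrix(
            sel_maps, labels=[f"comp{c}" for c in selection.selected]
        )
        similarity, _ = networks.complete_linkage_clusters(sim_mat)

    # serum change tests (baseline vs 120 min, per subject)
    serum_tests = {}
    t_base = float(dataset.serum_group.times_min[
        np.flatnonzero(dataset.serum_group.times_min <= run_spec.run_start_min[1])[-1]
    ])
    for marker in ("tnf", "acth"):
        base = np.array([s.value_at(marker, t_base)
                         for s in dataset.serum_subjects])
        t120 = np.array([s.value_at(marker, 120.0)
                         for s in dataset.serum_subjects])
        serum_tests[marker] = cpl.serum_change_test(base, t120)

    return PipelineResult(
        config=config,
        dataset=dataset,
        components=comps,
        specificity=spec_report,
        retained=retained,
        coupling_table=coupling_table,
        run_comparisons=run_comparisons,
        selection=selection,
        wholebrain_group_z=group_z,
        brain_voxel_index=wb_matrix.voxel_index,
        final_inference=final,
        similarity=similarity,
        serum_tests=serum_tests,
        group_timecourses=group_tc,
    )


def match_components_to_sources(
    comps: ComponentSet, truth_maps: np.ndarray
) -> dict[int, int]:
    """Greedy matching of estimated components to ground-truth sources by
    absolute spatial correlation over the mask voxels.

    Returns ``{source_index: component_index}``.
    """
    vidx = tuple(comps.voxel_index.T)
    truth_flat = np.asarray(truth_maps)[(slice(None),) + vidx]  # (K, V)
    d, k = comps.n_components, truth_flat.shape[0]
    corr = np.zeros((k, d))
    for i in range(k):
        for j in range(d):
            a, b = truth_flat[i], comps.maps_z[j]
            sa, sb = a.std(), b.std()
            corr[i, j] = 0.0 if sa == 0 or sb == 0 else abs(
                np.corrcoef(a, b)[0, 1]
            )
    matching: dict[int, int] = {}
    used: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(corr, axis=None)[::-1],
                                       corr.shape))[0]
    for i, j in order:
        i, j = int(i), int(j)
        if i in matching or j in used:
            continue
        matching[i] = j
        used.add(j)
        if len(matching) == min(k, d):
            break
    return matching
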