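"""Dual regression: group spatial maps → subject time courses → subject maps.

Stage 1 regresses each subject's masked data on the group component maps
(across voxels, per time point), yielding subject-specific time courses.
Stage 2 regresses every voxel's series on those time courses (across time),
yielding subject-specific beta and z maps.  Stage 1 always uses the ROI
voxels the components were estimated on; stage 2 may target any mask (ROI or
whole brain) and may be split per run for paired run comparisons.
"""

from __future__ import annotations

import numpy as np

from .containers import ComponentSet, MaskedMatrix, SubjectComponentMaps

__all__ = ["stage1_timecourses", "stage2_maps", "dual_regress"]

_COND_LIMIT = 1e8


def stage1_timecourses(
    subject_matrix: np.ndarray,
    maps: np.ndarray,
    demean_maps: bool = True,
) -> np.ndarray:
    """OLS of data rows on spatial maps: time courses = X · pinv(S).

    ``subject_matrix`` is T × V, ``maps`` d × V (each map demeaned over
    voxels before solving by default; ``demean_maps=False`` skips this —
    over a small mask the subtracted mean couples every component's time
    course to every other component's signal, so sparse-support regressors
    without demeaning can be preferable there).  Raises a conditioning
    error for collinear maps.
    """
    x = np.asarray(subject_matrix, dtype=float)
    s = np.asarray(maps, dtype=float)
    if x.shape[1] != s.shape[1]:
        raise ValueError("data and maps disagree on the number of voxels")
    if demean_maps:
        s = s - s.mean(axis=1, keepdims=True)
    cond = np.linalg.cond(s @ s.T)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"component maps are collinear (condition number {cond:.3g})"
        )
    return x @ np.linalg.pinv(s)


def stage2_maps(
    subject_matrix: np.ndarray,
    timecourses: np.ndarray,
    variance_normalize_tc: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise OLS of the data on the stage-1 time courses.

    Time courses are demeaned over time (and optionally scaled to unit
    variance); each voxel's series is demeaned.  Returns ``(beta, z)`` maps,
    both d × V, where z = beta / SE(beta) with the residual-variance-based
    standard error at T − d − 1 degrees of freedom.
    """
    x = np.asarray(subject_matrix, dtype=float)
    a = np.asarray(timecourses, dtype=float)
    t, d = a.shape
    if x.shape[0] != t:
        raise ValueError("data and timecourses disagree on the number of rows")
    if t < d + 2:
        raise np.linalg.LinAlgError(
            f"rank-deficient design: T={t} rows for d={d} regressors"
        )
    a = a - a.mean(axis=0, keepdims=True)
    if variance_normalize_tc:
        sd = a.std(axis=0, keepdims=True)
        if np.any(sd == 0):
            raise np.linalg.LinAlgError("zero-variance time course in design")
        a = a / sd
    gram = a.T @ a
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"collinear time courses (condition number {cond:.3g})"
        )
    xd = x - x.mean(axis=0, keepdims=True)
    gram_inv = np.linalg.inv(gram)
    beta = gram_inv @ (a.T @ xd)  # (d, V)
    resid = xd - a @ beta
    dof = t - d - 1
    sigma2 = (resid**2).sum(axis=0) / dof  # (V,)
    se = np.sqrt(np.outer(np.diag(gram_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    return beta, z


def _stage2_maps_loo(
    subject_matrix: np.ndarray,
    timecourses: np.ndarray,
    pinv_rows: np.ndarray,
    variance_normalize_tc: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage 2 with the target voxel's stage-1 contribution removed.

    When stage 1 and stage 2 use the same voxels, each voxel's own noise
    enters its regressors through its stage-1 projection weight
    (``pinv_rows[v]``), producing a deterministic bias shared by every
    subject — negligible for whole-brain masks but sizeable for masks of a
    few hundred voxels.  This variant performs, per voxel, OLS on the
    rank-one-downdated design ``A − x_v ⊗ pinv_rows[v]``, which removes the
    voxel's own contribution from its regressors exactly, in closed form.
    """
    x = np.asarray(subject_matrix, dtype=float)
    a = np.asarray(timecourses, dtype=float)
    w = np.asarray(pinv_rows, dtype=float)  # (V, d)
    t, d = a.shape
    if t < d + 2:
        raise np.linalg.LinAlgError(
            f"rank-deficient design: T={t} rows for d={d} regressors"
        )
    xd = x - x.mean(axis=0, keepdims=True)
    ad = a - a.mean(axis=0, keepdims=True)
    g = ad.T @ ad  # (d, d)
    u = ad.T @ xd  # (d, V)
    q = (xd**2).sum(axis=0)  # (V,)
    ut = u.T  # (V, d)
    gram = (
        g[None, :, :]
        - ut[:, :, None] * w[:, None, :]
        - w[:, :, None] * ut[:, None, :]
        + q[:, None, None] * (w[:, :, None] * w[:, None, :])
    )  # (V, d, d)
    rhs = ut - q[:, None] * w  # (V, d)
    beta = np.linalg.solve(gram, rhs[..., None])[..., 0]  # (V, d)
    resid_ss = np.clip(q - (rhs * beta).sum(axis=1), 0.0, None)
    dof = t - d - 1
    sigma2 = resid_ss / dof
    gram_inv_diag = np.diagonal(np.linalg.inv(gram), axis1=1, axis2=2)
    se = np.sqrt(np.clip(sigma2[:, None] * gram_inv_diag, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    if variance_normalize_tc:
        # report betas on the unit-variance-regressor scale (z unaffected)
        sd_cols = np.sqrt(np.clip(np.diagonal(gram, axis1=1, axis2=2), 0, None) / t)
        beta = beta * sd_cols
    return beta.T, z.T  # (d, V)


def _split_by_subject(matrix: MaskedMatrix) -> dict[int, list[tuple[int, tuple[int, int]]]]:
    per_subject: dict[int, list[tuple[int, tuple[int, int]]]] = {}
    for (s, r), (a, b) in matrix.block_bounds:
        per_subject.setdefault(s, []).append((r, (a, b)))
    return per_subject


def dual_regress(
    roi_matrix: MaskedMatrix,
    maps: ComponentSet | np.ndarray,
    target_matrix: MaskedMatrix | None = None,
    per_run: bool = False,
    variance_normalize_tc: bool = True,
    exclude_target_voxel: bool = True,
    demean_maps: bool = True,
) -> SubjectComponentMaps:
    """Run both stages for every subject in a concatenated dataset.

    ``roi_matrix`` holds the masked voxels the component maps live on (stage
    1 input).  ``target_matrix`` holds the voxels to project onto in stage 2
    (defaults to the ROI itself; pass a whole-brain matrix for whole-brain
    connectivity profiles).  With ``per_run`` the stage-2 regression is done
    separately per (subject, run) block using that block's rows of the
    stage-1 time courses — the input for paired run comparisons.

    When stage 2 targets the same voxels stage 1 was computed from and
    ``exclude_target_voxel`` is set (the default), each voxel's stage-1
    contribution is removed from its own stage-2 regressors (exact rank-one
    downdate), eliminating the small-mask self-noise bias.
    """
    map_arr = maps.maps_z if isinstance(maps, ComponentSet) else np.asarray(maps)
    if map_arr.shape[1] != roi_matrix.n_voxels:
        raise ValueError("maps and roi_matrix disagree on the number of voxels")
    same_target = target_matrix is None or target_matrix is roi_matrix
    if target_matrix is None:
        target_matrix = roi_matrix
    if target_matrix.n_rows != roi_matrix.n_rows:
        raise ValueError("roi and target matrices must share their row layout")
    use_loo = exclude_target_voxel and same_target
    pinv_rows = None
    if use_loo:
        s_dm = map_arr
        if demean_maps:
            s_dm = s_dm - s_dm.mean(axis=1, keepdims=True)
        pinv_rows = np.linalg.pinv(s_dm)  # (V, d)

    roi_by_subj = _split_by_subject(roi_matrix)
    tgt_by_subj = _split_by_subject(target_matrix)

    timecourses: dict[int, np.ndarray] = {}
    beta_maps: dict = {}
    z_maps: dict = {}
    for s in sorted(roi_by_subj):
        blocks = sorted(roi_by_subj[s])
        rows = np.concatenate([roi_matrix.values[a:b] for _r, (a, b) in blocks])
        tc = stage1_timecourses(rows, map_arr, demean_maps=demean_maps)
        timecourses[s] = tc
        tgt_blocks = sorted(tgt_by_subj[s])
        if per_run:
            offset = 0
            for (r, (a, b)), (_rt, (at, bt)) in zip(blocks, tgt_blocks):
                n = b - a
                tc_run = tc[offset:offset + n]
                offset += n
                if use_loo:
                    beta, z = _stage2_maps_loo(
                        target_matrix.values[at:bt], tc_run, pinv_rows,
                        variance_normalize_tc=variance_normalize_tc,
                    )
                else:
                    beta, z = stage2_maps(
                        target_matrix.values[at:bt], tc_run,
                        variance_normalize_tc=variance_normalize_tc,
                    )
                beta_maps[(s, r)] = beta
                z_maps[(s, r)] = z
        else:
            tgt_rows = np.concatenate(
                [target_matrix.values[a:b] for _r, (a, b) in tgt_blocks]
            )
            if use_loo:
                beta, z = _stage2_maps_loo(
                    tgt_rows, tc, pinv_rows,
                    variance_normalize_tc=variance_normalize_tc,
                )
            else:
                beta, z = stage2_maps(
                    tgt_rows, tc, variance_normalize_tc=variance_normalize_tc
                )
            beta_maps[s] = beta
            z_maps[s] = z

    return SubjectComponentMaps(
        timecourses=timecourses,
        beta_maps=beta_maps,
        z_maps=z_maps,
        target_voxel_index=target_matrix.voxel_index,
        target_grid_shape=target_matrix.grid_shape,
        per_run=per_run,
    )
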