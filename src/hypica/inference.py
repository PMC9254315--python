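"""Nonparametric permutation inference with TFCE and max-statistic FWE.

Threshold-free cluster enhancement integrates cluster extent and height over
all thresholds:  TFCE(v) = Σ_h e(h, v)^E · h^H · dh, summed from h = dh up
to the statistic at v, where e(h, v) is the voxel count of the connected
suprathreshold cluster containing v at height h.  Negative statistic values
are processed by enhancing the negated map and negating the result.

The permutation engines build the null by sign flipping (one-sample t on
subject maps, or on paired differences), enumerate all 2^n sign patterns
when that is within the permutation budget (then ``exhaustive=True``), and
correct family-wise error with the distribution of the maximum |TFCE| over
the analysis mask.  The identity permutation is always included, so the
attainable minimum p is 1 / n_permutations; ties count against rejection
(>= comparison).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

from .containers import PermutationResult, TfceParams

__all__ = [
    "tfce",
    "permutation_paired_ttest",
    "permutation_onesample_ttest",
    "permutation_paired_family",
]

_T_CAP = 1e6  # zero-variance, nonzero-mean voxels get a capped statistic

# Robust clip for the voxelwise t before enhancement.  With a handful of
# subjects the extreme tail of the sign-flip t reflects near-zero variance
# denominators (a few |differences| that happen to align), not effect
# evidence; unclipped, single such voxels dominate the maximum-TFCE null
# and destroy power.  Clipping is applied identically to the observed and
# every permuted map, so the test remains exact.
DEFAULT_STAT_CLIP = 20.0


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def _tfce_positive(stat: np.ndarray, params: TfceParams, dh: float) -> np.ndarray:
    """TFCE of the nonnegative part of a 3D map."""
    out = np.zeros_like(stat, dtype=float)
    top = float(stat.max())
    if top <= 0 or dh <= 0:
        return out
    structure = _structure(params.connectivity)
    h = dh
    while h <= top + 1e-12:
        supra = stat >= h
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab == 0:
            break
        sizes = np.bincount(labels.ravel())
        contrib = (sizes**params.E) * (h**params.H) * dh
        out[supra] += contrib[labels[supra]]
        h += dh
    return out


def tfce(stat_map: np.ndarray, params: TfceParams | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed 3D statistic map."""
    stat = np.asarray(stat_map, dtype=float)
    if stat.ndim != 3:
        raise ValueError("tfce expects a 3D statistic map")
    if not np.all(np.isfinite(stat)):
        raise ValueError("statistic map contains NaN or Inf")
    if params is None:
        params = TfceParams()
    dh = params.dh
    if dh is None:
        peak = float(np.max(np.abs(stat)))
        if peak == 0:
            return np.zeros_like(stat)
        dh = peak / params.n_steps
    pos = _tfce_positive(np.where(stat > 0, stat, 0.0), params, dh)
    neg = _tfce_positive(np.where(stat < 0, -stat, 0.0), params, dh)
    return pos - neg


def _one_sample_t(maps: np.ndarray) -> np.ndarray:
    """One-sample t over axis 0, with 0/0 -> 0 and sd=0, mean!=0 capped."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    t[zero_sd & (mean == 0)] = 0.0
    t[zero_sd & (mean != 0)] = np.sign(mean[zero_sd & (mean != 0)]) * _T_CAP
    return t


def _sign_patterns(
    n_subjects: int, n_perm: int, seed: int
) -> tuple[np.ndarray, bool]:
    """Sign-flip matrix (n_perm × n), identity first; exhaustive if 2^n fits."""
    if 2**n_subjects <= n_perm:
        signs = np.array(
            list(itertools.product((1.0, -1.0), repeat=n_subjects))
        )
        # put the identity (all +1) first; itertools already yields it first
        return signs, True
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_perm, n_subjects))
    signs[0] = 1.0  # the identity permutation is always included
    return signs, False


def _signflip_test(
    maps: np.ndarray,
    n_perm: int,
    seed: int,
    tfce_params: TfceParams | None,
    mask: np.ndarray | None,
    alternative: str = "greater",
    stat_clip: float | None = DEFAULT_STAT_CLIP,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, bool]:
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("expected maps of shape (n_subjects, nx, ny, nz)")
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    if tfce_params is None:
        tfce_params = TfceParams()
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != maps.shape[1:]:
            raise ValueError("mask grid does not match the maps")
        maps = maps * mask  # out-of-mask voxels carry no statistic

    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    signs, exhaustive = _sign_patterns(n, n_perm, seed)
    n_perm_eff = signs.shape[0]

    clip = np.inf if stat_clip is None else float(stat_clip)

    def _stat(m):
        return np.clip(_one_sample_t(m), -clip, clip)

    stat_obs = _one_sample_t(maps)
    tfce_obs = tfce(np.clip(stat_obs, -clip, clip), tfce_params)
    # 'greater' follows the standard permutation-tool convention (one tail,
    # signed maximum; attainable minimum p = 1/n_perm); 'two-sided' uses the
    # |TFCE| maximum, an exact two-tailed test whose attainable p values are
    # multiples of 2/n_perm because sign patterns come in (s, -s) pairs.
    obs_ref = tfce_obs if alternative == "greater" else np.abs(tfce_obs)

    def _null_max(tf: np.ndarray) -> float:
        v = tf if alternative == "greater" else np.abs(tf)
        return float(v[mask].max() if mask is not None else v.max())

    exceed = np.zeros_like(obs_ref)
    for p in range(n_perm_eff):
        if p == 0:
            max_null = _null_max(tfce_obs)
        else:
            t_map = _stat(signs[p][:, None, None, None] * maps)
            max_null = _null_max(tfce(t_map, tfce_params))
        exceed += max_null >= obs_ref
    p_map = exceed / n_perm_eff
    if mask is not None:
        p_map = np.where(mask, p_map, 1.0)
    return stat_obs, tfce_obs, p_map, n_perm_eff, exhaustive


def permutation_onesample_ttest(
    maps: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    tfce_params: TfceParams | None = None,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
    alternative: str = "greater",
    stat_clip: float | None = DEFAULT_STAT_CLIP,
) -> PermutationResult:
    """Sign-flip one-sample t test with TFCE max-statistic FWE correction.

    ``maps`` is (n_subjects, nx, ny, nz); the null flips each subject's map
    about zero.  ``alternative='greater'`` tests the positive direction
    (negate the maps for the other tail); ``'two-sided'`` corrects over the
    maximum |TFCE|.  A binary map thresholded at ``alpha`` is emitted
    alongside the statistic, TFCE and FWE-p maps.
    """
    stat, tf, p_map, n_eff, exhaustive = _signflip_test(
        maps, n_perm, seed, tfce_params, mask, alternative, stat_clip
    )
    return PermutationResult(
        stat_map=stat,
        tfce_map=tf,
        fwe_p_map=p_map,
        n_permutations=n_eff,
        seed=seed,
        exhaustive=exhaustive,
        alpha=alpha,
        threshold_map=p_map < alpha,
    )


def permutation_paired_ttest(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    tfce_params: TfceParams | None = None,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
    alternative: str = "greater",
    stat_clip: float | None = DEFAULT_STAT_CLIP,
) -> PermutationResult:
    """Sign-flip paired t test (one-sample t on subject difference maps)."""
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired map stacks must have equal shapes")
    stat, tf, p_map, n_eff, exhaustive = _signflip_test(
        a - b, n_perm, seed, tfce_params, mask, alternative, stat_clip
    )
    return PermutationResult(
        stat_map=stat,
        tfce_map=tf,
        fwe_p_map=p_map,
        n_permutations=n_eff,
        seed=seed,
        exhaustive=exhaustive,
        alpha=alpha,
        threshold_map=p_map < alpha,
    )


def permutation_paired_family(
    pairs: dict,
    n_perm: int = 5000,
    seed: int = 0,
    tfce_params: TfceParams | None = None,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
    stat_clip: float | None = DEFAULT_STAT_CLIP,
) -> dict:
    """Paired sign-flip tests over a family of condition pairs with a single
    max-statistic FWE correction across voxels *and* pairs.

    ``pairs`` maps a key (e.g. a run pair) to ``(maps_a, maps_b)`` stacks of
    shape (n_subjects, nx, ny, nz) sharing their subjects.  The same sign
    pattern is applied to every pair's difference maps per permutation, and
    the null maximum is taken over the whole family, so p < alpha anywhere
    controls the family-wise error of the entire comparison set.  Two-sided
    (maximum |TFCE|).  Returns ``{key: PermutationResult}`` with the
    family-corrected p maps.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    if tfce_params is None:
        tfce_params = TfceParams()
    diffs = {}
    n = None
    for key, (a, b) in pairs.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.ndim != 4:
            raise ValueError("paired map stacks must be 4D and equal shaped")
        if n is None:
            n = a.shape[0]
        elif a.shape[0] != n:
            raise ValueError("all pairs must share their subjects")
        d = a - b
        if mask is not None:
            d = d * mask
        diffs[key] = d
    if n < 2:
        raise ValueError("need at least 2 subjects")

    signs, exhaustive = _sign_patterns(n, n_perm, seed)
    n_eff = signs.shape[0]
    clip = np.inf if stat_clip is None else float(stat_clip)
    stat_obs = {k: _one_sample_t(d) for k, d in diffs.items()}
    tfce_obs = {k: tfce(np.clip(s, -clip, clip), tfce_params)
                for k, s in stat_obs.items()}

    def _family_max(tf_maps: dict) -> float:
        vals = []
        for tf_map in tf_maps.values():
            v = np.abs(tf_map)
            vals.append(float(v[mask].max() if mask is not None else v.max()))
        return max(vals)

    exceed = {k: np.zeros_like(v) for k, v in tfce_obs.items()}
    for p in range(n_eff):
        if p == 0:
            fam = _family_max(tfce_obs)
        else:
            s4 = signs[p][:, None, None, None]
            fam = _family_max({
                k: tfce(np.clip(_one_sample_t(s4 * d), -clip, clip),
                        tfce_params)
                for k, d in diffs.items()
            })
        for k in exceed:
            exceed[k] += fam >= np.abs(tfce_obs[k])
    out = {}
    for k in diffs:
        p_map = exceed[k] / n_eff
        if mask is not None:
            p_map = np.where(mask, p_map, 1.0)
        out[k] = PermutationResult(
            stat_map=stat_obs[k],
            tfce_map=tfce_obs[k],
            fwe_p_map=p_map,
            n_permutations=n_eff,
            seed=seed,
            exhaustive=exhaustive,
            alpha=alpha,
            threshold_map=p_map < alpha,
        )
    return out
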