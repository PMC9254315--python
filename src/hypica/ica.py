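"""Masked spatial ICA: PCA whitening, fixed-point component estimation,
Gaussian–Gamma mixture thresholding and dimensionality scanning.

The decomposition is spatial: the time-by-voxel matrix X (T × V) is modelled
as X = A S with d spatially independent maps S (d × V) and mixing time
courses A (T × d).  Estimation reduces X to d dimensions by SVD (whitening
the voxel representation), then maximises non-Gaussianity of the maps with a
symmetric fixed-point iteration (log-cosh contrast).  Sign ambiguity is
resolved by orienting every map to positive skew; components are ordered by
explained variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import eigh

from .containers import ComponentSet, MaskedMatrix

__all__ = [
    "WhitenedData",
    "reduce_and_whiten",
    "estimate_components",
    "mixture_threshold",
    "MixtureFit",
    "scan_dimensionalities",
]


@dataclass
class WhitenedData:
    """Spatially whitened data plus the operator mapping back to time rows.

    ``z`` (d × V) satisfies z zᵀ / V = I; ``back`` (T × d) maps unmixed
    sources back to mixing time courses; ``retained_variance`` is the
    fraction of total variance kept by the rank-d reduction.
    """

    z: np.ndarray
    back: np.ndarray
    retained_variance: float
    voxel_index: np.ndarray
    grid_shape: tuple[int, int, int]


def reduce_and_whiten(matrix: MaskedMatrix, d: int) -> WhitenedData:
    """SVD reduction of the masked matrix to d spatial dimensions.

    Raises a rank error when d exceeds the numerical rank of the data.
    """
    x = matrix.values
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    if d > min(x.shape):
        raise ValueError(
            f"d={d} exceeds min(rows, columns) = {min(x.shape)}"
        )
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(x.shape) * np.finfo(float).eps))
    if d > rank:
        raise ValueError(f"d={d} exceeds the numerical rank {rank} of the data")
    v = x.shape[1]
    z = vt[:d] * np.sqrt(v)  # whitened: z @ z.T / V = I
    back = u[:, :d] * (s[:d] / np.sqrt(v))  # X ≈ back @ z
    total = float(np.sum(s**2))
    retained = float(np.sum(s[:d] ** 2) / total) if total > 0 else 1.0
    return WhitenedData(
        z=z,
        back=back,
        retained_variance=retained,
        voxel_index=matrix.voxel_index,
        grid_shape=matrix.grid_shape,
    )


def _symmetric_decorrelation(w: np.ndarray) -> np.ndarray:
    s, u = eigh(w @ w.T)
    s = np.clip(s, 1e-12, None)
    return (u / np.sqrt(s)) @ u.T @ w


def _fixed_point(
    z: np.ndarray, w0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, bool, int]:
    """Symmetric FastICA iteration with the log-cosh contrast."""
    n = z.shape[1]
    w = _symmetric_decorrelation(w0)
    for it in range(max_iter):
        s = w @ z
        g = np.tanh(s)
        g_prime = (1.0 - g**2).mean(axis=1)
        w_new = (g @ z.T) / n - g_prime[:, None] * w
        w_new = _symmetric_decorrelation(w_new)
        delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", w_new, w)) - 1.0)))
        w = w_new
        if delta < tol:
            return w, True, it + 1
    return w, False, max_iter


def _negentropy_proxy(s: np.ndarray) -> float:
    # E[log cosh s] for a standard normal is ~0.3746
    return float(np.sum((np.mean(np.log(np.cosh(s)), axis=1) - 0.37457) ** 2))


def estimate_components(
    whitened: WhitenedData,
    d: int | None = None,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    restarts: int = 3,
    threshold: bool = True,
) -> ComponentSet:
    """Estimate spatially independent maps from whitened data.

    Runs ``restarts`` fixed-point iterations from seeded random rotations and
    keeps the best converged solution (highest log-cosh negentropy proxy).
    Non-convergence of all restarts yields the best attempt with
    ``converged=False`` and a warning.  Deterministic given the seed.
    """
    z = whitened.z
    if d is None:
        d = z.shape[0]
    if d != z.shape[0]:
        raise ValueError("d must match the whitened dimensionality")
    best = None
    for attempt in range(restarts):
        rng = np.random.default_rng(seed + 1000 * attempt)
        w0 = rng.standard_normal((d, d))
        w, conv, n_iter = _fixed_point(z, w0, max_iter, tol)
        score = _negentropy_proxy(w @ z)
        cand = (conv, score, attempt, w, n_iter)
        if best is None:
            best = cand
        else:
            # prefer converged; among equals, higher negentropy
            if (conv, score) > (best[0], best[1]):
                best = cand
    conv, _score, _attempt, w, _n_iter = best
    if not conv:
        warnings.warn(
            f"fixed-point ICA did not converge in {max_iter} iterations "
            f"({restarts} restarts); returning the best attempt",
            RuntimeWarning,
        )
    maps = w @ z  # (d, V), unit variance rows
    mixing = whitened.back @ w.T  # (T, d)

    # orient to positive skew
    skews = stats.skew(maps, axis=1)
    flip = np.where(skews < 0, -1.0, 1.0)
    maps = maps * flip[:, None]
    mixing = mixing * flip[None, :]

    # order by explained variance (norm of the mixing column; map rows are
    # unit variance so this is each component's share of data variance)
    ev = (mixing**2).sum(axis=0)
    order = np.argsort(ev)[::-1]
    maps = maps[order]
    mixing = mixing[:, order]
    ev = ev[order]

    maps_z = np.empty_like(maps)
    thr = np.zeros(maps.shape, dtype=bool)
    fallback = np.zeros(d, dtype=bool)
    for k in range(d):
        if threshold:
            fit = mixture_threshold(maps[k])
            maps_z[k] = (maps[k] - fit.mu0) / fit.sigma0
            thr[k] = fit.retained
            fallback[k] = fit.fallback
        else:
            maps_z[k] = (maps[k] - maps[k].mean()) / max(maps[k].std(), 1e-12)

    return ComponentSet(
        maps_z=maps_z,
        mixing=mixing,
        voxel_index=whitened.voxel_index,
        grid_shape=whitened.grid_shape,
        threshold_maps=thr,
        converged=bool(conv),
        explained_variance=ev,
        threshold_fallback=fallback,
        maps_raw=maps,
    )


@dataclass
class MixtureFit:
    """Gaussian background + shifted-Gamma signal mixture fit of a map."""

    mu0: float
    sigma0: float
    weight_signal: float
    gamma_shape: float
    gamma_scale: float
    gamma_loc: float
    retained: np.ndarray
    fallback: bool
    converged: bool
    n_iter: int


def mixture_threshold(
    map_values: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    min_signal_weight: float = 0.01,
) -> MixtureFit:
    """Threshold a component map with a two-class mixture model.

    Fits (by EM) a Gaussian background class plus a shifted-Gamma positive
    tail to the map values; voxels with posterior signal probability > 0.5
    are retained.  If the fit degenerates (signal weight below 1 %, or
    non-convergence) the threshold falls back to |z| > 3 relative to the
    background fit, with the fallback flagged.
    """
    x = np.asarray(map_values, dtype=float).ravel()
    if x.size < 50:
        raise ValueError("mixture fit needs at least 50 voxels")
    if np.ptp(x) < 1e-12:
        raise ValueError("constant map: mixture fit is degenerate")

    # initialisation: background from the bulk, signal from the top tail
    q95 = np.quantile(x, 0.95)
    bg0 = x[x < q95]
    mu0, sigma0 = float(bg0.mean()), float(max(bg0.std(), 1e-6))
    loc = q95
    sig0_vals = x[x >= q95]
    pi1 = max(len(sig0_vals) / x.size, 1e-3)
    m = float(max(sig0_vals.mean() - loc, 1e-6))
    v = float(max(sig0_vals.var(), 1e-12))
    shape, scale = max(m * m / v, 0.2), v / m

    converged = False
    it = 0
    prev_ll = -np.inf
    resp = None
    for it in range(1, max_iter + 1):
        # E step
        pdf0 = stats.norm.pdf(x, mu0, sigma0) * (1.0 - pi1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pdf1 = stats.gamma.pdf(x, shape, loc=loc, scale=scale) * pi1
        pdf1 = np.nan_to_num(pdf1)
        total = pdf0 + pdf1
        total[total <= 0] = 1e-300
        resp = pdf1 / total
        ll = float(np.log(total).sum())
        # M step
        pi1 = float(resp.mean())
        if pi1 < 1e-6:
            break
        w0 = 1.0 - resp
        mu0 = float((w0 * x).sum() / w0.sum())
        sigma0 = float(np.sqrt((w0 * (x - mu0) ** 2).sum() / w0.sum()))
        sigma0 = max(sigma0, 1e-6)
        w1 = resp
        w1sum = w1.sum()
        loc_new = mu0 + 0.5 * sigma0  # keep the signal class in the tail
        shifted = np.clip(x - loc_new, 1e-9, None)
        m = float((w1 * shifted).sum() / w1sum)
        v = float((w1 * (shifted - m) ** 2).sum() / w1sum)
        v = max(v, 1e-12)
        loc, shape, scale = loc_new, max(m * m / v, 0.2), v / m
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            converged = True
            break
        prev_ll = ll

    fallback = (not converged) or (pi1 < min_signal_weight)
    if fallback:
        z = (x - mu0) / sigma0
        retained = z > 3.0
    else:
        retained = resp > 0.5
    return MixtureFit(
        mu0=mu0,
        sigma0=sigma0,
        weight_signal=float(pi1),
        gamma_shape=float(shape),
        gamma_scale=float(scale),
        gamma_loc=float(loc),
        retained=retained,
        fallback=bool(fallback),
        converged=bool(converged),
        n_iter=it,
    )


def scan_dimensionalities(
    matrix: MaskedMatrix,
    d_range: list[int],
    seed: int = 0,
    **ica_kwargs,
) -> dict[int, dict]:
    """Estimate components for each dimensionality in ``d_range``.

    Emits, per d, the ComponentSet plus summary statistics (map sparsity and
    inter-map overlap) and a winner-take-all label volume.  The choice of
    the 'anatomically correct' dimensionality is a human judgement: this
    function only supports the inspection, it does not automate it.
    """
    if len(d_range) == 0:
        raise ValueError("d_range must not be empty")
    out: dict[int, dict] = {}
    for d in d_range:
        whitened = reduce_and_whiten(matrix, d)
        comps = estimate_components(whitened, d, seed=seed, **ica_kwargs)
        absz = np.abs(comps.maps_z)
        sparsity = (absz > 2.0).mean(axis=1)
        if d > 1:
            sup = comps.threshold_maps
            denom = np.maximum(
                sup.sum(axis=1)[:, None], 1
            )
            overlap = (sup[:, None, :] & sup[None, :, :]).sum(axis=2) / denom
            np.fill_diagonal(overlap, 0.0)
            max_overlap = float(overlap.max())
        else:
            max_overlap = 0.0
        out[d] = {
            "components": comps,
            "retained_variance": whitened.retained_variance,
            "sparsity": sparsity,
            "max_pairwise_overlap": max_overlap,
            "label_volume": comps.label_volume(),
        }
    return out
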