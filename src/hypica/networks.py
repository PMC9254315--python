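"""Similarity of whole-brain connectivity maps.

Pairwise spatial Pearson correlation of the unthresholded maps over an
analysis mask, followed by complete-linkage agglomerative clustering of the
correlation-matrix rows under Euclidean distance (the convention of the
usual heat-map tooling: items that correlate with everything else in the
same way cluster together).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import SimilarityMatrix

__all__ = [
    "spatial_correlation_matrix",
    "complete_linkage_clusters",
    "similarity_to_frame",
    "linkage_to_newick",
    "plot_heatmap",
]


def spatial_correlation_matrix(
    maps: np.ndarray,
    analysis_mask: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> SimilarityMatrix:
    """Pairwise Pearson correlation of unthresholded maps over a mask.

    ``maps`` is (m, nx, ny, nz) or already-flat (m, V).  Raises an error
    naming any zero-variance map.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 4:
        if analysis_mask is not None:
            mask = np.asarray(analysis_mask).astype(bool)
            if mask.shape != maps.shape[1:]:
                raise ValueError("analysis mask grid does not match the maps")
            if mask.sum() == 0:
                raise ValueError("analysis mask is empty")
            flat = maps[:, mask]
        else:
            flat = maps.reshape(maps.shape[0], -1)
    elif maps.ndim == 2:
        flat = maps if analysis_mask is None else maps[:, np.asarray(analysis_mask).astype(bool).ravel()]
    else:
        raise ValueError("maps must be (m, V) or (m, nx, ny, nz)")
    m = flat.shape[0]
    if labels is None:
        labels = [f"map{i}" for i in range(m)]
    if len(labels) != m:
        raise ValueError("labels length must match the number of maps")
    sds = flat.std(axis=1)
    for i, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(f"map {labels[i]!r} has zero variance over the mask")
    r = np.corrcoef(flat)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(labels=tuple(labels), r_matrix=r)


def complete_linkage_clusters(
    sim: SimilarityMatrix, n_clusters: int | None = None
) -> tuple[SimilarityMatrix, np.ndarray | None]:
    """Complete-linkage clustering of the correlation-matrix rows.

    Distances are Euclidean distances between rows of ``r_matrix``.  Ties
    are broken deterministically by label (input) order, which is scipy's
    behaviour for equal merge heights.  Returns the similarity object with
    ``linkage`` and ``leaf_order`` filled in, plus flat cluster assignments
    when ``n_clusters`` is requested (cutting the tree; when the requested
    count is not attainable by a horizontal cut, the next finer partition is
    returned, down to singletons).
    """
    m = sim.n_maps
    if m < 2:
        raise ValueError("need at least 2 maps to cluster")
    d = pdist(sim.r_matrix, metric="euclidean")
    link = hierarchy.linkage(d, method="complete")
    heights = link[:, 2]
    if np.any(np.diff(heights) < -1e-10):
        raise AssertionError("complete-linkage heights must be nondecreasing")
    leaf_order = np.asarray(hierarchy.leaves_list(link))
    out = SimilarityMatrix(labels=sim.labels, r_matrix=sim.r_matrix)
    out.linkage = link
    out.leaf_order = leaf_order
    flat = None
    if n_clusters is not None:
        if not 1 <= n_clusters <= m:
            raise ValueError(f"n_clusters must be in [1, {m}]")
        flat = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    return out, flat


def similarity_to_frame(sim: SimilarityMatrix) -> pd.DataFrame:
    """The correlation matrix as a labelled DataFrame (CSV twin of the
    heat map)."""
    return pd.DataFrame(sim.r_matrix, index=sim.labels, columns=sim.labels)


def linkage_to_newick(sim: SimilarityMatrix) -> str:
    """Serialise the dendrogram as a Newick string with branch lengths."""
    if sim.linkage is None:
        raise ValueError("run complete_linkage_clusters first")
    link = sim.linkage
    m = sim.n_maps
    heights = {i: 0.0 for i in range(m)}
    nodes = {i: sim.labels[i] for i in range(m)}
    for i, (a, b, h, _cnt) in enumerate(link):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nid = m + i
        nodes[nid] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[nid] = h
    return nodes[m + len(link) - 1] + ";"


def plot_heatmap(sim: SimilarityMatrix, path: str) -> None:
    """SVG heat map of the correlation matrix in dendrogram leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = sim.leaf_order if sim.leaf_order is not None else np.arange(sim.n_maps)
    r = sim.r_matrix[np.ix_(order, order)]
    labels = [sim.labels[i] for i in order]
    fig, ax = plt.subplots(figsize=(4 + 0.3 * len(labels), 3.5 + 0.3 * len(labels)))
    im = ax.imshow(r, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(labels)), labels, rotation=90)
    ax.set_yticks(range(len(labels)), labels)
    fig.colorbar(im, ax=ax, label="spatial r")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
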