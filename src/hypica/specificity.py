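"""Tissue-specificity filtering of components.

A component whose whole-brain activation sits in white matter or CSF rather
than grey matter is unlikely to be neural.  Each component gets a weighted
quotient Q of grey-matter versus white-matter-plus-CSF activation, and
components with Q more than one standard deviation below the mean across
components are excluded::

    Q = [Σ_v gm(v)·|z(v)| / Σ_v gm(v)] / [Σ_v (wm+csf)(v)·|z(v)| / Σ_v (wm+csf)(v)]

Absolute z is used so anticorrelated but tissue-specific components are not
penalised.  A zero denominator (no activation mass in WM/CSF) is flagged and
treated as maximally specific.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import SpecificityReport, TissuePhantom

__all__ = ["tissue_quotient", "flag_unspecific", "report_to_frame"]


def tissue_quotient(zmap: np.ndarray, tissue: TissuePhantom) -> float:
    """Weighted GM vs WM+CSF activation quotient of a whole-brain map.

    ``zmap`` may be a full 3D volume on the phantom grid or a flat vector
    paired with the phantom's brain-mask voxels.
    """
    zmap = np.asarray(zmap, dtype=float)
    gm = tissue.gm_prob
    wmcsf = tissue.wm_prob + tissue.csf_prob
    if zmap.shape == tissue.grid_shape:
        az = np.abs(zmap)
    elif zmap.ndim == 1 and zmap.size == int(tissue.brain_mask.sum()):
        az = np.zeros(tissue.grid_shape)
        az[tissue.brain_mask] = np.abs(zmap)
    else:
        raise ValueError(
            f"zmap shape {zmap.shape} matches neither the phantom grid "
            f"{tissue.grid_shape} nor its brain-mask voxel count"
        )
    gm_mass = gm.sum()
    wmcsf_mass = wmcsf.sum()
    if gm_mass <= 0:
        raise ValueError("phantom has zero grey-matter weight mass")
    num = (gm * az).sum() / gm_mass
    den = (wmcsf * az).sum() / wmcsf_mass if wmcsf_mass > 0 else 0.0
    if den == 0:
        return np.inf
    return float(num / den)


def flag_unspecific(quotients: np.ndarray) -> SpecificityReport:
    """Apply the 1-SD exclusion rule to per-component quotients.

    Uses the sample (n−1) standard deviation across components.  Infinite
    quotients (zero WM/CSF mass) are flagged, treated as maximally specific
    (never excluded) and left out of the mean/SD computation.
    """
    q = np.asarray(quotients, dtype=float)
    if q.ndim != 1 or len(q) < 3:
        raise ValueError("need at least 3 components for the 1-SD rule")
    denom_zero = ~np.isfinite(q)
    finite = q[~denom_zero]
    if len(finite) >= 2:
        mean_q = float(finite.mean())
        sd_q = float(finite.std(ddof=1))
    else:
        mean_q, sd_q = float("nan"), 0.0
    excluded = np.zeros(len(q), dtype=bool)
    if np.isfinite(mean_q):
        excluded = (q < mean_q - sd_q) & ~denom_zero
    return SpecificityReport(
        quotients=q,
        mean_q=mean_q,
        sd_q=sd_q,
        excluded=excluded,
        denominator_zero=denom_zero,
    )


def report_to_frame(report: SpecificityReport) -> pd.DataFrame:
    """CSV-ready table: component, Q, excluded."""
    return pd.DataFrame(
        {
            "component": np.arange(len(report.quotients)),
            "Q": report.quotients,
            "excluded": report.excluded,
            "denominator_zero": report.denominator_zero,
        }
    )
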