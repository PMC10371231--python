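"""Group-average speed maps and voxel-wise two-sample comparison maps.

Subject speed maps (assumed spatially aligned) are smoothed with a 0.4 mm
FWHM Gaussian and compared voxel-by-voxel with a pooled-variance
independent two-sample t test, reported as one-sided p maps in both
directions.  As is common in voxel-wise small-animal studies, no
multiple-testing adjustment is applied by default; a Benjamini-Hochberg FDR
option is available as a clearly labelled extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats as sps

from .grids import ImageGrid
from .preprocess import gaussian_smooth

__all__ = ["GroupStudy", "StatMap", "smooth_and_average", "ttest_map"]


@dataclass
class GroupStudy:
    """Two aligned cohorts of speed maps plus analysis settings."""

    group_a: List[np.ndarray]
    group_b: List[np.ndarray]
    grid: ImageGrid
    mask: Optional[np.ndarray] = None
    fwhm_mm: float = 0.4
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("need at least 2 subjects per group")
        shape = self.grid.dims
        for m in list(self.group_a) + list(self.group_b):
            if np.asarray(m).shape != shape:
                raise ValueError("all speed maps must share the study grid")
        if self.mask is None:
            self.mask = np.ones(shape, bool)
        else:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != shape:
                raise ValueError("analysis mask must share the study grid")


@dataclass
class StatMap:
    t: np.ndarray
    p_a_gt_b: np.ndarray  # one-sided p for mean(A) > mean(B)
    p_b_gt_a: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    df: int
    sig_a_gt_b: np.ndarray
    sig_b_gt_a: np.ndarray
    excluded: np.ndarray  # in-mask voxels with zero pooled variance
    alpha: float
    provenance: dict = field(default_factory=dict)


def _smoothed_stack(maps: List[np.ndarray], study: GroupStudy) -> np.ndarray:
    vs = study.grid.voxel_size_mm
    return np.stack([gaussian_smooth(m, study.fwhm_mm, vs) for m in maps])


def smooth_and_average(study: GroupStudy) -> Tuple[np.ndarray, np.ndarray]:
    """Per-group voxel-wise means of the smoothed subject maps."""
    a = _smoothed_stack(study.group_a, study)
    b = _smoothed_stack(study.group_b, study)
    return a.mean(axis=0), b.mean(axis=0)


def ttest_map(study: GroupStudy) -> StatMap:
    """Pooled-variance two-sample t map with one-sided p values both ways.

    Voxels with zero pooled variance are flagged in ``excluded`` and carry
    ``t = 0`` and ``p = 1``.  Voxels outside the analysis mask carry
    ``p = 1`` and are never significant.
    """
    a = _smoothed_stack(study.group_a, study)
    b = _smoothed_stack(study.group_b, study)
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    ss_a = ((a - mean_a) ** 2).sum(axis=0)
    ss_b = ((b - mean_b) ** 2).sum(axis=0)
    pooled_var = (ss_a + ss_b) / df
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    zero_var = se == 0
    t = np.zeros_like(mean_a)
    np.divide(mean_a - mean_b, se, out=t, where=~zero_var)
    p_a = np.where(zero_var, 1.0, sps.t.sf(t, df))
    p_b = np.where(zero_var, 1.0, sps.t.sf(-t, df))
    mask = study.mask
    p_a = np.where(mask, p_a, 1.0)
    p_b = np.where(mask, p_b, 1.0)
    # "significant" follows a two-sided test at alpha, split by direction
    crit = study.alpha / 2.0
    sig_a = mask & ~zero_var & (p_a < crit)
    sig_b = mask & ~zero_var & (p_b < crit)
    return StatMap(
        t=t,
        p_a_gt_b=p_a,
        p_b_gt_a=p_b,
        mean_a=mean_a,
        mean_b=mean_b,
        df=df,
        sig_a_gt_b=sig_a,
        sig_b_gt_a=sig_b,
        excluded=mask & zero_var,
        alpha=study.alpha,
        provenance={
            "n_a": na,
            "n_b": nb,
            "fwhm_mm": study.fwhm_mm,
            "test": "pooled-variance independent two-sample t",
            "multiple_testing": "none (FDR available via fdr_correct)",
        },
    )


def fdr_correct(p: np.ndarray, mask: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Optional extension to the default protocol: Benjamini-Hochberg FDR mask."""
    mask = np.asarray(mask, bool)
    pv = p[mask]
    if pv.size == 0:
        return np.zeros_like(mask)
    order = np.argsort(pv)
    ranked = pv[order]
    n = pv.size
    thresh = alpha * (np.arange(1, n + 1)) / n
    passing = ranked <= thresh
    out = np.zeros_like(mask)
    if passing.any():
        k = np.max(np.flatnonzero(passing))
        cut = ranked[k]
        sel = np.zeros(n, bool)
        sel[pv <= cut] = True
        out[mask] = sel
    return out
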