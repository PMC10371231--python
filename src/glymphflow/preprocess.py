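"""Preprocessing of dynamic contrast-enhanced series for the transport solver.

Raw signal series are converted to voxel-wise percent signal change from a
pre-contrast baseline, smoothed with a small isotropic Gaussian kernel
(default FWHM 0.1 mm), restricted to the analysis window (default ~100
minutes), and floored to a strictly positive density before entering the
mass-transport solver.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import DCESeries, PercentChangeSeries

__all__ = [
    "PreprocessConfig",
    "percent_change",
    "gaussian_smooth",
    "smooth_series",
    "select_frames",
    "apply_density_floor",
    "fwhm_to_sigma_vox",
    "preprocess_series",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class PreprocessConfig:
    fwhm_mm: float = 0.1
    window_duration_min: float = 100.0
    floor_epsilon_frac: float = 1e-4  # density floor as a fraction of the series max
    smooth_before_percent_change: bool = False  # default: smooth the ratio images

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        if self.window_duration_min <= 0:
            raise ValueError("window_duration_min must be positive")


def percent_change(series: DCESeries) -> PercentChangeSeries:
    """Voxel-wise percent signal change from the mean of the baseline frames.

    Voxels whose baseline mean is <= 0 are set to 0 in every frame and
    flagged in ``invalid_baseline``.
    """
    if not series.baseline_indices:
        raise ValueError("series has no baseline frames; set baseline_indices")
    base = series.frames[list(series.baseline_indices)].mean(axis=0)
    invalid = base <= 0
    safe = np.where(invalid, 1.0, base)
    pc = 100.0 * (series.frames - base) / safe
    pc[:, invalid] = 0.0
    return PercentChangeSeries(
        pc,
        series.frame_times_s,
        series.grid,
        invalid_baseline=invalid,
        provenance={"baseline_indices": list(series.baseline_indices)},
    )


def fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm: np.ndarray) -> np.ndarray:
    """Per-axis Gaussian sigma in voxels for a given FWHM in mm."""
    return fwhm_mm / FWHM_TO_SIGMA / np.atleast_1d(np.asarray(voxel_size_mm, float))


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Isotropic Gaussian smoothing specified by FWHM in physical mm.

    Reflective boundaries, which preserve the total sum of the volume;
    ``fwhm_mm = 0`` is the identity.  On anisotropic grids the sigma is
    computed per axis and a warning is logged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    vs = np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))
    if vs.size == 1:
        vs = np.repeat(vs, 3)
    if not np.allclose(vs, vs[0]):
        logger.warning("anisotropic voxels %s: per-axis smoothing sigma applied", vs)
        warnings.warn("anisotropic voxels: per-axis smoothing sigma applied")
    sigma = fwhm_to_sigma_vox(fwhm_mm, vs)
    return gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma, mode="reflect")


def smooth_series(pc: PercentChangeSeries, fwhm_mm: float) -> PercentChangeSeries:
    vs = pc.grid.voxel_size_mm
    frames = np.stack([gaussian_smooth(f, fwhm_mm, vs) for f in pc.frames])
    prov = dict(pc.provenance)
    prov["smoothing_fwhm_mm"] = fwhm_mm
    return PercentChangeSeries(
        frames, pc.frame_times_s, pc.grid, pc.invalid_baseline, prov
    )


def select_frames(
    pc: PercentChangeSeries, window_duration_min: float
) -> PercentChangeSeries:
    """Keep frames with time <= first frame time + window duration."""
    if pc.n_frames == 0:
        raise ValueError("series is empty")
    t0 = pc.frame_times_s[0]
    keep = pc.frame_times_s <= t0 + window_duration_min * 60.0
    n_keep = int(keep.sum())
    if n_keep < 2:
        raise ValueError(
            f"analysis window of {window_duration_min} min retains {n_keep} frame(s); "
            "the solver needs at least an adjacent pair"
        )
    prov = dict(pc.provenance)
    prov["window_duration_min"] = window_duration_min
    prov["frames_retained"] = n_keep
    return PercentChangeSeries(
        pc.frames[keep], pc.frame_times_s[keep], pc.grid, pc.invalid_baseline, prov
    )


def apply_density_floor(
    pc: PercentChangeSeries, floor_epsilon_frac: float = 1e-4
) -> PercentChangeSeries:
    """Clamp percent-change values at >= 0 and offset by a small positive floor.

    Optimal mass transport requires nonnegative mass; measurement noise
    produces small negative percent-change values.  The floor is
    ``floor_epsilon_frac * max(series)``.
    """
    peak = float(pc.frames.max())
    eps = floor_epsilon_frac * peak if peak > 0 else floor_epsilon_frac
    frames = np.maximum(pc.frames, 0.0) + eps
    prov = dict(pc.provenance)
    prov["density_floor"] = eps
    return PercentChangeSeries(
        frames, pc.frame_times_s, pc.grid, pc.invalid_baseline, prov
    )


def preprocess_series(
    series, config: PreprocessConfig | None = None, already_percent_change: bool = False
) -> PercentChangeSeries:
    """percent-change -> smooth -> window -> density floor, per configuration.

    Whether smoothing precedes or follows the percent-change conversion is
    configurable (``smooth_before_percent_change``); the default smooths the
    percent-change frames.
    """
    config = config or PreprocessConfig()
    if already_percent_change or getattr(series, "units", None) == "percent_change":
        pc = PercentChangeSeries(
            series.frames, series.frame_times_s, series.grid, provenance={}
        )
        if config.fwhm_mm > 0:
            pc = smooth_series(pc, config.fwhm_mm)
    elif config.smooth_before_percent_change and config.fwhm_mm > 0:
        from dataclasses import replace as _replace

        smoothed = np.stack(
            [
                gaussian_smooth(f, config.fwhm_mm, series.grid.voxel_size_mm)
                for f in series.frames
            ]
        )
        pc = percent_change(_replace(series, frames=smoothed))
        pc.provenance["smoothing_fwhm_mm"] = config.fwhm_mm
        pc.provenance["smoothing_order"] = "before percent change"
    else:
        pc = percent_change(series)
        if config.fwhm_mm > 0:
            pc = smooth_series(pc, config.fwhm_mm)
    pc = select_frames(pc, config.window_duration_min)
    return apply_density_floor(pc, config.floor_epsilon_frac)
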