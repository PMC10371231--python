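"""Lymph-node time-signal curves: extraction, normalisation and kinetics.

A time-signal curve (TSC) is the mean in-VOI signal of a dynamic series
versus time.  Node TSCs are normalised to the subject's CSF signal (the
CSF VOI acts as the reference input function), denoised with a trailing
2-point moving average, and summarised by time-to-peak, peak magnitude and
trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .grids import DCESeries

__all__ = ["TSC", "TSCMetrics", "extract_and_normalize", "smooth_tsc", "tsc_metrics"]


@dataclass
class TSC:
    """A time-signal curve in minutes / arbitrary units."""

    times_min: np.ndarray
    values_au: np.ndarray
    node: str = ""
    side: str = ""
    normalized: bool = False
    volume_mm3: float = np.nan
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float).ravel()
        self.values_au = np.asarray(self.values_au, dtype=float).ravel()
        if self.times_min.size != self.values_au.size:
            raise ValueError("times and values must have equal length")
        if self.times_min.size and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class TSCMetrics:
    time_to_peak_min: float
    peak_magnitude_au: float
    auc_au_min: float
    node: str = ""
    side: str = ""
    volume_mm3: float = np.nan


def extract_and_normalize(
    series: DCESeries,
    voi_masks: Dict[str, np.ndarray],
    csf_mask: np.ndarray,
    divisor: str = "max",
) -> List[TSC]:
    """Extract per-VOI mean TSCs and normalise them to the CSF signal.

    Each node curve is divided by the ``divisor`` (``"max"`` or ``"mean"``)
    of the subject's CSF curve.  The CSF curve itself is returned
    unnormalised (last element) for provenance.  Node volume is the VOI
    voxel count times the voxel volume.
    """
    csf_mask = np.asarray(csf_mask, dtype=bool)
    if csf_mask.shape != series.grid.dims:
        raise ValueError("CSF mask shape does not match series grid")
    if not csf_mask.any():
        raise ValueError("CSF mask is empty")
    times_min = series.frame_times_s / 60.0
    csf_curve = series.frames[:, csf_mask].mean(axis=1)
    if divisor == "max":
        denom = float(csf_curve.max())
    elif divisor == "mean":
        denom = float(csf_curve.mean())
    else:
        raise ValueError(f"unknown CSF divisor {divisor!r} (use 'max' or 'mean')")
    if denom <= 0:
        raise ValueError("CSF reference signal is non-positive; cannot normalize")
    vol = series.grid.voxel_volume_mm3
    out: List[TSC] = []
    for name, mask in voi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != series.grid.dims:
            raise ValueError(f"VOI {name!r} shape does not match series grid")
        if not mask.any():
            raise ValueError(f"VOI {name!r} is empty")
        curve = series.frames[:, mask].mean(axis=1)
        out.append(
            TSC(
                times_min,
                curve / denom,
                node=name,
                normalized=True,
                volume_mm3=mask.sum() * vol,
                provenance={"csf_divisor": divisor, "csf_reference": denom},
            )
        )
    out.append(
        TSC(
            times_min,
            csf_curve,
            node="CSF",
            normalized=False,
            volume_mm3=csf_mask.sum() * vol,
            provenance={"csf_divisor": divisor},
        )
    )
    return out


def smooth_tsc(tsc: TSC) -> TSC:
    """Trailing 2-point moving average; the output keeps the later time stamp.

    Output length is input length - 1.
    """
    if tsc.times_min.size < 2:
        raise ValueError("need at least 2 points for the 2-step moving average")
    values = 0.5 * (tsc.values_au[1:] + tsc.values_au[:-1])
    prov = dict(tsc.provenance)
    prov["smoothed"] = "trailing 2-point moving average"
    return TSC(
        tsc.times_min[1:],
        values,
        node=tsc.node,
        side=tsc.side,
        normalized=tsc.normalized,
        volume_mm3=tsc.volume_mm3,
        provenance=prov,
    )


def tsc_metrics(tsc: TSC, window_min: Optional[float] = None) -> TSCMetrics:
    """Time-to-peak (earliest global maximum), peak magnitude and trapezoidal AUC.

    ``window_min`` restricts the analysis to times <= window_min (measured
    from the first time point); by default the full curve is used.
    """
    t, y = tsc.times_min, tsc.values_au
    if window_min is not None:
        sel = t <= t[0] + window_min
        t, y = t[sel], y[sel]
    if t.size == 0:
        raise ValueError("analysis window contains no time points")
    i_peak = int(np.argmax(y))  # argmax returns the first maximum: earliest wins
    auc = float(np.trapezoid(y, t)) if t.size > 1 else 0.0
    return TSCMetrics(
        time_to_peak_min=float(t[i_peak]),
        peak_magnitude_au=float(y[i_peak]),
        auc_au_min=auc,
        node=tsc.node,
        side=tsc.side,
        volume_mm3=tsc.volume_mm3,
    )
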