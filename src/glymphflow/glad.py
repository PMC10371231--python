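"""Lagrangian post-processing of the estimated velocity fields.

Solute trajectories ("pathlines") are traced through the per-substep
velocity fields of the interval solutions by RK4 integration, one step per
substep, concatenated across intervals.  Per-step speeds (|v| at the
current point, in um/s) are deposited into voxels to form speed maps, from
which compartment metrics follow: the mean solute speed (average of all
strictly positive voxel speeds in a mask) and the volume transport flux
(v-flux: volume of voxels visited by retained pathlines).  Velocity flux
vectors connect each retained pathline's start to its endpoint and capture
how far and in which direction solute is transported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .grids import ImageGrid
from .romt import IntervalSolution

__all__ = [
    "GladConfig",
    "Pathline",
    "Pathlines",
    "SpeedMap",
    "TransportMetrics",
    "FluxVector",
    "trace_pathlines",
    "speed_map",
    "transport_metrics",
    "flux_vectors",
]


@dataclass
class GladConfig:
    """Seeding and retention rules; both thresholds are this package's choices."""

    seed_threshold_frac: float = 0.1  # fraction of in-mask max first-frame density
    retention_min_displacement_vox: float = 0.5


@dataclass
class Pathline:
    """One traced trajectory: physical positions and per-step speeds."""

    positions_mm: np.ndarray  # (n_steps + 1, 3)
    speeds_um_s: np.ndarray  # (n_steps + 1,)
    seed_voxel: np.ndarray  # (3,) int
    retained: bool


class Pathlines(Sequence):
    """A bundle of pathlines sharing one grid (sequence of :class:`Pathline`)."""

    def __init__(
        self,
        positions_mm: np.ndarray,
        speeds_um_s: np.ndarray,
        seed_voxels: np.ndarray,
        retained: np.ndarray,
        grid: ImageGrid,
    ) -> None:
        self.positions_mm = positions_mm
        self.speeds_um_s = speeds_um_s
        self.seed_voxels = seed_voxels
        self.retained = np.asarray(retained, bool)
        self.grid = grid

    def __len__(self) -> int:
        return int(self.positions_mm.shape[0])

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return Pathline(
            self.positions_mm[i],
            self.speeds_um_s[i],
            self.seed_voxels[i],
            bool(self.retained[i]),
        )

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass
class SpeedMap:
    values_um_s: np.ndarray
    grid: ImageGrid
    provenance: dict = field(default_factory=dict)


@dataclass
class TransportMetrics:
    mean_speed_um_s: float
    v_flux_mm3: float
    compartment: str = "whole_brain"
    n_positive_voxels: int = 0


@dataclass
class FluxVector:
    start_mm: np.ndarray
    displacement_mm: np.ndarray

    @property
    def magnitude_mm(self) -> float:
        return float(np.linalg.norm(self.displacement_mm))


def _sample_velocity(v: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Trilinear sample of a (nx,ny,nz,3) field at index-space positions (P,3)."""
    dims = v.shape[:3]
    p = np.clip(pos, 0.0, np.asarray(dims, float) - 1.0)
    i0 = np.floor(p).astype(np.int64)
    for a in range(3):
        np.minimum(i0[:, a], dims[a] - 2, out=i0[:, a])
    f = p - i0
    out = np.zeros((pos.shape[0], 3))
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1.0 - f[:, 0]
        for dy in (0, 1):
            wy = f[:, 1] if dy else 1.0 - f[:, 1]
            for dz in (0, 1):
                wz = f[:, 2] if dz else 1.0 - f[:, 2]
                out += (wx * wy * wz)[:, None] * v[
                    i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz
                ]
    return out


def trace_pathlines(
    solutions: List[IntervalSolution],
    mask: Optional[np.ndarray] = None,
    config: Optional[GladConfig] = None,
) -> Pathlines:
    """Trace solute trajectories through all interval solutions.

    Seeds are the centres of in-mask voxels whose first-frame density
    exceeds ``seed_threshold_frac`` of the in-mask maximum.  Integration is
    RK4 through the trilinearly interpolated velocity, piecewise constant in
    pseudo-time, one RK4 step per substep; positions are clamped to the
    grid.  A pathline is retained when its total start-to-end displacement
    is at least ``retention_min_displacement_vox`` voxels.
    """
    config = config or GladConfig()
    if not solutions:
        raise ValueError("need at least one interval solution")
    grid = solutions[0].velocity.grid
    for s in solutions[1:]:
        if s.velocity.grid.dims != grid.dims:
            raise ValueError("interval solutions do not share a grid")
    dims = grid.dims
    if mask is None:
        mask = np.ones(dims, bool)
    mask = np.asarray(mask, bool)

    rho0 = solutions[0].trajectory[0]
    in_mask_max = rho0[mask].max() if mask.any() else 0.0
    threshold = config.seed_threshold_frac * in_mask_max
    seed_sel = mask & (rho0 > threshold)
    if not seed_sel.any():
        raise ValueError(
            f"no seed voxels: no in-mask density exceeds threshold {threshold:.4g} "
            f"({config.seed_threshold_frac:.0%} of in-mask max {in_mask_max:.4g})"
        )
    seed_idx = np.argwhere(seed_sel)
    pos = seed_idx.astype(float)  # voxel centres, index coordinates
    n_seeds = pos.shape[0]

    total_steps = sum(s.velocity.n_substeps for s in solutions)
    positions = np.empty((n_seeds, total_steps + 1, 3))
    speeds = np.empty((n_seeds, total_steps + 1))
    positions[:, 0] = pos
    step = 0
    last_scale = solutions[-1].velocity.vox_per_substep_to_um_s
    for sol in solutions:
        vf = sol.velocity
        scale = vf.vox_per_substep_to_um_s
        for k in range(vf.n_substeps):
            vk = vf.v[k]
            v_here = _sample_velocity(vk, pos)
            speeds[:, step] = np.linalg.norm(v_here, axis=1) * scale
            k1 = v_here
            k2 = _sample_velocity(vk, pos + 0.5 * k1)
            k3 = _sample_velocity(vk, pos + 0.5 * k2)
            k4 = _sample_velocity(vk, pos + k3)
            pos = pos + (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            np.clip(pos, 0.0, np.asarray(dims, float) - 1.0, out=pos)
            step += 1
            positions[:, step] = pos
    v_final = _sample_velocity(solutions[-1].velocity.v[-1], pos)
    speeds[:, total_steps] = np.linalg.norm(v_final, axis=1) * last_scale

    disp = np.linalg.norm(positions[:, -1] - positions[:, 0], axis=1)
    retained = disp >= config.retention_min_displacement_vox
    positions_mm = grid.index_to_mm(positions)
    return Pathlines(positions_mm, speeds, seed_idx, retained, grid)


def speed_map(pathlines: Pathlines, grid: Optional[ImageGrid] = None) -> SpeedMap:
    """Deposit per-step speeds of retained pathlines; voxel value = mean deposit.

    A voxel counts as visited when an RK4 endpoint lies inside it;
    segments crossing a voxel between endpoints are not rasterised.
    """
    grid = grid or pathlines.grid
    dims = grid.dims
    n_flat = int(np.prod(dims))
    sums = np.zeros(n_flat)
    counts = np.zeros(n_flat)
    ret = pathlines.retained
    if ret.any():
        pos_idx = grid.mm_to_index(pathlines.positions_mm[ret])
        vox = np.rint(pos_idx).astype(np.int64)
        for a in range(3):
            np.clip(vox[..., a], 0, dims[a] - 1, out=vox[..., a])
        flat = (vox[..., 0] * dims[1] + vox[..., 1]) * dims[2] + vox[..., 2]
        sp = pathlines.speeds_um_s[ret]
        sums = np.bincount(flat.ravel(), weights=sp.ravel(), minlength=n_flat)
        counts = np.bincount(flat.ravel(), minlength=n_flat).astype(float)
    values = np.zeros(n_flat)
    visited = counts > 0
    values[visited] = sums[visited] / counts[visited]
    return SpeedMap(
        values.reshape(dims),
        grid,
        provenance={"n_pathlines": len(pathlines), "n_retained": pathlines.n_retained},
    )


def transport_metrics(
    smap: SpeedMap, mask: np.ndarray, compartment: str = "whole_brain"
) -> TransportMetrics:
    """Mean of strictly positive in-mask speeds, and visited volume (v-flux)."""
    mask = np.asarray(mask, bool)
    if mask.shape != smap.grid.dims:
        raise ValueError("mask shape does not match speed map grid")
    if not mask.any():
        raise ValueError(f"empty mask for compartment {compartment!r}")
    vals = smap.values_um_s[mask]
    pos = vals[vals > 0]
    mean_speed = float(pos.mean()) if pos.size else 0.0
    v_flux = float(pos.size * smap.grid.voxel_volume_mm3)
    return TransportMetrics(mean_speed, v_flux, compartment, int(pos.size))


def flux_vectors(pathlines: Pathlines) -> List[FluxVector]:
    """Start-to-end displacement vector of every retained pathline."""
    out = []
    for i in np.flatnonzero(pathlines.retained):
        start = pathlines.positions_mm[i, 0]
        end = pathlines.positions_mm[i, -1]
        out.append(FluxVector(start_mm=start.copy(), displacement_mm=end - start))
    return out
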