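"""Image grids, 4D series containers and coordinate conventions.

Conventions used throughout the package:

* Volumes are ``numpy`` arrays of shape ``(nx, ny, nz)``; 4D series are
  ``(n_frames, nx, ny, nz)``.
* Voxel indices are 0-based.  The physical position of the centre of voxel
  ``(i, j, k)`` is ``(i + 0.5, j + 0.5, k + 0.5) * voxel_size_mm``.
* All pathline geometry is expressed in physical millimetres; solver
  internals work in voxel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

__all__ = ["ImageGrid", "DCESeries", "PercentChangeSeries"]


@dataclass
class ImageGrid:
    """A regular 3D voxel grid with optional named binary masks.

    Parameters
    ----------
    dims:
        Number of voxels per axis, ``(nx, ny, nz)``.
    voxel_size_mm:
        Isotropic voxel edge length in mm (anisotropic grids pass a
        3-vector).
    origin_mm:
        Physical position of the corner of voxel (0,0,0).
    masks:
        Named binary volumes (``brain``, ``csf``, ``tissue``, VOIs ...).
        CSF and tissue masks are expected to be disjoint subsets of brain.
    """

    dims: tuple
    voxel_size_mm: float | Sequence[float] = 0.3
    origin_mm: Sequence[float] = (0.0, 0.0, 0.0)
    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three positive ints, got {self.dims}")
        vs = np.atleast_1d(np.asarray(self.voxel_size_mm, dtype=float))
        if vs.size == 1:
            vs = np.repeat(vs, 3)
        if vs.size != 3 or np.any(vs <= 0):
            raise ValueError("voxel_size_mm must be positive (scalar or 3-vector)")
        self.voxel_size_mm = vs
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        for name, m in self.masks.items():
            m = np.asarray(m)
            if m.shape != self.dims:
                raise ValueError(
                    f"mask {name!r} has shape {m.shape}, grid dims are {self.dims}"
                )
            self.masks[name] = m.astype(bool)
        # compartment consistency: CSF and tissue are disjoint subsets of brain
        if "brain" in self.masks:
            for name in ("csf", "tissue"):
                if name in self.masks and np.any(
                    self.masks[name] & ~self.masks["brain"]
                ):
                    raise ValueError(f"{name!r} mask extends outside the brain mask")
        if "csf" in self.masks and "tissue" in self.masks and np.any(
            self.masks["csf"] & self.masks["tissue"]
        ):
            raise ValueError("csf and tissue masks overlap")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def isotropic(self) -> bool:
        return bool(np.allclose(self.voxel_size_mm, self.voxel_size_mm[0]))

    def voxel_centers_mm(self) -> np.ndarray:
        """Physical centre coordinates, shape ``dims + (3,)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(d) for d in self.dims], indexing="ij"), axis=-1
        )
        return self.origin_mm + (idx + 0.5) * self.voxel_size_mm

    def index_to_mm(self, pos_idx: np.ndarray) -> np.ndarray:
        """Continuous index coordinates -> physical mm (voxel centre at integer index)."""
        pos_idx = np.asarray(pos_idx, dtype=float)
        return self.origin_mm + (pos_idx + 0.5) * self.voxel_size_mm

    def mm_to_index(self, pos_mm: np.ndarray) -> np.ndarray:
        pos_mm = np.asarray(pos_mm, dtype=float)
        return (pos_mm - self.origin_mm) / self.voxel_size_mm - 0.5

    def full_mask(self) -> np.ndarray:
        return np.ones(self.dims, dtype=bool)

    def mask(self, name: Optional[str]) -> np.ndarray:
        """Return a named mask, or an all-true mask for ``None``."""
        if name is None:
            return self.full_mask()
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(f"grid has no mask named {name!r}; have {sorted(self.masks)}")


@dataclass
class DCESeries:
    """An ordered dynamic contrast-enhanced series (raw signal units)."""

    frames: np.ndarray  # (n_frames, nx, ny, nz)
    frame_times_s: np.ndarray
    grid: ImageGrid
    baseline_indices: Sequence[int] = ()
    units: str = "signal"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be 4D (n_frames, nx, ny, nz)")
        if self.frames.shape[0] != self.frame_times_s.size:
            raise ValueError("frame count and frame_times_s length differ")
        if self.frames.shape[1:] != self.grid.dims:
            raise ValueError("frame shape does not match grid dims")
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame_times_s must be strictly increasing")
        self.baseline_indices = tuple(int(i) for i in self.baseline_indices)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class PercentChangeSeries:
    """Percent-signal-change series: 100*(S - S_base)/S_base per voxel."""

    frames: np.ndarray
    frame_times_s: np.ndarray
    grid: ImageGrid
    invalid_baseline: Optional[np.ndarray] = None  # voxels with S_base <= 0
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.frames.shape[0] != self.frame_times_s.size:
            raise ValueError("frame count and frame_times_s length differ")
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame_times_s must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_interval_s(self) -> float:
        """Median inter-frame spacing in seconds."""
        return float(np.median(np.diff(self.frame_times_s)))
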