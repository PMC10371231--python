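"""Reading and writing the pipeline's file formats.

NIfTI-1 for volumes and 4D/5D series (via nibabel), HDF5 for pathline
bundles, CSV for traces/curves/metrics and JSON for provenance.  Affines
are diagonal with the voxel size in mm; the origin is the corner of voxel
(0,0,0).
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Dict, Tuple

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .glad import Pathlines, SpeedMap
from .grids import DCESeries, ImageGrid, PercentChangeSeries
from .icp import ICPRecording
from .romt import VelocityField
from .tsc import TSC

__all__ = [
    "save_volume",
    "load_volume",
    "save_series",
    "load_series",
    "save_velocity",
    "load_velocity",
    "save_pathlines",
    "load_pathlines",
    "save_icp_csv",
    "load_icp_csv",
    "save_tsc_csv",
    "load_tsc_csv",
    "save_json",
]


def _affine(grid: ImageGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.voxel_size_mm
    aff[:3, 3] = grid.origin_mm
    return aff


def save_volume(path, volume: np.ndarray, grid: ImageGrid) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float64), _affine(grid)), str(path))


def load_volume(path) -> Tuple[np.ndarray, ImageGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    vs = np.abs(np.diag(img.affine)[:3])
    grid = ImageGrid(data.shape[:3], vs, img.affine[:3, 3])
    return data, grid


def save_series(path, series) -> None:
    """Save a DCESeries or PercentChangeSeries as 4D NIfTI (x,y,z,t) + JSON sidecar."""
    frames = np.moveaxis(series.frames, 0, -1)  # (x,y,z,t)
    nib.save(nib.Nifti1Image(frames, _affine(series.grid)), str(path))
    side = {
        "frame_times_s": list(map(float, series.frame_times_s)),
        "baseline_indices": list(getattr(series, "baseline_indices", ())),
        "units": getattr(series, "units", "percent_change"),
    }
    Path(str(path) + ".json").write_text(json.dumps(side, indent=2))


def load_series(path, percent_change: bool = False):
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    vs = np.abs(np.diag(img.affine)[:3])
    grid = ImageGrid(data.shape[1:], vs, img.affine[:3, 3])
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        times = np.asarray(side["frame_times_s"])
        baseline = side.get("baseline_indices", [])
        units = side.get("units", "signal")
    else:
        times = np.arange(data.shape[0], dtype=float)
        baseline, units = [], "signal"
    if percent_change or units == "percent_change":
        return PercentChangeSeries(data, times, grid)
    return DCESeries(data, times, grid, baseline_indices=baseline, units=units)


def save_velocity(path, vf: VelocityField) -> None:
    """Velocity as HDF5: (m, nx, ny, nz, 3) voxels/substep plus metadata."""
    with h5py.File(str(path), "w") as f:
        d = f.create_dataset("velocity_vox_per_substep", data=vf.v)
        d.attrs["frame_interval_s"] = vf.frame_interval_s
        d.attrs["voxel_size_mm"] = vf.grid.voxel_size_mm
        d.attrs["origin_mm"] = vf.grid.origin_mm


def load_velocity(path) -> VelocityField:
    with h5py.File(str(path), "r") as f:
        d = f["velocity_vox_per_substep"]
        v = d[...]
        grid = ImageGrid(v.shape[1:4], d.attrs["voxel_size_mm"], d.attrs["origin_mm"])
        return VelocityField(v, grid, float(d.attrs["frame_interval_s"]))


def save_pathlines(path, pl: Pathlines) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("positions_mm", data=pl.positions_mm)
        f.create_dataset("speeds_um_s", data=pl.speeds_um_s)
        f.create_dataset("seed_voxels", data=pl.seed_voxels)
        f.create_dataset("retained", data=pl.retained)
        f.attrs["voxel_size_mm"] = pl.grid.voxel_size_mm
        f.attrs["dims"] = pl.grid.dims
        f.attrs["origin_mm"] = pl.grid.origin_mm


def load_pathlines(path) -> Pathlines:
    with h5py.File(str(path), "r") as f:
        grid = ImageGrid(
            tuple(f.attrs["dims"]), f.attrs["voxel_size_mm"], f.attrs["origin_mm"]
        )
        return Pathlines(
            f["positions_mm"][...],
            f["speeds_um_s"][...],
            f["seed_voxels"][...],
            f["retained"][...],
            grid,
        )


def save_speed_map(path, smap: SpeedMap) -> None:
    save_volume(path, smap.values_um_s, smap.grid)


def save_flux_vectors_vtk(path, vectors) -> None:
    """Velocity flux vectors as a legacy-ASCII VTK polydata point set.

    Points are pathline starts; a VECTORS attribute holds the displacement,
    so standard viewers can render the field as glyphs.
    """
    lines = [
        "# vtk DataFile Version 3.0",
        "velocity flux vectors",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vectors)} float",
    ]
    for v in vectors:
        lines.append(f"{v.start_mm[0]:.6f} {v.start_mm[1]:.6f} {v.start_mm[2]:.6f}")
    lines.append(f"POINT_DATA {len(vectors)}")
    lines.append("VECTORS displacement float")
    for v in vectors:
        d = v.displacement_mm
        lines.append(f"{d[0]:.6f} {d[1]:.6f} {d[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_icp_csv(path, rec: ICPRecording) -> None:
    pd.DataFrame(
        {"time_s": rec.times_s(), "pressure_mmHg": rec.samples_mmhg}
    ).to_csv(path, index=False)


def load_icp_csv(path, epochs: Dict[str, Tuple[float, float]] | None = None) -> ICPRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("ICP CSV needs at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("ICP CSV must be uniformly sampled")
    return ICPRecording(df["pressure_mmHg"].to_numpy(), 1.0 / dt[0], epochs or {})


def save_tsc_csv(path, tsc: TSC) -> None:
    pd.DataFrame({"time_min": tsc.times_min, "signal_au": tsc.values_au}).to_csv(
        path, index=False
    )


def load_tsc_csv(path, node: str = "", normalized: bool = True) -> TSC:
    df = pd.read_csv(path)
    return TSC(
        df["time_min"].to_numpy(), df["signal_au"].to_numpy(), node=node,
        normalized=normalized,
    )


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
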