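"""Ground-truthed synthetic inputs for the transport, ICP and TSC analyses.

The phantom generator emulates a dynamic contrast-enhanced acquisition: a
Gaussian tracer bolus (percent-signal-change units) transported by a known
velocity field with diffusion on a 3D grid, imaged every ~5 minutes over a
~100-minute window.  To keep recovery tests honest, the forward simulation
never uses the solver's own transport operator: it integrates the
advection-diffusion equation

    drho/dt + div(rho v) = sigma * laplace(rho)

with an explicit conservative upwind scheme on a grid refined 2x in space,
with CFL-limited substeps (at least 4 per frame interval), under zero-flux
boundaries, and block-averages the result down to the requested resolution.

The ICP generator produces a 10 kHz pressure trace with cardiac (~4.22 Hz,
heart rate 253 bpm) and respiratory (~0.73 Hz, 44 bpm) sinusoidal
components; the TSC generator produces gamma-variate lymph-node uptake
curves.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .grids import DCESeries, ImageGrid
from .icp import ICPRecording
from .tsc import TSC

__all__ = [
    "BolusSpec",
    "SourceSpec",
    "RegionScale",
    "PhantomSpec",
    "GroundTruth",
    "ICPSpec",
    "make_velocity_field",
    "simulate_tracer_series",
    "make_icp_waveform",
    "make_tsc",
    "default_phantom_spec",
]

_VELOCITY_KINDS = ("constant", "rotation", "smooth_random", "zero")


@dataclass
class BolusSpec:
    """Initial Gaussian tracer distribution in percent-change units."""

    center_mm: Optional[Sequence[float]] = None  # default: grid centre
    width_mm: float = 1.0  # Gaussian sigma
    amplitude: float = 30.0  # peak percent signal change

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("bolus amplitude must be >= 0")
        if self.width_mm <= 0:
            raise ValueError("bolus width must be positive")


@dataclass
class SourceSpec:
    """Optional inlet region emulating a slow intrathecal infusion."""

    center_mm: Sequence[float]
    radius_mm: float
    rate_per_s: float  # percent-change units added per second inside the inlet


@dataclass
class RegionScale:
    """Scale the velocity magnitude inside a box subregion (planted contrast)."""

    lo_vox: Sequence[int]
    hi_vox: Sequence[int]  # exclusive upper corner
    factor: float = 1.5

    def mask(self, dims: Tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(dims, dtype=bool)
        lo = [max(0, int(v)) for v in self.lo_vox]
        hi = [min(d, int(v)) for v, d in zip(self.hi_vox, dims)]
        m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
        return m


@dataclass
class PhantomSpec:
    """Configuration of one synthetic DCE acquisition.

    ``velocity_magnitude`` is expressed in mm per frame interval (the
    natural scale of frame-to-frame displacement); ``sigma_true`` is the
    physical diffusion coefficient in mm^2/s.
    """

    grid_dims: Tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 0.3
    frame_interval_s: float = 300.0
    n_frames: int = 5
    velocity_kind: str = "constant"
    velocity_magnitude: float = 0.3  # mm per frame interval
    velocity_direction: Sequence[float] = (1.0, 0.0, 0.0)
    rotation_omega_rad_s: float = 1e-3
    rotation_axis: int = 2
    smooth_random_corr_vox: float = 3.0
    sigma_true: float = 0.0  # mm^2/s
    bolus: BolusSpec = field(default_factory=BolusSpec)
    source: Optional[SourceSpec] = None
    region_scale: Optional[RegionScale] = None
    noise_sd: float = 1.0  # percent-change units
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        if any(d < 8 for d in self.grid_dims):
            raise ValueError("grid_dims must be >= 8 voxels per axis")
        if self.velocity_kind not in _VELOCITY_KINDS:
            raise ValueError(
                f"unknown velocity_kind {self.velocity_kind!r}; choose from {_VELOCITY_KINDS}"
            )
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sigma_true < 0:
            raise ValueError("sigma_true must be >= 0")

    def grid(self) -> ImageGrid:
        return ImageGrid(self.grid_dims, self.voxel_size_mm)


@dataclass
class GroundTruth:
    """True transport parameters of a phantom, for recovery tests."""

    velocity_true_mm_s: np.ndarray  # dims + (3,)
    sigma_true_mm2_s: float
    expected_mean_speed_um_s: float  # mean |v| over the tracer-occupied region
    displacement_true_mm: np.ndarray  # mm per frame interval, dims + (3,)
    tracer_region: np.ndarray  # bool, region used for expected_mean_speed


def _bolus_center_mm(spec: PhantomSpec) -> np.ndarray:
    if spec.bolus.center_mm is not None:
        return np.asarray(spec.bolus.center_mm, dtype=float)
    return 0.5 * np.asarray(spec.grid_dims, dtype=float) * spec.voxel_size_mm


def _evaluate_velocity_mm_s(spec: PhantomSpec, centers_mm: np.ndarray) -> np.ndarray:
    """Velocity in mm/s at the given physical positions (shape ... x 3)."""
    shape = centers_mm.shape[:-1]
    v = np.zeros(shape + (3,), dtype=float)
    mag_mm_s = spec.velocity_magnitude / spec.frame_interval_s
    if spec.velocity_kind == "zero":
        pass
    elif spec.velocity_kind == "constant":
        d = np.asarray(spec.velocity_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("velocity_direction must be nonzero for constant kind")
        v[:] = mag_mm_s * d / n
    elif spec.velocity_kind == "rotation":
        axis = spec.rotation_axis
        center = 0.5 * np.asarray(spec.grid_dims, dtype=float) * spec.voxel_size_mm
        r = centers_mm - center
        omega = np.zeros(3)
        omega[axis] = spec.rotation_omega_rad_s
        v[:] = np.cross(omega, r)
    elif spec.velocity_kind == "smooth_random":
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
        # band-limited field at spec resolution, interpolated if evaluated elsewhere
        raw = rng.standard_normal(spec.grid_dims + (3,))
        for c in range(3):
            raw[..., c] = gaussian_filter(
                raw[..., c], spec.smooth_random_corr_vox, mode="wrap"
            )
        rms = np.sqrt(np.mean(np.sum(raw**2, axis=-1)))
        raw *= mag_mm_s / rms if rms > 0 else 0.0
        if shape == tuple(spec.grid_dims):
            v[:] = raw
        else:
            from scipy.ndimage import map_coordinates

            idx = centers_mm / spec.voxel_size_mm - 0.5
            coords = [np.clip(idx[..., a], 0, spec.grid_dims[a] - 1) for a in range(3)]
            for c in range(3):
                v[..., c] = map_coordinates(raw[..., c], coords, order=1, mode="nearest")
    if spec.region_scale is not None:
        # region defined in spec-resolution voxel indices; map physical pos -> voxel
        idx = np.floor(centers_mm / spec.voxel_size_mm).astype(int)
        dims = spec.grid_dims
        lo = np.asarray(spec.region_scale.lo_vox)
        hi = np.asarray(spec.region_scale.hi_vox)
        inside = np.all((idx >= lo) & (idx < hi), axis=-1) & np.all(
            (idx >= 0) & (idx < np.asarray(dims)), axis=-1
        )
        v[inside] *= spec.region_scale.factor
    return v


def make_velocity_field(spec: PhantomSpec) -> GroundTruth:
    """Evaluate the ground-truth velocity field at spec-resolution voxel centres."""
    grid = spec.grid()
    centers = grid.voxel_centers_mm()
    v_mm_s = _evaluate_velocity_mm_s(spec, centers)
    rho0 = _initial_bolus(spec, grid)
    thresh = 0.1 * rho0.max() if rho0.max() > 0 else 0.0
    region = rho0 >= thresh if rho0.max() > 0 else np.ones(grid.dims, bool)
    speed = np.sqrt(np.sum(v_mm_s**2, axis=-1))
    mean_speed_um_s = float(speed[region].mean() * 1000.0)
    return GroundTruth(
        velocity_true_mm_s=v_mm_s,
        sigma_true_mm2_s=spec.sigma_true,
        expected_mean_speed_um_s=mean_speed_um_s,
        displacement_true_mm=v_mm_s * spec.frame_interval_s,
        tracer_region=region,
    )


def _initial_bolus(spec: PhantomSpec, grid: ImageGrid) -> np.ndarray:
    centers = grid.voxel_centers_mm()
    c = _bolus_center_mm(spec)
    r2 = np.sum((centers - c) ** 2, axis=-1)
    return spec.bolus.amplitude * np.exp(-0.5 * r2 / spec.bolus.width_mm**2)


def _neumann_laplacian_apply(rho: np.ndarray) -> np.ndarray:
    """7-point Laplacian with zero-flux (mirror) boundaries."""
    out = np.zeros_like(rho)
    for axis in range(3):
        lo = np.concatenate(
            [rho.take([0], axis=axis), rho.take(range(rho.shape[axis] - 1), axis=axis)],
            axis=axis,
        )
        hi = np.concatenate(
            [rho.take(range(1, rho.shape[axis]), axis=axis), rho.take([-1], axis=axis)],
            axis=axis,
        )
        out += lo + hi - 2 * rho
    return out


def _upwind_divergence(rho: np.ndarray, v_vox: np.ndarray) -> np.ndarray:
    """div(rho v) by first-order upwind fluxes; zero-flux boundary faces.

    ``v_vox`` holds cell-centred velocity in voxels per unit time; interior
    face velocity is the mean of the adjacent cells.
    """
    out = np.zeros_like(rho)
    for axis in range(3):
        n = rho.shape[axis]
        vc = v_vox[..., axis]
        sl = [slice(None)] * 3
        sl_lo, sl_hi = list(sl), list(sl)
        sl_lo[axis] = slice(0, n - 1)
        sl_hi[axis] = slice(1, n)
        v_face = 0.5 * (vc[tuple(sl_lo)] + vc[tuple(sl_hi)])
        rho_up = np.where(v_face > 0, rho[tuple(sl_lo)], rho[tuple(sl_hi)])
        flux = v_face * rho_up  # flux through interior faces, positive along +axis
        # divergence: flux out minus flux in per cell
        pad = [(0, 0)] * 3
        pad[axis] = (1, 1)
        flux_padded = np.pad(flux, pad)  # zero-flux at domain faces
        sl_out, sl_in = list(sl), list(sl)
        sl_out[axis] = slice(1, n + 1)
        sl_in[axis] = slice(0, n)
        out += flux_padded[tuple(sl_out)] - flux_padded[tuple(sl_in)]
    return out


def _downsample2(rho: np.ndarray) -> np.ndarray:
    s = rho.shape
    return rho.reshape(s[0] // 2, 2, s[1] // 2, 2, s[2] // 2, 2).mean(axis=(1, 3, 5))


MAX_SUBSTEPS_PER_FRAME = 20000


def simulate_tracer_series(
    spec: PhantomSpec, truth: Optional[GroundTruth] = None
) -> DCESeries:
    """Integrate the tracer forward and sample frames at the spec resolution.

    Frames are in percent-change units at times ``k * frame_interval_s``;
    frame 0 is the initial bolus.  Noise is additive Gaussian per voxel per
    frame.  The integrator (refined-grid explicit upwind + explicit
    diffusion) is deliberately independent of the solver's transport
    operator.
    """
    if truth is None:
        truth = make_velocity_field(spec)
    grid = spec.grid()
    # refined grid: 2x in each spatial axis
    dims_r = tuple(2 * d for d in spec.grid_dims)
    vox_r = spec.voxel_size_mm / 2.0
    grid_r = ImageGrid(dims_r, vox_r)
    centers_r = grid_r.voxel_centers_mm()
    v_mm_s = _evaluate_velocity_mm_s(spec, centers_r)
    v_vox_s = v_mm_s / vox_r  # refined voxels per second
    sigma_vox_s = spec.sigma_true / vox_r**2

    c = _bolus_center_mm(spec)
    r2 = np.sum((centers_r - c) ** 2, axis=-1)
    rho = spec.bolus.amplitude * np.exp(-0.5 * r2 / spec.bolus.width_mm**2)

    vmax = float(np.max(np.abs(v_vox_s)))
    # CFL limits (explicit upwind advection and explicit diffusion)
    dt_adv = 0.4 / vmax if vmax > 0 else np.inf
    dt_dif = 0.8 / (6.0 * sigma_vox_s) if sigma_vox_s > 0 else np.inf
    dt_max = min(dt_adv, dt_dif)
    n_sub = max(4, int(np.ceil(spec.frame_interval_s / dt_max)) if np.isfinite(dt_max) else 4)
    if n_sub > MAX_SUBSTEPS_PER_FRAME:
        raise ValueError(
            f"velocity/diffusion magnitude violates the CFL budget on the refined grid "
            f"({n_sub} substeps per frame needed, cap {MAX_SUBSTEPS_PER_FRAME}); "
            "reduce velocity_magnitude or sigma_true, or enlarge frame_interval_s"
        )
    dt = spec.frame_interval_s / n_sub

    source_mask = None
    if spec.source is not None:
        d2 = np.sum((centers_r - np.asarray(spec.source.center_mm)) ** 2, axis=-1)
        source_mask = d2 <= spec.source.radius_mm**2

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    frames = np.empty((spec.n_frames,) + spec.grid_dims)
    frames[0] = _downsample2(rho)
    for k in range(1, spec.n_frames):
        for _ in range(n_sub):
            rho = rho - dt * _upwind_divergence(rho, v_vox_s)
            if sigma_vox_s > 0:
                rho = rho + dt * sigma_vox_s * _neumann_laplacian_apply(rho)
            if source_mask is not None:
                rho = rho + dt * spec.source.rate_per_s * source_mask
        frames[k] = _downsample2(rho)
    # the phantom's "brain" compartment: the noise-free tracer-occupied
    # region (any frame >= 10% of bolus amplitude), dilated 2 voxels --
    # the closed-skull analogue of the anatomical mask a real study uses
    if spec.bolus.amplitude > 0:
        occupied = (frames >= 0.1 * spec.bolus.amplitude).any(axis=0)
    else:
        occupied = np.ones(spec.grid_dims, bool)
    from scipy.ndimage import binary_dilation

    grid.masks["brain"] = binary_dilation(occupied, iterations=2)
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)
    times = np.arange(spec.n_frames) * spec.frame_interval_s
    return DCESeries(frames, times, grid, baseline_indices=(), units="percent_change")


@dataclass
class ICPSpec:
    """Synthetic ICP trace: baseline + respiratory + cardiac sinusoids + drift + noise.

    Default frequencies follow the measured rat physiology (heart rate
    253 bpm -> 4.22 Hz; respiratory rate 44 bpm -> 0.73 Hz) and the
    recording is sampled at 10 kHz.
    """

    duration_s: float = 30.0
    sampling_rate_hz: float = 10000.0
    baseline_mmhg: float = 5.0
    cardiac_freq_hz: float = 4.22
    cardiac_amp_mmhg: float = 0.25
    resp_freq_hz: float = 0.73
    resp_amp_mmhg: float = 0.4
    drift_mmhg_per_s: float = 0.0
    noise_sd_mmhg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cardiac_freq_hz <= 0 or self.resp_freq_hz <= 0:
            raise ValueError("frequencies must be positive")
        if self.sampling_rate_hz <= 2 * self.cardiac_freq_hz:
            raise ValueError("sampling_rate_hz must exceed twice the cardiac frequency")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.noise_sd_mmhg < 0:
            raise ValueError("noise_sd_mmhg must be >= 0")


def make_icp_waveform(spec: ICPSpec) -> ICPRecording:
    """Generate a deterministic composite pressure trace."""
    n = int(round(spec.duration_s * spec.sampling_rate_hz))
    t = np.arange(n) / spec.sampling_rate_hz
    p = (
        spec.baseline_mmhg
        + spec.resp_amp_mmhg * np.sin(2 * np.pi * spec.resp_freq_hz * t)
        + spec.cardiac_amp_mmhg * np.sin(2 * np.pi * spec.cardiac_freq_hz * t)
        + spec.drift_mmhg_per_s * t
    )
    if spec.noise_sd_mmhg > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 13]))
        p = p + rng.normal(0.0, spec.noise_sd_mmhg, size=n)
    return ICPRecording(p, spec.sampling_rate_hz)


def make_tsc(
    times_min: Sequence[float],
    t0_min: float,
    t_peak_min: float,
    alpha: float,
    amplitude: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    node: str = "dcLN",
) -> TSC:
    """Gamma-variate uptake curve y(t) = A * tau^alpha * exp(alpha*(1 - tau)).

    ``tau = (t - t0)/(t_peak - t0)`` for t > t0, else y = 0; the noise-free
    curve peaks at exactly ``t_peak`` with value ``A``.  Defaults elsewhere
    in the package place the peak near 87 minutes, the measured deep
    cervical lymph node time-to-peak.
    """
    if t_peak_min <= t0_min:
        raise ValueError("t_peak must be strictly greater than t0")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    t = np.asarray(times_min, dtype=float)
    tau = np.where(t > t0_min, (t - t0_min) / (t_peak_min - t0_min), 0.0)
    y = np.where(tau > 0, amplitude * tau**alpha * np.exp(alpha * (1.0 - tau)), 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return TSC(t, y, node=node, normalized=True)


def default_phantom_spec(**overrides) -> PhantomSpec:
    """The desk-scale study phantom: 32^3 grid, 0.3 mm voxels, 5 frames at 300 s."""
    return PhantomSpec(**overrides)
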