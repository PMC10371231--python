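"""Regularized optimal mass transport (rOMT) between adjacent frames.

For each pair of adjacent percent-change frames ``(rho0, rho1)`` the solver
estimates per-substep velocity fields ``v_0..v_{m-1}`` minimising a
Benamou-Brenier kinetic energy subject to an advection-diffusion transport
constraint, with the endpoint constraint relaxed into a penalty:

    E(v) = m * sum_k <rho_k, |v_k|^2> + beta * ||rho_m - rho1||^2

where ``rho_{k+1} = D T(v_k) rho_k``; ``T(v)`` is a mass-preserving
push-forward (each voxel's mass deposited at its displaced position via
trilinear weights, displacements clamped inside the domain) and
``D = (I - sigma L)^{-1}`` an implicit diffusion step with ``L`` the
7-point Neumann Laplacian.  The diffusion term regularises plain dynamic
OMT into a model of combined bulk flow and diffusion, which is the point:
tracer redistribution explicable by diffusion alone should not be
attributed to flow.

With velocity expressed in voxels per substep and kinetic weight ``m``
(substeps spanning a unit pseudo-time horizon), a pure translation by
``d`` voxels has kinetic energy ``mass * |d|^2`` — the squared Wasserstein-2
distance between translated profiles — which anchors the solver's scale.

Minimisation is Gauss-Newton: exact adjoint gradients through the ``m``
substeps, a conjugate-gradient inner solve of the GN normal equations, and
Armijo backtracking.  The solver is fully deterministic.

Internal units are voxels and substeps; speeds are converted to um/s only
at reporting:  ``speed_um_s = |v| * voxel_mm * 1000 * m / frame_interval_s``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.fft
from scipy.sparse.linalg import LinearOperator, cg as sparse_cg

from .grids import ImageGrid, PercentChangeSeries

__all__ = [
    "RomtConfig",
    "VelocityField",
    "IntervalSolution",
    "advect_diffuse_step",
    "forward_solve",
    "romt_energy",
    "romt_gradient",
    "solve_pair",
    "solve_series",
    "sigma_vox_from_physical",
]

logger = logging.getLogger(__name__)


@dataclass
class RomtConfig:
    """Solver settings.  ``sigma`` is in voxel^2 per substep.

    No canonical values exist for these constants; the defaults here are
    this package's own, recorded in every output's provenance.
    """

    sigma: float = 0.002
    beta: float = 1.0e4
    n_substeps: int = 8
    max_outer_iterations: int = 32
    beta_continuation_stages: int = 4  # homotopy: beta * 10^(i+1-stages), i = 0..
    inner_cg_tolerance: float = 1.0e-8
    inner_cg_maxiter: int = 15
    armijo_c1: float = 1.0e-4
    armijo_contraction: float = 0.5
    armijo_max_trials: int = 10
    convergence_tol: float = 1.0e-4  # relative energy decrease
    diffusion_solver: str = "dct"  # "dct" (spectral, exact) or "cg"
    gn_damping: float = 1.0e-3  # Levenberg damping relative to the kinetic diagonal

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")
        if self.beta_continuation_stages < 1:
            raise ValueError("beta_continuation_stages must be >= 1")
        if self.diffusion_solver not in ("dct", "cg"):
            raise ValueError("diffusion_solver must be 'dct' or 'cg'")


def sigma_vox_from_physical(
    sigma_mm2_s: float, voxel_size_mm: float, frame_interval_s: float, n_substeps: int
) -> float:
    """Convert a physical diffusion coefficient to voxel^2 per substep."""
    return sigma_mm2_s * frame_interval_s / (float(voxel_size_mm) ** 2 * n_substeps)


@dataclass
class VelocityField:
    """Per-substep cell-centred velocity in voxels per substep.

    Shape ``(m, nx, ny, nz, 3)``.  Conversion to physical speed uses the
    frame interval the field spans.
    """

    v: np.ndarray
    grid: ImageGrid
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 5 or self.v.shape[-1] != 3:
            raise ValueError("velocity must have shape (m, nx, ny, nz, 3)")
        if self.v.shape[1:4] != self.grid.dims:
            raise ValueError("velocity grid does not match ImageGrid dims")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("velocity must be finite everywhere")

    @property
    def n_substeps(self) -> int:
        return int(self.v.shape[0])

    @property
    def vox_per_substep_to_um_s(self) -> float:
        return (
            float(self.grid.voxel_size_mm[0])
            * 1000.0
            * self.n_substeps
            / self.frame_interval_s
        )

    def speed_vox(self) -> np.ndarray:
        """Per-substep speed |v| in voxels/substep, shape (m, nx, ny, nz)."""
        return np.sqrt(np.sum(self.v**2, axis=-1))

    def speed_um_s(self) -> np.ndarray:
        return self.speed_vox() * self.vox_per_substep_to_um_s

    def to_mm_s(self) -> np.ndarray:
        """Velocity in mm/s, shape (m, nx, ny, nz, 3)."""
        return self.v * (
            float(self.grid.voxel_size_mm[0]) * self.n_substeps / self.frame_interval_s
        )


@dataclass
class IntervalSolution:
    """rOMT solution for one adjacent frame pair.

    ``energy_log`` holds accepted energies; it is non-increasing within each
    continuation stage (entries of ``stage_starts`` mark where the endpoint
    penalty was raised, which resets the energy scale).
    """

    velocity: VelocityField
    trajectory: np.ndarray  # (m+1, nx, ny, nz)
    energy_total: float
    energy_kinetic: float
    energy_mismatch: float
    energy_log: List[float] = field(default_factory=list)
    stage_starts: List[int] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    frame_index: int = 0
    warnings: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# discrete transport machinery


_BASE_CACHE: dict = {}


def _base_positions(dims: Tuple[int, int, int]) -> np.ndarray:
    if dims not in _BASE_CACHE:
        g = np.stack(
            np.meshgrid(*[np.arange(d, dtype=float) for d in dims], indexing="ij"),
            axis=-1,
        )
        _BASE_CACHE[dims] = g
    return _BASE_CACHE[dims]


def _trilinear_setup(v: np.ndarray, dims: Tuple[int, int, int]):
    """Clamped displaced positions and trilinear cell/fraction decomposition.

    Returns ``(i0, frac, interior)`` where ``interior[..., a]`` is False at
    positions clamped along axis ``a`` (where the derivative w.r.t. the
    displacement vanishes).
    """
    pos = _base_positions(dims) + v
    n = np.asarray(dims, dtype=float)
    interior = (pos > 0.0) & (pos < n - 1.0)
    pos = np.clip(pos, 0.0, n - 1.0)
    i0 = np.floor(pos).astype(np.int64)
    for a in range(3):
        np.minimum(i0[..., a], dims[a] - 2, out=i0[..., a])
    frac = pos - i0
    return i0, frac, interior


def _corner_flat_indices(i0: np.ndarray, dims) -> List[np.ndarray]:
    nx, ny, nz = dims
    ix, iy, iz = i0[..., 0], i0[..., 1], i0[..., 2]
    out = []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                out.append(((ix + dx) * ny + (iy + dy)) * nz + (iz + dz))
    return out


def _corner_weights(frac: np.ndarray) -> List[np.ndarray]:
    fx, fy, fz = frac[..., 0], frac[..., 1], frac[..., 2]
    gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz
    return [
        gx * gy * gz, gx * gy * fz, gx * fy * gz, gx * fy * fz,
        fx * gy * gz, fx * gy * fz, fx * fy * gz, fx * fy * fz,
    ]


class _SubstepOps:
    """Trilinear push/pull/derivative operators for one fixed displacement field.

    Precomputes the clamped corner indices and weights once, so repeated
    applications (the inner CG loop applies them many times per outer
    iteration) cost only gathers and scatter-adds.
    """

    # per-corner sign of the weight derivative along each axis, matching
    # the corner ordering of _corner_weights
    _SX = (-1.0, -1.0, -1.0, -1.0, 1.0, 1.0, 1.0, 1.0)
    _SY = (-1.0, -1.0, 1.0, 1.0, -1.0, -1.0, 1.0, 1.0)
    _SZ = (-1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0)

    def __init__(self, v: np.ndarray, dims: Tuple[int, int, int]) -> None:
        self.dims = dims
        self.n_flat = int(np.prod(dims))
        i0, frac, interior = _trilinear_setup(v, dims)
        self.interior = interior
        self.flats = [f.ravel() for f in _corner_flat_indices(i0, dims)]
        self.weights = [w.ravel() for w in _corner_weights(frac)]
        fx, fy, fz = frac[..., 0].ravel(), frac[..., 1].ravel(), frac[..., 2].ravel()
        gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz
        self._wx = (gx, gx, gx, gx, fx, fx, fx, fx)
        self._wy = (gy, gy, fy, fy, gy, gy, fy, fy)
        self._wz = (gz, fz, gz, fz, gz, fz, gz, fz)

    def push(self, rho: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n_flat)
        r = rho.ravel()
        for fl, w in zip(self.flats, self.weights):
            out += np.bincount(fl, weights=r * w, minlength=self.n_flat)
        return out.reshape(self.dims)

    def pull(self, x: np.ndarray) -> np.ndarray:
        xf = x.ravel()
        out = np.zeros(self.n_flat)
        for fl, w in zip(self.flats, self.weights):
            out += xf[fl] * w
        return out.reshape(self.dims)

    def interp_gradient(self, x: np.ndarray) -> np.ndarray:
        xf = x.ravel()
        grad = np.zeros((self.n_flat, 3))
        for c in range(8):
            val = xf[self.flats[c]]
            grad[:, 0] += val * (self._SX[c] * self._wy[c] * self._wz[c])
            grad[:, 1] += val * (self._wx[c] * self._SY[c] * self._wz[c])
            grad[:, 2] += val * (self._wx[c] * self._wy[c] * self._SZ[c])
        grad = grad.reshape(self.dims + (3,))
        grad *= self.interior
        return grad

    def deposit_directional(self, rho: np.ndarray, p: np.ndarray) -> np.ndarray:
        px = ((p[..., 0] * self.interior[..., 0]) * rho).ravel()
        py = ((p[..., 1] * self.interior[..., 1]) * rho).ravel()
        pz = ((p[..., 2] * self.interior[..., 2]) * rho).ravel()
        out = np.zeros(self.n_flat)
        for c in range(8):
            dw = (
                px * (self._SX[c] * self._wy[c] * self._wz[c])
                + py * (self._wx[c] * self._SY[c] * self._wz[c])
                + pz * (self._wx[c] * self._wy[c] * self._SZ[c])
            )
            out += np.bincount(self.flats[c], weights=dw, minlength=self.n_flat)
        return out.reshape(self.dims)


def _make_ops(v: np.ndarray) -> List[_SubstepOps]:
    dims = v.shape[1:4]
    return [_SubstepOps(v[k], dims) for k in range(v.shape[0])]


def _push_forward(rho: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Mass-preserving advection: deposit each voxel's mass at its displaced position."""
    return _SubstepOps(v, rho.shape).push(rho)


def _pull_back(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Adjoint of the push-forward: trilinear interpolation of x at displaced positions."""
    return _SubstepOps(v, x.shape).pull(x)


def _interp_gradient(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Gradient of ``_pull_back(x, v)`` w.r.t. the displacement; zero where clamped."""
    return _SubstepOps(v, x.shape).interp_gradient(x)


def _deposit_directional(rho: np.ndarray, v: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Directional derivative ``d/de T(v + e p) rho`` at ``e = 0``."""
    return _SubstepOps(v, rho.shape).deposit_directional(rho, p)


def _laplacian_neumann(rho: np.ndarray) -> np.ndarray:
    """7-point Laplacian with mirrored (zero-flux) boundaries."""
    out = np.zeros_like(rho)
    for axis in range(3):
        n = rho.shape[axis]
        lo = np.concatenate(
            [rho.take([0], axis=axis), rho.take(range(n - 1), axis=axis)], axis=axis
        )
        hi = np.concatenate(
            [rho.take(range(1, n), axis=axis), rho.take([-1], axis=axis)], axis=axis
        )
        out += lo + hi - 2.0 * rho
    return out


_DCT_DENOM_CACHE: dict = {}


def _dct_denominator(dims: Tuple[int, int, int], sigma: float) -> np.ndarray:
    key = (dims, float(sigma))
    if key not in _DCT_DENOM_CACHE:
        eigs = []
        for n in dims:
            k = np.arange(n)
            eigs.append(2.0 * np.cos(np.pi * k / n) - 2.0)
        lam = (
            eigs[0][:, None, None] + eigs[1][None, :, None] + eigs[2][None, None, :]
        )
        _DCT_DENOM_CACHE[key] = 1.0 - sigma * lam
    return _DCT_DENOM_CACHE[key]


def _diffuse(rho: np.ndarray, sigma: float, config: RomtConfig) -> np.ndarray:
    """Solve ``(I - sigma L) x = rho`` with zero-flux boundaries.

    The default spectral route diagonalises the Neumann Laplacian in the
    DCT-II basis (exact); the "cg" route solves the same SPD system by
    conjugate gradients to ``inner_cg_tolerance``.
    """
    if sigma == 0:
        return rho.copy()
    if config.diffusion_solver == "dct":
        denom = _dct_denominator(rho.shape, sigma)
        rho_hat = scipy.fft.dctn(rho, type=2, norm="ortho")
        return scipy.fft.idctn(rho_hat / denom, type=2, norm="ortho")
    dims = rho.shape
    n = rho.size

    def matvec(x):
        x3 = x.reshape(dims)
        return (x3 - sigma * _laplacian_neumann(x3)).ravel()

    op = LinearOperator((n, n), matvec=matvec, dtype=float)
    x, info = sparse_cg(
        op,
        rho.ravel(),
        rtol=config.inner_cg_tolerance,
        maxiter=max(200, 10 * config.inner_cg_maxiter),
    )
    if info != 0:
        resid = np.linalg.norm(matvec(x) - rho.ravel()) / max(
            np.linalg.norm(rho), 1e-300
        )
        raise RuntimeError(
            f"diffusion CG failed to converge (info={info}, relative residual {resid:.3e})"
        )
    return x.reshape(dims)


# ---------------------------------------------------------------------------
# public transport operations


def advect_diffuse_step(
    rho: np.ndarray, v_substep: np.ndarray, config: RomtConfig
) -> np.ndarray:
    """One operator-splitting substep: push-forward advection, then implicit diffusion."""
    if not np.all(np.isfinite(v_substep)):
        raise ValueError("velocity substep must be finite")
    rho_adv = _push_forward(np.asarray(rho, dtype=float), v_substep)
    return _diffuse(rho_adv, config.sigma, config)


def forward_solve(
    rho0: np.ndarray,
    velocity: VelocityField | np.ndarray,
    config: RomtConfig,
    ops: Optional[List[_SubstepOps]] = None,
) -> np.ndarray:
    """Apply ``m`` advection-diffusion substeps; returns the full trajectory.

    Output shape ``(m+1,) + dims`` with ``trajectory[0] = rho0``.
    """
    v = velocity.v if isinstance(velocity, VelocityField) else np.asarray(velocity)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity must be finite")
    m = v.shape[0]
    if ops is None:
        ops = _make_ops(v)
    traj = np.empty((m + 1,) + rho0.shape)
    traj[0] = np.asarray(rho0, dtype=float)
    for k in range(m):
        traj[k + 1] = _diffuse(ops[k].push(traj[k]), config.sigma, config)
    return traj


def romt_energy(
    rho0: np.ndarray,
    rho1: np.ndarray,
    velocity: VelocityField | np.ndarray,
    config: RomtConfig,
    trajectory: Optional[np.ndarray] = None,
) -> Tuple[float, float, float]:
    """Total, kinetic and mismatch energy of a candidate velocity field."""
    v = velocity.v if isinstance(velocity, VelocityField) else np.asarray(velocity)
    m = v.shape[0]
    if trajectory is None:
        trajectory = forward_solve(rho0, v, config)
    speed2 = np.sum(v**2, axis=-1)  # (m,) + dims
    kinetic = float(m * np.sum(trajectory[:m] * speed2))
    mismatch = float(config.beta * np.sum((trajectory[m] - rho1) ** 2))
    return kinetic + mismatch, kinetic, mismatch


def romt_gradient(
    rho0: np.ndarray,
    rho1: np.ndarray,
    v: np.ndarray,
    config: RomtConfig,
    trajectory: Optional[np.ndarray] = None,
    ops: Optional[List[_SubstepOps]] = None,
) -> np.ndarray:
    """Exact adjoint gradient of the energy with respect to ``v``."""
    m = v.shape[0]
    if ops is None:
        ops = _make_ops(v)
    if trajectory is None:
        trajectory = forward_solve(rho0, v, config, ops)
    grad = np.empty_like(v)
    lam = 2.0 * config.beta * (trajectory[m] - rho1)
    for k in range(m - 1, -1, -1):
        mu = _diffuse(lam, config.sigma, config)
        rho_k = trajectory[k]
        grad[k] = 2.0 * m * rho_k[..., None] * v[k] + rho_k[..., None] * ops[
            k
        ].interp_gradient(mu)
        if k > 0:
            lam = ops[k].pull(mu) + m * np.sum(v[k] ** 2, axis=-1)
    return grad


def _gauss_newton_hvp(
    p: np.ndarray,
    v: np.ndarray,
    trajectory: np.ndarray,
    config: RomtConfig,
    damping: float,
    mask: Optional[np.ndarray],
    ops: Optional[List[_SubstepOps]] = None,
) -> np.ndarray:
    """Gauss-Newton Hessian-vector product (kinetic diagonal + J^T J of the mismatch)."""
    m = v.shape[0]
    if ops is None:
        ops = _make_ops(v)
    if mask is not None:
        p = p * mask[None, ..., None]
    delta = np.zeros_like(trajectory[0])
    for k in range(m):
        delta = _diffuse(
            ops[k].push(delta) + ops[k].deposit_directional(trajectory[k], p[k]),
            config.sigma,
            config,
        )
    out = np.empty_like(p)
    nu = 2.0 * config.beta * delta
    for k in range(m - 1, -1, -1):
        mu = _diffuse(nu, config.sigma, config)
        rho_k = trajectory[k]
        out[k] = (
            2.0 * m * rho_k[..., None] * p[k]
            + rho_k[..., None] * ops[k].interp_gradient(mu)
            + damping * p[k]
        )
        if k > 0:
            nu = ops[k].pull(mu)
    if mask is not None:
        out *= mask[None, ..., None]
    return out


def _cg_solve_gn(
    g: np.ndarray,
    v: np.ndarray,
    trajectory: np.ndarray,
    config: RomtConfig,
    damping: float,
    mask: Optional[np.ndarray],
    ops: Optional[List[_SubstepOps]] = None,
) -> np.ndarray:
    """Preconditioned conjugate gradients on the damped GN system ``H p = -g``.

    The preconditioner is the kinetic diagonal ``2 m rho_k + damping``
    (Jacobi), which equalises the wildly varying density weights.
    """
    m = v.shape[0]
    diag = 2.0 * m * trajectory[:m][..., None] + damping  # (m,)+dims+(1,)
    inv_diag = 1.0 / diag
    p = np.zeros_like(g)
    r = -g.copy()
    if mask is not None:
        r *= mask[None, ..., None]
    z = inv_diag * r
    d = z.copy()
    rz = float(np.sum(r * z))
    r0 = float(np.sum(r * r))
    if r0 == 0 or rz <= 0:
        return p
    for _ in range(config.inner_cg_maxiter):
        hd = _gauss_newton_hvp(d, v, trajectory, config, damping, mask, ops)
        dhd = float(np.sum(d * hd))
        if dhd <= 0:
            break  # indefinite direction (numerical); keep current iterate
        alpha = rz / dhd
        p += alpha * d
        r -= alpha * hd
        if float(np.sum(r * r)) <= config.inner_cg_tolerance**2 * r0:
            break
        z = inv_diag * r
        rz_new = float(np.sum(r * z))
        if rz_new <= 0:
            break
        d = z + (rz_new / rz) * d
        rz = rz_new
    return p


def solve_pair(
    rho0: np.ndarray,
    rho1: np.ndarray,
    config: Optional[RomtConfig] = None,
    grid: Optional[ImageGrid] = None,
    frame_interval_s: float = 300.0,
    mask: Optional[np.ndarray] = None,
    frame_index: int = 0,
) -> IntervalSolution:
    """Estimate the optimal velocity transporting ``rho0`` toward ``rho1``.

    Gauss-Newton with Armijo backtracking, initialised at ``v = 0``, with
    continuation on the endpoint penalty: the solve is repeated over
    ``beta_continuation_stages`` increasing values of beta (final stage at
    the configured beta), warm-started from the previous stage.  Without
    continuation a strong penalty pulls the iterates onto kinetically
    inefficient transport paths; the homotopy keeps them near the optimal
    (Wasserstein-geodesic) flow.  The accepted-energy log is non-increasing
    within each stage.  If a brain ``mask`` is given the velocity is
    constrained to zero outside it.  Deterministic for fixed inputs.
    """
    config = config or RomtConfig()
    rho0 = np.asarray(rho0, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    if rho0.shape != rho1.shape:
        raise ValueError("frames must share a grid")
    if np.any(rho0 < 0) or np.any(rho1 < 0):
        raise ValueError("frames must be nonnegative (apply the density floor first)")
    if grid is None:
        grid = ImageGrid(rho0.shape, 0.3)
    mask_f = None if mask is None else np.asarray(mask, dtype=float)

    m = config.n_substeps
    v = np.zeros((m,) + rho0.shape + (3,))
    warns: List[str] = []
    damping_scale = 2.0 * m * max(float(rho0.mean()), 1e-12)
    energy_log: List[float] = []
    stage_starts: List[int] = []
    n_stages = config.beta_continuation_stages
    iters_per_stage = max(1, config.max_outer_iterations // n_stages)
    total_iters = 0
    any_step_accepted = False
    converged = False
    ops = _make_ops(v)
    traj = forward_solve(rho0, v, config, ops)

    for stage in range(n_stages):
        # homotopy on the endpoint penalty: follow the efficient-transport path
        beta_stage = config.beta * 10.0 ** (stage + 1 - n_stages)
        cfg_stage = dataclasses.replace(config, beta=beta_stage)
        e_total, e_kin, e_mis = romt_energy(rho0, rho1, v, cfg_stage, traj)
        if not np.isfinite(e_total):
            raise FloatingPointError("non-finite energy at continuation stage start")
        stage_starts.append(len(energy_log))
        energy_log.append(e_total)
        converged = False
        for _ in range(iters_per_stage):
            total_iters += 1
            g = romt_gradient(rho0, rho1, v, cfg_stage, traj, ops)
            if mask_f is not None:
                g *= mask_f[None, ..., None]
            p = _cg_solve_gn(
                g, v, traj, cfg_stage, config.gn_damping * damping_scale, mask_f, ops
            )
            slope = float(np.sum(g * p))
            if slope >= 0:  # not a descent direction; fall back to steepest descent
                p = -g
                slope = -float(np.sum(g * g))
                if slope == 0:
                    converged = True
                    break
            # Armijo backtracking
            t = 1.0
            accepted = False
            for _ in range(config.armijo_max_trials):
                v_new = v + t * p
                ops_new = _make_ops(v_new)
                traj_new = forward_solve(rho0, v_new, config, ops_new)
                e_new, k_new, m_new = romt_energy(rho0, rho1, v_new, cfg_stage, traj_new)
                if not np.isfinite(e_new):
                    raise FloatingPointError("non-finite energy during line search")
                if e_new <= e_total + config.armijo_c1 * t * slope:
                    accepted = True
                    break
                t *= config.armijo_contraction
            if not accepted:
                break
            any_step_accepted = True
            rel_decrease = (e_total - e_new) / max(abs(e_total), 1e-300)
            v, traj, ops = v_new, traj_new, ops_new
            e_total, e_kin, e_mis = e_new, k_new, m_new
            energy_log.append(e_total)
            if rel_decrease < config.convergence_tol:
                converged = True
                break

    if not any_step_accepted and not converged:
        msg = "line search failed at the first iteration; returning v = 0"
        warnings.warn(msg)
        warns.append(msg)

    vel = VelocityField(v, grid, frame_interval_s)
    return IntervalSolution(
        velocity=vel,
        trajectory=traj,
        energy_total=e_total,
        energy_kinetic=e_kin,
        energy_mismatch=e_mis,
        energy_log=energy_log,
        stage_starts=stage_starts,
        n_iterations=total_iters,
        converged=converged,
        frame_index=frame_index,
        warnings=warns,
    )


def solve_series(
    pc: PercentChangeSeries,
    config: Optional[RomtConfig] = None,
    mask: Optional[np.ndarray] = None,
) -> List[IntervalSolution]:
    """Run the pair solver between each pair of adjacent frames (F-1 solutions)."""
    config = config or RomtConfig()
    if pc.n_frames < 2:
        raise ValueError("need at least 2 frames")
    out = []
    for i in range(pc.n_frames - 1):
        dt = float(pc.frame_times_s[i + 1] - pc.frame_times_s[i])
        logger.info("rOMT solve for frame pair %d -> %d (dt=%.0f s)", i, i + 1, dt)
        out.append(
            solve_pair(
                pc.frames[i],
                pc.frames[i + 1],
                config,
                grid=pc.grid,
                frame_interval_s=dt,
                mask=mask,
                frame_index=i,
            )
        )
    return out
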