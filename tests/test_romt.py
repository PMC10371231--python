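"""Transport operators, energy/adjoint consistency, and the pair solver."""

import numpy as np
import pytest

from glymphflow.grids import ImageGrid, PercentChangeSeries
from glymphflow.romt import (
    RomtConfig,
    advect_diffuse_step,
    forward_solve,
    romt_energy,
    romt_gradient,
    sigma_vox_from_physical,
    solve_pair,
    solve_series,
)

from conftest import gaussian_blob


class TestAdvectDiffuseStep:
    def test_identity_when_no_velocity_no_diffusion(self, rng):
        cfg = RomtConfig(sigma=0.0)
        rho = rng.random((8, 8, 8))
        v = np.zeros((8, 8, 8, 3))
        assert np.allclose(advect_diffuse_step(rho, v, cfg), rho, atol=1e-14)

    def test_unit_velocity_shifts_impulse_one_voxel(self):
        cfg = RomtConfig(sigma=0.0)
        rho = np.zeros((8, 8, 8))
        rho[3, 4, 4] = 2.0
        v = np.zeros((8, 8, 8, 3))
        v[..., 0] = 1.0
        out = advect_diffuse_step(rho, v, cfg)
        assert out[4, 4, 4] == pytest.approx(2.0)
        assert out.sum() == pytest.approx(2.0)

    def test_implicit_diffusion_matches_dense_neumann_solve(self, rng):
        """(I - sigma L)^-1 via the spectral route equals a dense linear solve."""
        dims = (8, 8, 8)
        n = 512
        sigma = 0.15
        L = np.zeros((n, n))
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    row = (i * 8 + j) * 8 + k
                    for axis, (a, b, c) in enumerate([(i, j, k)] * 3):
                        pass
                    for d, (di, dj, dk) in enumerate(
                        [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
                    ):
                        ii, jj, kk = i + di, j + dj, k + dk
                        # mirrored (zero-flux) neighbour
                        ii, jj, kk = np.clip([ii, jj, kk], 0, 7)
                        col = (ii * 8 + jj) * 8 + kk
                        L[row, col] += 1.0
                        L[row, row] -= 1.0
        rho = gaussian_blob(dims, (3.5, 3.5, 3.5), width=1.5, amplitude=1.0)
        cfg = RomtConfig(sigma=sigma)
        out = advect_diffuse_step(rho, np.zeros(dims + (3,)), cfg)
        dense = np.linalg.solve(np.eye(n) - sigma * L, rho.ravel()).reshape(dims)
        assert np.max(np.abs(out - dense)) < 1e-8

    def test_cg_and_spectral_diffusion_agree(self, rng):
        rho = rng.random((10, 10, 10))
        v = np.zeros((10, 10, 10, 3))
        a = advect_diffuse_step(rho, v, RomtConfig(sigma=0.05, diffusion_solver="dct"))
        b = advect_diffuse_step(rho, v, RomtConfig(sigma=0.05, diffusion_solver="cg"))
        assert np.allclose(a, b, atol=1e-7)

    def test_nonnegativity_preserved(self, rng):
        cfg = RomtConfig(sigma=0.01)
        rho = rng.random((8, 8, 8))
        v = 0.5 * rng.standard_normal((8, 8, 8, 3))
        out = advect_diffuse_step(rho, v, cfg)
        assert out.min() > -1e-10


class TestForwardSolve:
    def test_zero_velocity_trajectory_constant(self, rng):
        cfg = RomtConfig(sigma=0.0)
        rho = rng.random((8, 8, 8))
        traj = forward_solve(rho, np.zeros((4, 8, 8, 8, 3)), cfg)
        assert all(np.allclose(traj[k], rho, atol=1e-14) for k in range(5))

    def test_composition_matches_manual_substeps_bitwise(self, rng):
        cfg = RomtConfig(sigma=0.003)
        rho = rng.random((8, 8, 8))
        v = 0.3 * rng.standard_normal((4, 8, 8, 8, 3))
        traj = forward_solve(rho, v, cfg)
        manual = rho
        for k in range(4):
            manual = advect_diffuse_step(manual, v[k], cfg)
        assert np.array_equal(traj[4], manual)

    def test_mass_conserved_over_forty_substeps(self):
        """Interior-supported flow: total mass drift < 1e-8 relative."""
        dims = (16, 16, 16)
        cfg = RomtConfig(sigma=0.002)
        rho = gaussian_blob(dims, (6.0, 8.0, 8.0), width=1.5)
        v = np.zeros((40,) + dims + (3,))
        v[..., 0] = 0.05  # 2 voxels total displacement, interior support
        traj = forward_solve(rho, v, cfg)
        masses = traj.sum(axis=(1, 2, 3))
        assert np.max(np.abs(masses - masses[0]) / masses[0]) < 1e-8

    def test_constant_velocity_moves_centroid(self):
        dims = (16, 16, 16)
        cfg = RomtConfig(sigma=0.0)
        rho = gaussian_blob(dims, (5.0, 8.0, 8.0), width=1.5)
        v = np.zeros((4,) + dims + (3,))
        v[..., 0] = 0.5  # total displacement 2 voxels
        traj = forward_solve(rho, v, cfg)
        x = np.arange(16.0)[:, None, None]
        c0 = (traj[0] * x).sum() / traj[0].sum()
        c1 = (traj[4] * x).sum() / traj[4].sum()
        assert c1 - c0 == pytest.approx(2.0, abs=0.1)


class TestRomtEnergy:
    def test_zero_everything_gives_zero_energy(self, rng):
        cfg = RomtConfig(sigma=0.0, beta=100.0)
        rho = rng.random((8, 8, 8))
        v = np.zeros((3, 8, 8, 8, 3))
        total, kin, mis = romt_energy(rho, rho, v, cfg)
        assert total == 0.0 and kin == 0.0 and mis == 0.0

    def test_zero_velocity_energy_is_beta_weighted_mismatch(self, rng):
        cfg = RomtConfig(sigma=0.0, beta=250.0)
        rho0 = rng.random((8, 8, 8))
        rho1 = rng.random((8, 8, 8))
        total, kin, mis = romt_energy(rho0, rho1, np.zeros((3, 8, 8, 8, 3)), cfg)
        assert kin == 0.0
        assert total == pytest.approx(250.0 * np.sum((rho0 - rho1) ** 2), rel=1e-12)

    def test_kinetic_matches_independent_quadrature(self, rng):
        """Re-summation over the stored trajectory reproduces the kinetic term."""
        cfg = RomtConfig(sigma=0.004, beta=10.0)
        rho0 = 1.0 + rng.random((8, 8, 8))
        rho1 = 1.0 + rng.random((8, 8, 8))
        m = 4
        v = 0.2 * rng.standard_normal((m, 8, 8, 8, 3))
        traj = forward_solve(rho0, v, cfg)
        total, kin, mis = romt_energy(rho0, rho1, v, cfg, traj)
        kin_ref = m * sum(
            float(np.sum(traj[k] * np.sum(v[k] ** 2, axis=-1))) for k in range(m)
        )
        mis_ref = 10.0 * float(np.sum((traj[m] - rho1) ** 2))
        assert kin == pytest.approx(kin_ref, rel=1e-10)
        assert mis == pytest.approx(mis_ref, rel=1e-10)
        assert total == pytest.approx(kin_ref + mis_ref, rel=1e-10)


class TestAdjointGradient:
    def test_matches_central_finite_differences(self, rng):
        """Adjoint gradient vs central differences: relative error < 1e-4 on 6^3."""
        dims = (6, 6, 6)
        cfg = RomtConfig(sigma=0.01, beta=100.0, n_substeps=3)
        rho0 = 1.0 + rng.random(dims)
        rho1 = 1.0 + rng.random(dims)
        v = 0.3 * rng.standard_normal((3,) + dims + (3,))
        g = romt_gradient(rho0, rho1, v, cfg)
        for _ in range(3):
            d = rng.standard_normal(v.shape)
            d /= np.linalg.norm(d)
            eps = 1e-5
            ep = romt_energy(rho0, rho1, v + eps * d, cfg)[0]
            em = romt_energy(rho0, rho1, v - eps * d, cfg)[0]
            fd = (ep - em) / (2 * eps)
            ad = float(np.sum(g * d))
            assert ad == pytest.approx(fd, rel=1e-4)


class TestSolvePair:
    def test_identical_frames_recover_near_zero_velocity(self, rng):
        cfg = RomtConfig(sigma=0.0, n_substeps=2, max_outer_iterations=8)
        rho = 1.0 + gaussian_blob((10, 10, 10), (4.5, 4.5, 4.5), width=2.0, amplitude=5.0)
        sol = solve_pair(rho, rho.copy(), cfg, frame_interval_s=300.0)
        mean_speed = np.mean(np.linalg.norm(sol.velocity.v, axis=-1))
        assert mean_speed < 1e-3

    def test_energy_descends_within_each_stage(self):
        dims = (12, 12, 12)
        rho0 = gaussian_blob(dims, (4.5, 5.5, 5.5), width=1.5) + 1e-3
        rho1 = gaussian_blob(dims, (6.5, 5.5, 5.5), width=1.5) + 1e-3
        cfg = RomtConfig(sigma=1e-4, beta=1e4, n_substeps=3, max_outer_iterations=12)
        sol = solve_pair(rho0, rho1, cfg, frame_interval_s=300.0)
        bounds = sol.stage_starts + [len(sol.energy_log)]
        for s, e in zip(bounds[:-1], bounds[1:]):
            stage_log = sol.energy_log[s:e]
            assert all(b <= a + 1e-12 for a, b in zip(stage_log, stage_log[1:]))
        # the final energy never exceeds the v = 0 energy at the target beta
        e0 = romt_energy(rho0, rho1, np.zeros_like(sol.velocity.v), cfg)[0]
        assert sol.energy_total <= e0

    def test_deterministic_bitwise(self):
        dims = (10, 10, 10)
        rho0 = gaussian_blob(dims, (3.5, 4.5, 4.5), width=1.5) + 1e-3
        rho1 = gaussian_blob(dims, (5.5, 4.5, 4.5), width=1.5) + 1e-3
        cfg = RomtConfig(sigma=1e-3, n_substeps=2, max_outer_iterations=8)
        a = solve_pair(rho0, rho1, cfg)
        b = solve_pair(rho0, rho1, cfg)
        assert np.array_equal(a.velocity.v, b.velocity.v)
        assert a.energy_log == b.energy_log

    def test_negative_input_rejected(self):
        rho = -np.ones((8, 8, 8))
        with pytest.raises(ValueError, match="nonnegative"):
            solve_pair(rho, np.ones((8, 8, 8)))

    def test_mask_constrains_velocity_support(self):
        dims = (12, 12, 12)
        rho0 = gaussian_blob(dims, (4.5, 5.5, 5.5), width=1.5) + 1e-3
        rho1 = gaussian_blob(dims, (6.5, 5.5, 5.5), width=1.5) + 1e-3
        mask = np.zeros(dims, bool)
        mask[2:10, 2:10, 2:10] = True
        cfg = RomtConfig(sigma=1e-4, n_substeps=2, max_outer_iterations=8)
        sol = solve_pair(rho0, rho1, cfg, mask=mask)
        assert np.all(sol.velocity.v[:, ~mask] == 0.0)

    def test_wasserstein_limit_trend(self):
        """Translated-Gaussian kinetic energy approaches W2^2 = mass*|d|^2
        as sigma -> 0 and beta grows."""
        dims = (16, 16, 16)
        rho0 = gaussian_blob(dims, (5.5, 7.5, 7.5), width=2.0) + 1e-3
        rho1 = gaussian_blob(dims, (7.5, 7.5, 7.5), width=2.0) + 1e-3
        w2 = rho0.sum() * 4.0  # |d| = 2 voxels
        errs = []
        for sigma, beta in ((0.01, 1e2), (0.003, 1e3), (1e-4, 1e4)):
            cfg = RomtConfig(
                sigma=sigma, beta=beta, n_substeps=4, max_outer_iterations=16,
                inner_cg_maxiter=10,
            )
            sol = solve_pair(rho0, rho1, cfg)
            errs.append(abs(sol.energy_kinetic - w2) / w2)
        assert errs[2] < errs[0]
        assert errs[2] < 0.2


class TestSolveSeries:
    def _pc(self, frames):
        frames = np.asarray(frames)
        grid = ImageGrid(frames.shape[1:], 0.3)
        times = np.arange(frames.shape[0]) * 300.0
        return PercentChangeSeries(frames, times, grid)

    def test_three_identical_frames_give_two_quiet_solutions(self):
        rho = gaussian_blob((10, 10, 10), (4.5, 4.5, 4.5), width=2.0) + 1e-3
        cfg = RomtConfig(sigma=0.0, n_substeps=2, max_outer_iterations=4)
        sols = solve_series(self._pc([rho, rho, rho]), cfg)
        assert len(sols) == 2
        for s in sols:
            assert np.mean(np.linalg.norm(s.velocity.v, axis=-1)) < 1e-3

    def test_solution_count_is_frames_minus_one(self):
        rho = gaussian_blob((8, 8, 8), (3.5, 3.5, 3.5), width=1.5) + 1e-3
        cfg = RomtConfig(sigma=0.0, n_substeps=1, max_outer_iterations=2)
        sols = solve_series(self._pc([rho] * 5), cfg)
        assert len(sols) == 4

    def test_piecewise_motion_localised_to_first_interval(self):
        dims = (12, 12, 12)
        a = gaussian_blob(dims, (3.5, 5.5, 5.5), width=1.5) + 1e-3
        b = gaussian_blob(dims, (6.5, 5.5, 5.5), width=1.5) + 1e-3
        cfg = RomtConfig(sigma=1e-4, n_substeps=3, max_outer_iterations=16)
        sols = solve_series(self._pc([a, b, b]), cfg)
        core = b > 0.1 * b.max()
        disp1 = np.linalg.norm(
            sols[0].velocity.v.sum(axis=0)[core], axis=-1
        ).mean()  # summed over substeps = total displacement
        disp2 = np.linalg.norm(sols[1].velocity.v.sum(axis=0)[core], axis=-1).mean()
        assert disp1 > 1.5  # moved ~3 voxels
        assert disp2 < 0.3 * disp1

    def test_single_frame_rejected(self):
        rho = np.ones((8, 8, 8))
        with pytest.raises(ValueError, match="2 frames"):
            solve_series(self._pc([rho]))


def test_sigma_unit_conversion():
    # 3e-4 mm^2/s over 300 s on 0.3 mm voxels with 8 substeps
    assert sigma_vox_from_physical(3e-4, 0.3, 300.0, 8) == pytest.approx(0.125)
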