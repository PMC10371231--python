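"""Pathline tracing, speed maps, transport metrics and flux vectors."""

import numpy as np
import pytest

from glymphflow.glad import (
    GladConfig,
    Pathlines,
    flux_vectors,
    speed_map,
    trace_pathlines,
    transport_metrics,
)
from glymphflow.grids import ImageGrid
from glymphflow.romt import IntervalSolution, VelocityField

DIMS = (24, 24, 24)
VOX = 0.3
INTERVAL_S = 300.0


def make_solution(v, rho0=None, grid=None, n_substeps=None):
    """Wrap a velocity array (m, nx, ny, nz, 3) into an IntervalSolution."""
    grid = grid or ImageGrid(DIMS, VOX)
    m = v.shape[0]
    if rho0 is None:
        rho0 = np.ones(grid.dims)
    traj = np.stack([rho0] * (m + 1))
    vf = VelocityField(v, grid, INTERVAL_S)
    return IntervalSolution(vf, traj, 0.0, 0.0, 0.0)


def central_blob(grid, center, width=2.0):
    x = np.stack(
        np.meshgrid(*[np.arange(float(d)) for d in grid.dims], indexing="ij"), -1
    )
    return np.exp(-0.5 * np.sum((x - np.asarray(center)) ** 2, -1) / width**2)


class TestTracePathlines:
    def test_zero_velocity_stationary_and_unretained(self):
        sol = make_solution(np.zeros((4,) + DIMS + (3,)))
        pl = trace_pathlines([sol])
        assert np.allclose(pl.positions_mm[:, 0], pl.positions_mm[:, -1])
        assert pl.n_retained == 0

    def test_constant_velocity_straight_equal_displacement(self):
        grid = ImageGrid(DIMS, VOX)
        m = 4
        v = np.zeros((m,) + DIMS + (3,))
        v[..., 0] = 0.5  # voxels per substep
        rho0 = central_blob(grid, (8.0, 12.0, 12.0))
        sol = make_solution(v, rho0)
        pl = trace_pathlines([sol])
        disp = pl.positions_mm[:, -1] - pl.positions_mm[:, 0]
        # every seed displaced by v*T = 0.5*4 voxels = 0.6 mm along x
        assert np.allclose(disp[:, 0], 0.5 * m * VOX, atol=1e-9)
        assert np.allclose(disp[:, 1:], 0.0, atol=1e-9)
        assert pl.retained.all()
        # per-step speed is |v| in um/s
        expected_um_s = 0.5 * VOX * 1000 * m / INTERVAL_S
        assert np.allclose(pl.speeds_um_s, expected_um_s)

    def test_rotation_orbit_radius_drift_below_one_percent(self):
        """One full revolution in 64 RK4 steps keeps the orbit radius."""
        grid = ImageGrid((32, 32, 32), VOX)
        dims = grid.dims
        m = 64
        theta = 2 * np.pi / m  # rotation angle per substep
        x = np.stack(
            np.meshgrid(*[np.arange(float(d)) for d in dims], indexing="ij"), -1
        )
        c = np.array([15.5, 15.5, 0.0])
        v = np.zeros((m,) + dims + (3,))
        # angular velocity theta per substep about the z axis through c
        v[..., 0] = -theta * (x[..., 1] - c[1])
        v[..., 1] = theta * (x[..., 0] - c[0])
        rho0 = np.zeros(dims)
        seed = (21, 15, 15)  # radius 5.5 voxels from the axis
        rho0[seed] = 1.0
        sol = make_solution(v, rho0, grid)
        pl = trace_pathlines([sol], config=GladConfig(seed_threshold_frac=0.5))
        pos_idx = grid.mm_to_index(pl.positions_mm[0])
        radii = np.linalg.norm(pos_idx[:, :2] - c[:2], axis=1)
        drift = np.abs(radii - radii[0]) / radii[0]
        assert drift.max() < 0.01
        # closed orbit: flux vector much shorter than the circumference
        vecs = flux_vectors(pl)
        if vecs:  # retained only if net displacement >= 0.5 voxel
            circumference = 2 * np.pi * radii[0] * VOX
            assert vecs[0].magnitude_mm < 0.02 * circumference
        else:
            end_err = np.linalg.norm(pos_idx[-1] - pos_idx[0])
            assert end_err < 0.5

    def test_no_seeds_raises_with_threshold(self):
        sol = make_solution(np.zeros((2,) + DIMS + (3,)), rho0=np.zeros(DIMS))
        with pytest.raises(ValueError, match="threshold"):
            trace_pathlines([sol])

    def test_concatenation_across_intervals(self):
        v1 = np.zeros((2,) + DIMS + (3,))
        v1[..., 0] = 0.5
        v2 = np.zeros((2,) + DIMS + (3,))
        v2[..., 1] = 0.25
        grid = ImageGrid(DIMS, VOX)
        rho0 = central_blob(grid, (10.0, 10.0, 12.0))
        sols = [make_solution(v1, rho0), make_solution(v2, rho0)]
        pl = trace_pathlines(sols)
        disp_vox = (pl.positions_mm[:, -1] - pl.positions_mm[:, 0]) / VOX
        assert np.allclose(disp_vox[:, 0], 1.0, atol=1e-9)
        assert np.allclose(disp_vox[:, 1], 0.5, atol=1e-9)


class TestSpeedMap:
    def test_single_pathline_deposits_constant_speed(self):
        grid = ImageGrid(DIMS, VOX)
        positions = grid.index_to_mm(
            np.array([[[2.0, 3.0, 3.0], [3.0, 3.0, 3.0], [4.0, 3.0, 3.0]]])
        )
        speeds = np.full((1, 3), 2.5)
        pl = Pathlines(positions, speeds, np.array([[2, 3, 3]]), np.array([True]), grid)
        sm = speed_map(pl)
        assert sm.values_um_s[2, 3, 3] == 2.5
        assert sm.values_um_s[3, 3, 3] == 2.5
        assert sm.values_um_s[4, 3, 3] == 2.5
        assert np.count_nonzero(sm.values_um_s) == 3

    def test_shared_voxel_averages_speeds(self):
        grid = ImageGrid(DIMS, VOX)
        p = grid.index_to_mm(np.array([[[5.0, 5.0, 5.0]], [[5.0, 5.0, 5.0]]]))
        speeds = np.array([[2.0], [4.0]])
        pl = Pathlines(
            p, speeds, np.array([[5, 5, 5], [5, 5, 5]]), np.array([True, True]), grid
        )
        sm = speed_map(pl)
        assert sm.values_um_s[5, 5, 5] == pytest.approx(3.0)

    def test_unretained_pathlines_do_not_deposit(self):
        grid = ImageGrid(DIMS, VOX)
        p = grid.index_to_mm(np.array([[[5.0, 5.0, 5.0]]]))
        pl = Pathlines(p, np.array([[2.0]]), np.array([[5, 5, 5]]), np.array([False]), grid)
        assert np.count_nonzero(speed_map(pl).values_um_s) == 0

    def test_single_pathline_map_mean_equals_pathline_mean(self):
        grid = ImageGrid(DIMS, VOX)
        # distinct voxels, one visit each: map mean over visited = pathline mean
        idx = np.array([[[2.0, 2.0, 2.0], [4.0, 2.0, 2.0], [6.0, 2.0, 2.0]]])
        speeds = np.array([[1.0, 2.0, 3.0]])
        pl = Pathlines(
            grid.index_to_mm(idx), speeds, np.array([[2, 2, 2]]), np.array([True]), grid
        )
        sm = speed_map(pl)
        vals = sm.values_um_s[sm.values_um_s > 0]
        assert vals.mean() == pytest.approx(speeds.mean(), abs=1e-10)


class TestTransportMetrics:
    def test_worked_example(self):
        grid = ImageGrid(DIMS, VOX)
        sm_vals = np.zeros(DIMS)
        sm_vals[1, 1, 1] = 1.0
        sm_vals[2, 2, 2] = 3.0
        from glymphflow.glad import SpeedMap

        m = transport_metrics(SpeedMap(sm_vals, grid), np.ones(DIMS, bool))
        assert m.mean_speed_um_s == pytest.approx(2.0)
        assert m.v_flux_mm3 == pytest.approx(2 * VOX**3)

    def test_all_zero_map(self):
        grid = ImageGrid(DIMS, VOX)
        from glymphflow.glad import SpeedMap

        m = transport_metrics(SpeedMap(np.zeros(DIMS), grid), np.ones(DIMS, bool))
        assert m.mean_speed_um_s == 0.0 and m.v_flux_mm3 == 0.0

    def test_empty_mask_raises(self):
        grid = ImageGrid(DIMS, VOX)
        from glymphflow.glad import SpeedMap

        with pytest.raises(ValueError, match="empty mask"):
            transport_metrics(SpeedMap(np.zeros(DIMS), grid), np.zeros(DIMS, bool))

    def test_vflux_additive_over_partition(self, rng):
        grid = ImageGrid(DIMS, VOX)
        from glymphflow.glad import SpeedMap

        vals = np.where(rng.random(DIMS) > 0.7, rng.random(DIMS), 0.0)
        brain = np.ones(DIMS, bool)
        csf = rng.random(DIMS) > 0.5
        tissue = ~csf
        sm = SpeedMap(vals, grid)
        total = transport_metrics(sm, brain).v_flux_mm3
        parts = (
            transport_metrics(sm, csf, "csf").v_flux_mm3
            + transport_metrics(sm, tissue, "tissue").v_flux_mm3
        )
        assert total == pytest.approx(parts, abs=1e-10)


class TestFluxVectors:
    def test_constant_velocity_vector(self):
        grid = ImageGrid(DIMS, VOX)
        m = 4
        v = np.zeros((m,) + DIMS + (3,))
        v[..., 2] = 0.5
        rho0 = central_blob(grid, (12.0, 12.0, 8.0))
        pl = trace_pathlines([make_solution(v, rho0)])
        vecs = flux_vectors(pl)
        assert len(vecs) == pl.n_retained > 0
        for vec in vecs[:10]:
            assert np.allclose(vec.displacement_mm, [0, 0, 0.5 * m * VOX], atol=1e-9)
            assert vec.magnitude_mm == pytest.approx(
                np.linalg.norm(vec.displacement_mm)
            )

    def test_monotone_seeding_lowering_threshold_never_lowers_vflux(self):
        grid = ImageGrid(DIMS, VOX)
        m = 4
        v = np.zeros((m,) + DIMS + (3,))
        v[..., 0] = 0.4
        rho0 = central_blob(grid, (10.0, 12.0, 12.0), width=3.0)
        fluxes = []
        for frac in (0.5, 0.2, 0.05):
            pl = trace_pathlines(
                [make_solution(v, rho0)], config=GladConfig(seed_threshold_frac=frac)
            )
            sm = speed_map(pl)
            fluxes.append(transport_metrics(sm, np.ones(grid.dims, bool)).v_flux_mm3)
        assert fluxes[0] <= fluxes[1] <= fluxes[2]
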