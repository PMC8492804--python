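import numpy as np
import pandas as pd
import pytest

from quorumdim.calibration import (
    fit_calibration,
    invert_pair,
    trajectory_on_surface,
)
from quorumdim.errors import MissingNodeError, OutOfRangeError
from quorumdim.io import ConditionGrid
from quorumdim.scoord import SSurface, axis_transform


def cal_grid():
    # spans the calibrated ranges: C8HSL 0-800 nM, 3OC6HSL 0-200 nM
    return ConditionGrid(
        c8_levels=(0, 5, 10, 25, 50, 100, 300, 800),
        oc6_levels=(0, 5, 10, 25, 50, 100, 150, 200),
    )


def hill(c, k, n, top):
    return top * c**n / (k**n + c**n)


def hill_pair():
    """Two complementary sensors: one prefers c8, the other oc6."""
    grid = cal_grid()
    C8, OC6 = np.meshgrid(grid.c8_levels, grid.oc6_levels, indexing="ij")
    r1 = hill(C8, 50, 1.5, 1e4) + 0.1 * hill(OC6, 40, 1.5, 1e4) + 50
    r2 = hill(OC6, 30, 1.5, 2e4) + 0.15 * hill(C8, 60, 1.5, 2e4) + 80
    return grid, fit_calibration(grid, r1), fit_calibration(grid, r2)


class TestFitCalibration:
    def test_constant_response(self):
        grid = cal_grid()
        cal = fit_calibration(grid, np.full(grid.shape, 123.0))
        assert cal(37.0, 88.0) == pytest.approx(123.0)

    def test_bilinear_exact_on_transformed_coordinate(self):
        grid = cal_grid()
        U1, _ = np.meshgrid(
            axis_transform(np.array(grid.c8_levels)),
            axis_transform(np.array(grid.oc6_levels)),
            indexing="ij",
        )
        cal = fit_calibration(grid, U1)
        for c8 in (3.0, 40.0, 600.0):
            assert cal(c8, 77.0) == pytest.approx(axis_transform(c8), abs=1e-12)

    def test_hill_interpolation_error_bounded(self):
        grid, cal1, _ = hill_pair()
        rng = np.random.default_rng(4)
        dynamic_range = cal1.response.max() - cal1.response.min()
        for _ in range(50):
            c8 = rng.uniform(0, 800)
            oc6 = rng.uniform(0, 200)
            truth = hill(c8, 50, 1.5, 1e4) + 0.1 * hill(oc6, 40, 1.5, 1e4) + 50
            assert abs(cal1(c8, oc6) - truth) < 0.05 * dynamic_range

    def test_missing_node_raises(self):
        grid = cal_grid()
        bad = np.full(grid.shape, 10.0)
        bad[2, 3] = np.nan
        with pytest.raises(MissingNodeError):
            fit_calibration(grid, bad)


class TestInvertPair:
    def test_node_readings_recover_node(self):
        grid, cal1, cal2 = hill_pair()
        c8, oc6 = grid.c8_levels[3], grid.oc6_levels[4]
        res = invert_pair(cal1(c8, oc6), cal2(c8, oc6), cal1, cal2)
        assert res.residual < 1e-9
        assert res.c8_est == pytest.approx(c8, rel=0.02, abs=0.5)
        assert res.oc6_est == pytest.approx(oc6, rel=0.02, abs=0.5)

    def test_off_node_recovery_within_one_cell(self):
        grid, cal1, cal2 = hill_pair()
        refine = 200
        for c8, oc6 in [(17.0, 33.0), (120.0, 8.0), (420.0, 140.0)]:
            res = invert_pair(cal1(c8, oc6), cal2(c8, oc6), cal1, cal2, refine=refine)
            du1 = (axis_transform(800) - 0) / (refine - 1)
            du2 = (axis_transform(200) - 0) / (refine - 1)
            assert abs(axis_transform(res.c8_est) - axis_transform(c8)) <= du1
            assert abs(axis_transform(res.oc6_est) - axis_transform(oc6)) <= du2
            assert res.residual <= 1e-9

    def test_interior_nodes_roundtrip(self):
        grid, cal1, cal2 = hill_pair()
        refine = 120
        du1 = axis_transform(800) / (refine - 1)
        du2 = axis_transform(200) / (refine - 1)
        for c8 in grid.c8_levels[1:-1]:
            for oc6 in grid.oc6_levels[1:-1]:
                res = invert_pair(cal1(c8, oc6), cal2(c8, oc6), cal1, cal2,
                                  refine=refine)
                assert res.residual <= 1e-9
                assert abs(axis_transform(res.c8_est) - axis_transform(c8)) <= du1
                assert abs(axis_transform(res.oc6_est) - axis_transform(oc6)) <= du2

    def test_reading_above_range_raises(self):
        _, cal1, cal2 = hill_pair()
        with pytest.raises(OutOfRangeError):
            invert_pair(cal1.response.max() * 2, 100.0, cal1, cal2)


def lux_like_surface():
    """S rising mostly with oc6, gently with c8 — a lux-flavored response."""
    grid = ConditionGrid(
        c8_levels=(0, 10, 20, 50, 100, 200, 500),
        oc6_levels=(0, 10, 20, 30, 50, 100, 200, 500),
    )
    u1 = axis_transform(np.array(grid.c8_levels))
    u2 = axis_transform(np.array(grid.oc6_levels))
    U1, U2 = np.meshgrid(u1, u2, indexing="ij")
    node_s = np.clip(0.08 + 0.45 * np.clip(U2 - 1.0, 0, None) + 0.02 * U1, 0, 1)
    u = np.linspace(0, 1, 2)
    return SSurface(grid=grid, node_s=node_s, u1_nodes=u1, u2_nodes=u2,
                    u1_dense=u, u2_dense=u, dense_s=np.zeros((2, 2)))


class TestTrajectoryOnSurface:
    def test_constant_surface(self):
        surf = lux_like_surface()
        const = SSurface(
            grid=surf.grid, node_s=np.full_like(surf.node_s, 0.3),
            u1_nodes=surf.u1_nodes, u2_nodes=surf.u2_nodes,
            u1_dense=surf.u1_dense, u2_dense=surf.u2_dense, dense_s=surf.dense_s,
        )
        traj = pd.DataFrame({"od600": [0.1, 0.5, 1.0],
                             "c8_est": [1, 50, 400], "oc6_est": [0.5, 3, 15]})
        out = trajectory_on_surface(traj, const)
        assert np.allclose(out["s"], 0.3)
        assert not out["clamped"].any()

    def test_linear_interpolation_along_a_row(self):
        surf = lux_like_surface()
        # along oc6 between two nodes at fixed c8 = 0 the interpolation is linear
        oc6_a, oc6_b = 100.0, 200.0
        s_a = surf.node_s[0, 5]
        s_b = surf.node_s[0, 6]
        mid_u = (axis_transform(oc6_a) + axis_transform(oc6_b)) / 2
        oc6_mid = 10 * 10 ** (mid_u - 1)
        traj = pd.DataFrame({"od600": [1.0], "c8_est": [0.0], "oc6_est": [oc6_mid]})
        out = trajectory_on_surface(traj, surf)
        assert out["s"].iloc[0] == pytest.approx((s_a + s_b) / 2, abs=1e-12)

    def test_slow_oc6_trajectory_hugs_low_s_contour(self):
        # c8 rises quickly, oc6 stays low until late growth: S stays in a
        # narrow band until the final point
        surf = lux_like_surface()
        od = np.array([0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2])
        c8 = np.array([0.5, 2, 10, 60, 150, 250, 350, 450])
        oc6 = np.array([0.1, 0.3, 0.8, 2, 4, 7, 12, 60])
        out = trajectory_on_surface(
            pd.DataFrame({"od600": od, "c8_est": c8, "oc6_est": oc6}), surf
        )
        early = out["s"].iloc[:-1]
        assert early.max() - early.min() < 0.15
        assert out["s"].iloc[-1] > early.max()
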