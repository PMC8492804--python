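"""Two-reporter HSL quantification.

Two sensor strains with complementary HSL preferences are calibrated on a
concentration grid (luminescence response per node).  A pair of readings
from the two strains is inverted to a (C8HSL, 3OC6HSL) estimate by searching
the calibrated plane for the concentrations whose predicted responses best
match the readings in log-compressed least squares — luminescence spans
orders of magnitude, so the objective uses log(1 + r).  Concentration
trajectories recorded during culture growth can then be overlaid on a
response surface S to read off what output distributions a growing culture
actually visits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import minimize

from .errors import MissingNodeError, OutOfRangeError
from .io import ConditionGrid
from .scoord import SSurface, axis_transform


@dataclass(frozen=True)
class CalibrationSurface:
    grid: ConditionGrid
    response: np.ndarray         # (len(c8_levels), len(oc6_levels)), >= 0
    u1_nodes: np.ndarray
    u2_nodes: np.ndarray

    def interpolator(self):
        return RegularGridInterpolator(
            (self.u1_nodes, self.u2_nodes), self.response, method="linear"
        )

    def __call__(self, c8, oc6):
        pts = np.stack(
            [np.atleast_1d(axis_transform(c8)), np.atleast_1d(axis_transform(oc6))], axis=1
        )
        out = self.interpolator()(pts)
        return float(out[0]) if out.size == 1 else out


def fit_calibration(grid: ConditionGrid, response) -> CalibrationSurface:
    """Build a bilinear interpolator over the transformed concentration axes."""
    response = np.asarray(response, dtype=float)
    if response.shape != grid.shape:
        raise MissingNodeError(
            f"response shape {response.shape} does not match grid {grid.shape}"
        )
    if not np.all(np.isfinite(response)):
        bad = np.argwhere(~np.isfinite(response))
        raise MissingNodeError(f"non-finite response at grid nodes {bad.tolist()}")
    if np.any(response < 0):
        raise ValueError("luminescence response must be non-negative")
    return CalibrationSurface(
        grid=grid,
        response=response,
        u1_nodes=axis_transform(np.array(grid.c8_levels)),
        u2_nodes=axis_transform(np.array(grid.oc6_levels)),
    )


class InversionResult(NamedTuple):
    c8_est: float
    oc6_est: float
    residual: float
    boundary: bool
    near_degenerate: list  # (c8, oc6, residual) minima within 5% of the best


def invert_pair(
    r1: float,
    r2: float,
    cal1: CalibrationSurface,
    cal2: CalibrationSurface,
    refine: int = 200,
) -> InversionResult:
    """Invert a pair of readings to concentrations on the calibrated plane.

    Grid search over a ``refine`` x ``refine`` transformed grid minimizing
    sum_i (log(1+r_i) - log(1+cal_i))^2, followed by Nelder-Mead refinement.
    Solutions touching the calibrated boundary are flagged, and local grid
    minima whose residual is within 5% of the best (plus a floor for exactly
    realizable readings) are reported as near-degenerate alternatives.
    """
    if not np.allclose(cal1.u1_nodes, cal2.u1_nodes) or not np.allclose(
        cal1.u2_nodes, cal2.u2_nodes
    ):
        raise ValueError("both calibrations must share one grid")
    for name, r, cal in (("r1", r1, cal1), ("r2", r2, cal2)):
        if r < 0 or r > cal.response.max():
            raise OutOfRangeError(
                f"{name}={r} outside calibrated range [0, {cal.response.max()}]"
            )

    f1, f2 = cal1.interpolator(), cal2.interpolator()
    t1, t2 = np.log1p(r1), np.log1p(r2)

    def objective(u):
        pt = np.asarray(u)[None, :]
        return float(
            (t1 - np.log1p(f1(pt)[0])) ** 2 + (t2 - np.log1p(f2(pt)[0])) ** 2
        )

    lo1, hi1 = cal1.u1_nodes[0], cal1.u1_nodes[-1]
    lo2, hi2 = cal1.u2_nodes[0], cal1.u2_nodes[-1]
    u1g = np.linspace(lo1, hi1, refine)
    u2g = np.linspace(lo2, hi2, refine)
    U1, U2 = np.meshgrid(u1g, u2g, indexing="ij")
    pts = np.stack([U1.ravel(), U2.ravel()], axis=1)
    obj = (t1 - np.log1p(f1(pts))) ** 2 + (t2 - np.log1p(f2(pts))) ** 2
    obj = obj.reshape(refine, refine)
    best_flat = int(np.argmin(obj))
    i1, i2 = np.unravel_index(best_flat, obj.shape)

    res = minimize(
        objective,
        x0=np.array([u1g[i1], u2g[i2]]),
        method="Nelder-Mead",
        bounds=[(lo1, hi1), (lo2, hi2)],
        options={"xatol": 1e-10, "fatol": 1e-18},
    )
    u_best = np.clip(res.x, [lo1, lo2], [hi1, hi2])
    residual = float(objective(u_best))

    # local minima of the residual landscape within 5% of the best
    interior = obj[1:-1, 1:-1]
    is_min = (
        (interior <= obj[:-2, 1:-1]) & (interior <= obj[2:, 1:-1])
        & (interior <= obj[1:-1, :-2]) & (interior <= obj[1:-1, 2:])
    )
    thresh = max(residual * 1.05, residual + 1e-12)
    cand = np.argwhere(is_min & (interior <= thresh)) + 1
    du = max(u1g[1] - u1g[0], u2g[1] - u2g[0])
    near = []
    for j1, j2 in cand:
        if abs(u1g[j1] - u_best[0]) < 2 * du and abs(u2g[j2] - u_best[1]) < 2 * du:
            continue
        near.append(
            (
                float(_u_to_c(u1g[j1])),
                float(_u_to_c(u2g[j2])),
                float(obj[j1, j2]),
            )
        )

    tol = 1e-9
    boundary = bool(
        np.any(np.isclose(u_best, [lo1, lo2], atol=tol))
        or np.any(np.isclose(u_best, [hi1, hi2], atol=tol))
    )
    return InversionResult(
        c8_est=float(_u_to_c(u_best[0])),
        oc6_est=float(_u_to_c(u_best[1])),
        residual=residual,
        boundary=boundary,
        near_degenerate=near,
    )


def _u_to_c(u: float) -> float:
    return 10.0 * u if u <= 1.0 else 10.0 * 10.0 ** (u - 1.0)


def trajectory_on_surface(points: pd.DataFrame, surface: SSurface) -> pd.DataFrame:
    """Interpolate S at each trajectory (c8_est, oc6_est); clamp + flag outside.

    ``points`` needs columns od600, c8_est, oc6_est.  Returns a copy with
    columns ``s`` and ``clamped``.
    """
    interp = RegularGridInterpolator(
        (surface.u1_nodes, surface.u2_nodes), surface.node_s, method="linear"
    )
    u1 = np.asarray(axis_transform(points["c8_est"].to_numpy()))
    u2 = np.asarray(axis_transform(points["oc6_est"].to_numpy()))
    lo1, hi1 = surface.u1_nodes[0], surface.u1_nodes[-1]
    lo2, hi2 = surface.u2_nodes[0], surface.u2_nodes[-1]
    clamped = (u1 < lo1) | (u1 > hi1) | (u2 < lo2) | (u2 > hi2)
    u1c = np.clip(u1, lo1, hi1)
    u2c = np.clip(u2, lo2, hi2)
    out = points.copy()
    out["s"] = interp(np.stack([u1c, u2c], axis=1))
    out["clamped"] = clamped
    return out
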