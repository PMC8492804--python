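"""Arc-length S coordinate along the 1-D NLPCA manifold, and its surface.

The first nonlinear component defines a curve through the embedded histogram
space.  Position along that curve, rescaled by cumulative chord length to
[0, 1], gives the response coordinate S: equal increments in S correspond to
equal distances between the underlying histograms.  S is then interpolated
over the input-concentration grid in transformed axis coordinates (linear
below 10 concentration units, logarithmic above) to give a response surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .embed import HistogramPoint
from .errors import DegenerateDataError, MissingNodeError
from .io import ConditionGrid
from .nlpca import NlpcaModel, decode, encode

DEFAULT_SWEEP = 512
AXIS_LOG_THRESHOLD = 10.0


def arc_length_rescale(curve: np.ndarray) -> np.ndarray:
    """Normalized cumulative chord length along a polyline; 0 at the first
    vertex, 1 at the last.  Purely geometric: any monotone re-indexing of the
    vertices that preserves the traced curve leaves the values unchanged."""
    curve = np.asarray(curve, dtype=float)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    if cum[-1] < 1e-9:
        raise DegenerateDataError(f"degenerate curve: total length {cum[-1]}")
    return cum / cum[-1]  # endpoints exactly 0 and 1


def axis_transform(c):
    """Concentration -> plot coordinate: c/10 below 10 units, 1+log10(c/10) above."""
    c = np.asarray(c, dtype=float)
    out = np.where(c <= AXIS_LOG_THRESHOLD, c / 10.0,
                   1.0 + np.log10(np.maximum(c, AXIS_LOG_THRESHOLD) / 10.0))
    return out if out.ndim else float(out)


def axis_untransform(u):
    """Inverse of :func:`axis_transform`."""
    u = np.asarray(u, dtype=float)
    out = np.where(u <= 1.0, 10.0 * u, 10.0 * 10.0 ** (u - 1.0))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SCoordinateMap:
    """S per condition plus the decoded curve it was measured along."""

    curve: np.ndarray            # (m, n_bins) unit vectors along the latent sweep
    curve_latents: np.ndarray    # (m,) latent values of the sweep
    curve_s: np.ndarray          # (m,) normalized arc length, 0..1
    s_per_condition: dict        # condition_id -> S in [0, 1]
    orientation: int             # +1 if sweep order kept, -1 if flipped


@dataclass(frozen=True)
class SSurface:
    grid: ConditionGrid
    node_s: np.ndarray           # (len(c8_levels), len(oc6_levels))
    u1_nodes: np.ndarray         # transformed c8 levels
    u2_nodes: np.ndarray         # transformed oc6 levels
    u1_dense: np.ndarray
    u2_dense: np.ndarray
    dense_s: np.ndarray          # (refine, refine), axis 0 = u1


def build_s_map(
    model: NlpcaModel,
    points: Sequence[HistogramPoint],
    sweep: int = DEFAULT_SWEEP,
    zero_condition_id: str | None = None,
) -> SCoordinateMap:
    """Rescale the first nonlinear component to arc length in [0, 1].

    The curve is the decoder image of a dense sweep over the span of the
    training latents (first component, others zero), renormalized onto the
    unit sphere.  Each condition's S is the normalized cumulative chord
    length at its own encoded latent.  Orientation is fixed so the
    zero-input condition (when named) sits at the S = 0 end.
    """
    points = list(points)
    Z = np.atleast_2d(encode(model, points))
    t = Z[:, 0]
    lo, hi = float(t.min()), float(t.max())
    if hi - lo < 1e-12:
        raise DegenerateDataError("degenerate latent range")
    grid_t = np.linspace(lo, hi, sweep)
    latents = np.zeros((sweep, model.n_components))
    latents[:, 0] = grid_t
    curve = np.atleast_2d(decode(model, latents))
    norms = np.linalg.norm(curve, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise DegenerateDataError("decoded curve passes through the origin")
    curve = curve / norms

    cum = arc_length_rescale(curve)

    s_vals = np.interp(t, grid_t, cum)
    orientation = 1
    if zero_condition_id is not None:
        ids = [p.condition_id for p in points]
        if zero_condition_id in ids:
            if s_vals[ids.index(zero_condition_id)] > 0.5:
                s_vals = 1.0 - s_vals
                cum = 1.0 - cum[::-1]
                curve = curve[::-1]
                grid_t = grid_t[::-1]
                orientation = -1
    s_per_condition = {p.condition_id: float(s) for p, s in zip(points, s_vals)}
    return SCoordinateMap(
        curve=curve,
        curve_latents=grid_t,
        curve_s=cum,
        s_per_condition=s_per_condition,
        orientation=orientation,
    )


def build_s_surface(
    s_map: SCoordinateMap | Mapping[str, float],
    grid: ConditionGrid,
    refine: int = 200,
) -> SSurface:
    """Bilinearly interpolate S over the transformed concentration grid."""
    s_values = s_map.s_per_condition if isinstance(s_map, SCoordinateMap) else dict(s_map)
    missing = [cid for cid, _, _ in grid.iter_conditions() if cid not in s_values]
    if missing:
        raise MissingNodeError(f"no S value for conditions: {missing}")
    node_s = np.array(
        [[s_values[grid.condition_id(c8, oc6)] for oc6 in grid.oc6_levels]
         for c8 in grid.c8_levels]
    )
    u1 = axis_transform(np.array(grid.c8_levels))
    u2 = axis_transform(np.array(grid.oc6_levels))
    interp = RegularGridInterpolator((u1, u2), node_s, method="linear")
    u1_dense = np.linspace(u1[0], u1[-1], refine)
    u2_dense = np.linspace(u2[0], u2[-1], refine)
    U1, U2 = np.meshgrid(u1_dense, u2_dense, indexing="ij")
    dense = interp(np.stack([U1.ravel(), U2.ravel()], axis=1)).reshape(refine, refine)
    dense = np.clip(dense, 0.0, 1.0)
    return SSurface(
        grid=grid, node_s=node_s, u1_nodes=u1, u2_nodes=u2,
        u1_dense=u1_dense, u2_dense=u2_dense, dense_s=dense,
    )
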