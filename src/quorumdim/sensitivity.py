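"""Maximum-information input prior: the HSL distribution that flattens S.

A sensing pathway carries the most information about its inputs where the
output changes fastest.  Operationally: find the probability distribution
over the input-concentration plane whose pushforward through the response
surface S is uniform.  By the coarea formula, weighting each surface cell by
|grad S| concentrates mass on steep regions; renormalizing every equal-width
S bin to carry the same total mass then makes all S values equally probable,
which is the mutual-information-maximizing prior for a deterministic
response.

Discretization: the surface is resampled at the centers of an equal-area
cell grid in the transformed coordinates, and each cell's weight is split
across the S bins its own S-span overlaps (the span estimated from the local
gradient, i.e. linear binning).  This keeps bin totals exact to second order
and makes the construction's pushforward uniform to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import FlatSurfaceError
from .scoord import SSurface, axis_untransform

DEFAULT_N_S_BINS = 20


def gradient_magnitude(surface: SSurface) -> np.ndarray:
    """|grad S| w.r.t. the transformed coordinates (u1, u2), on the dense grid.

    Central differences in the interior, one-sided at the boundaries.
    """
    g1, g2 = np.gradient(surface.dense_s, surface.u1_dense, surface.u2_dense)
    return np.hypot(g1, g2)


@dataclass(frozen=True)
class SensitivityPrior:
    """Input prior with uniform S pushforward, on a cell-centered grid.

    ``mass[i, j]`` is the probability carried by the cell centered at
    ``(u1_centers[i], u2_centers[j])``; all cells have equal area in the
    transformed coordinates and the masses sum to 1.  Within a cell that
    straddles an S-bin edge the mass is distributed over the overlapped bins
    (each part normalized by its own bin), which is what makes the
    pushforward exactly flat.
    """

    surface: SSurface
    mass: np.ndarray
    density: np.ndarray        # mass / cell area
    gradient_field: np.ndarray  # |grad S| at the cell centers
    u1_centers: np.ndarray
    u2_centers: np.ndarray
    s_centers: np.ndarray      # S at the cell centers
    s_halfwidth: np.ndarray    # half of each cell's S-span
    bin_edges: np.ndarray      # n_s_bins + 1 equal-width S edges
    bin_target: np.ndarray     # mass each S bin carries (1/n, or 0 if empty)
    n_s_bins: int
    empty_bins: tuple

    @property
    def cell_area(self) -> float:
        du1 = self.u1_centers[1] - self.u1_centers[0]
        du2 = self.u2_centers[1] - self.u2_centers[0]
        return float(du1 * du2)


def _bin_fractions(s, half, edges):
    """Fraction of each cell's S-span falling in each bin; yields (b, frac)."""
    n = len(edges) - 1
    s_lo = np.clip(s - half, edges[0], edges[-1])
    s_hi = np.clip(s + half, edges[0], edges[-1])
    span = s_hi - s_lo
    degenerate = span <= 0
    # degenerate (flat) cells: hard-assign to the bin containing S
    hard = np.clip(np.digitize(s, edges[1:-1]), 0, n - 1)
    for b in range(n):
        overlap = np.minimum(s_hi, edges[b + 1]) - np.maximum(s_lo, edges[b])
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(degenerate, (hard == b).astype(float),
                            np.clip(overlap, 0.0, None) / np.where(span > 0, span, 1.0))
        yield b, frac


def flat_output_prior(surface: SSurface, n_s_bins: int = DEFAULT_N_S_BINS) -> SensitivityPrior:
    """Input prior under which all S values are equally probable.

    Cells are weighted by |grad S| x cell area and partitioned (fractionally,
    by S-span overlap) into ``n_s_bins`` equal-width S bins; every bin's
    weight is renormalized to carry total mass 1/n_s_bins.  S bins with no
    overlapping cells pass their share uniformly to the adjacent non-empty
    bins (reported via ``empty_bins``).
    """
    dense_interp = RegularGridInterpolator(
        (surface.u1_dense, surface.u2_dense), surface.dense_s, method="linear"
    )
    lo1, hi1 = surface.u1_dense[0], surface.u1_dense[-1]
    lo2, hi2 = surface.u2_dense[0], surface.u2_dense[-1]
    m1, m2 = len(surface.u1_dense) - 1, len(surface.u2_dense) - 1
    du1, du2 = (hi1 - lo1) / m1, (hi2 - lo2) / m2
    uc1 = lo1 + (np.arange(m1) + 0.5) * du1
    uc2 = lo2 + (np.arange(m2) + 0.5) * du2
    U1, U2 = np.meshgrid(uc1, uc2, indexing="ij")
    S = dense_interp(np.stack([U1.ravel(), U2.ravel()], axis=1)).reshape(m1, m2)
    S = np.clip(S, 0.0, 1.0)
    if S.max() - S.min() < 1e-12:
        raise FlatSurfaceError("S is constant; a flat-output prior is undefined")

    g1, g2 = np.gradient(S, uc1, uc2)
    grad = np.hypot(g1, g2)
    w = grad * du1 * du2
    half = (np.abs(g1) * du1 + np.abs(g2) * du2) / 2.0

    # bins span the full S-range covered by the cells' spans, so edge cells
    # are never clipped (clipping would overweight them in the outer bins)
    edges = np.linspace((S - half).min(), (S + half).max(), n_s_bins + 1)
    bin_weight = np.zeros(n_s_bins)
    fracs = []
    for b, frac in _bin_fractions(S, half, edges):
        bin_weight[b] = (w * frac).sum()
        fracs.append(frac)

    occupied = bin_weight > 1e-300
    target = np.full(n_s_bins, 1.0 / n_s_bins)
    empty = np.where(~occupied)[0]
    occ_idx = np.where(occupied)[0]
    for b in empty:
        lower = occ_idx[occ_idx < b]
        upper = occ_idx[occ_idx > b]
        neighbors = [x for x in (lower[-1] if lower.size else None,
                                 upper[0] if upper.size else None) if x is not None]
        share = target[b] / len(neighbors)
        for nb in neighbors:
            target[nb] += share
        target[b] = 0.0

    mass = np.zeros_like(w)
    for b in occ_idx:
        mass += w * fracs[b] * (target[b] / bin_weight[b])
    mass /= mass.sum()  # guard fp rounding; construction sums to 1 within 1e-12
    return SensitivityPrior(
        surface=surface,
        mass=mass,
        density=mass / (du1 * du2),
        gradient_field=grad,
        u1_centers=uc1,
        u2_centers=uc2,
        s_centers=S,
        s_halfwidth=half,
        bin_edges=edges,
        bin_target=target,
        n_s_bins=n_s_bins,
        empty_bins=tuple(int(b) for b in empty),
    )


def pushforward_histogram(prior: SensitivityPrior) -> np.ndarray:
    """Mass of S landing in each of the prior's equal-width S bins.

    Evaluated with the same fractional S-span convention used to build the
    prior, i.e. the pushforward of the constructed piecewise density itself.
    """
    w = prior.gradient_field * prior.cell_area
    bin_weight = np.zeros(prior.n_s_bins)
    fracs = []
    for b, frac in _bin_fractions(prior.s_centers, prior.s_halfwidth, prior.bin_edges):
        bin_weight[b] = (w * frac).sum()
        fracs.append(frac)
    out = np.zeros(prior.n_s_bins)
    for b in range(prior.n_s_bins):
        if bin_weight[b] > 1e-300:
            out[b] = (w * fracs[b] * (prior.bin_target[b] / bin_weight[b])).sum()
    return out / out.sum()


def sensitive_region_summary(prior: SensitivityPrior, mass: float = 0.5) -> dict:
    """Smallest (greedy, highest-density-first) cell set holding ``mass``.

    Returns the probability captured, cell count/fraction, and bounding
    boxes in both transformed and native concentration coordinates.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    flat = prior.mass.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    n_take = int(np.searchsorted(csum, mass) + 1)
    n_take = min(n_take, flat.size)
    take = order[:n_take]
    i1, i2 = np.unravel_index(take, prior.mass.shape)
    u1 = prior.u1_centers[i1]
    u2 = prior.u2_centers[i2]
    return {
        "mass_requested": mass,
        "mass_captured": float(csum[n_take - 1]),
        "n_cells": n_take,
        "cell_fraction": n_take / flat.size,
        "u1_range": (float(u1.min()), float(u1.max())),
        "u2_range": (float(u2.min()), float(u2.max())),
        "c8_range": (axis_untransform(float(u1.min())), axis_untransform(float(u1.max()))),
        "oc6_range": (axis_untransform(float(u2.min())), axis_untransform(float(u2.max()))),
    }
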