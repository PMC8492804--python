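"""Equal-occupancy histograms and their square-root embedding on the sphere.

All single-cell fluorescence values for one reporter (all input conditions
pooled) define 20 bins of equal occupancy.  Each condition's histogram is a
probability vector p over those bins; the square-root map q_i = sqrt(p_i)
places every histogram on the unit sphere in bin space, where the Euclidean
distance between two points is the chord distance between histograms and the
great-circle distance is the information-geometric (Fisher/Hellinger-type)
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateDataError, EmptyInputError

DEFAULT_N_BINS = 20


@dataclass(frozen=True)
class BinningScheme:
    """Bin edges shared by all conditions of one reporter.

    ``edges`` has ``n_bins + 1`` strictly increasing entries; the outer edges
    are -inf/+inf so a frozen scheme can histogram any later value.  Interior
    edges sit at the k/n_bins empirical quantiles of the reference aggregate.
    Bins are half-open [lo, hi): a value equal to an edge falls in the upper
    bin.
    """

    edges: np.ndarray
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        if edges.shape != (self.n_bins + 1,):
            raise ValueError(f"expected {self.n_bins + 1} edges, got {edges.shape}")
        if np.any(np.diff(edges) <= 0):
            raise DegenerateDataError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)


@dataclass(frozen=True)
class HistogramPoint:
    """One condition's histogram and its unit-sphere embedding."""

    condition_id: str
    p: np.ndarray
    q: np.ndarray
    n_cells: int

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        if abs((q**2).sum() - 1.0) > 1e-12:
            raise ValueError("q is not on the unit sphere")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)

    @property
    def n_bins(self) -> int:
        return self.p.size


def equal_occupancy_edges(values, n_bins: int = DEFAULT_N_BINS) -> BinningScheme:
    """Find bin edges equally populated by the aggregated reference values."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyInputError("no finite values to bin")
    if np.unique(values).size < n_bins:
        raise DegenerateDataError(
            f"only {np.unique(values).size} distinct values for {n_bins} bins"
        )
    probs = np.arange(1, n_bins) / n_bins
    interior = np.quantile(values, probs, method="linear")
    if np.any(np.diff(interior) <= 0):
        raise DegenerateDataError("tied quantiles collapse adjacent bins")
    edges = np.concatenate(([-np.inf], interior, [np.inf]))
    return BinningScheme(edges=edges, n_bins=n_bins)


def histogram_point(values, scheme: BinningScheme, condition_id: str = "") -> HistogramPoint:
    """Histogram one condition's values with a frozen scheme and embed."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyInputError("cannot histogram an empty value collection")
    # ties at an edge go right: side='right' assigns v == edge to the upper bin
    idx = np.searchsorted(scheme.edges[1:-1], values, side="right")
    counts = np.bincount(idx, minlength=scheme.n_bins).astype(float)
    p = counts / counts.sum()
    return HistogramPoint(condition_id=condition_id, p=p, q=np.sqrt(p), n_cells=values.size)


def _check_pair(a: HistogramPoint, b: HistogramPoint) -> None:
    if a.n_bins != b.n_bins:
        raise ValueError(f"bin-count mismatch: {a.n_bins} vs {b.n_bins}")


def chord_distance(a: HistogramPoint, b: HistogramPoint) -> float:
    """Euclidean distance between the embedded points; range [0, sqrt(2)]."""
    _check_pair(a, b)
    return float(np.linalg.norm(a.q - b.q))


def arc_distance(a: HistogramPoint, b: HistogramPoint) -> float:
    """Great-circle (information-geometric) distance; range [0, pi/2]."""
    _check_pair(a, b)
    dot = np.clip(np.dot(a.q, b.q), -1.0, 1.0)
    return float(np.arccos(dot))


def points_to_matrix(points: Sequence[HistogramPoint]) -> np.ndarray:
    """Stack embedded q vectors into an (n_conditions, n_bins) matrix."""
    points = list(points)
    if not points:
        raise EmptyInputError("no histogram points")
    n_bins = points[0].n_bins
    if any(p.n_bins != n_bins for p in points):
        raise ValueError("all points must share one binning scheme")
    return np.vstack([p.q for p in points])


def build_histograms(cells, scheme: BinningScheme, value_column: str = "green"):
    """Histogram every condition in a cell table; returns list of points.

    Conditions appear in first-occurrence order of ``condition_id``.
    """
    points = []
    for cid, grp in cells.groupby("condition_id", sort=False):
        points.append(histogram_point(grp[value_column].to_numpy(), scheme, condition_id=cid))
    return points
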