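"""Linear PCA of the embedded histograms.

Each condition contributes one unit-sphere point q; PCA of the mean-centered
q vectors gives scores (the condition dependence of each component), loadings
(the constituent histogram shapes) and explained-variance fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .embed import HistogramPoint, points_to_matrix
from .errors import ZeroVarianceError


@dataclass(frozen=True)
class PcaModel:
    mean_q: np.ndarray          # (n_bins,)
    loadings: np.ndarray        # (n_components, n_bins), orthonormal rows
    ev_fraction: np.ndarray     # (n_components,), non-increasing, sums to 1
    scores: np.ndarray          # (n_conditions, n_components)
    condition_ids: tuple

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def _fix_signs(loadings: np.ndarray, scores: np.ndarray):
    """Deterministic sign convention: each loading's largest-|entry| is positive."""
    for k in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    return loadings, scores


def fit_pca(points: Sequence[HistogramPoint]) -> PcaModel:
    """PCA (centered, unscaled) of the q vectors via SVD."""
    Q = points_to_matrix(points)
    if Q.shape[0] < 2:
        raise ZeroVarianceError("need at least 2 points")
    mean_q = Q.mean(axis=0)
    X = Q - mean_q
    total = float((X**2).sum())
    if total < 1e-24:
        raise ZeroVarianceError("all histogram points are identical")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    ev = s**2
    loadings, scores = _fix_signs(Vt.copy(), U * s)
    return PcaModel(
        mean_q=mean_q,
        loadings=loadings,
        ev_fraction=ev / ev.sum(),
        scores=scores,
        condition_ids=tuple(p.condition_id for p in points),
    )


def project(model: PcaModel, point: HistogramPoint, k: int) -> np.ndarray:
    """Coordinates of a (centered) point on the first k loadings."""
    if not 1 <= k <= model.n_components:
        raise ValueError(f"k={k} out of range 1..{model.n_components}")
    return (point.q - model.mean_q) @ model.loadings[:k].T


def reconstruct(model: PcaModel, point: HistogramPoint, k: int) -> np.ndarray:
    """Rank-k reconstruction of a point's q vector."""
    return model.mean_q + project(model, point, k) @ model.loadings[:k]
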