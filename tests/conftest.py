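"""Shared fixtures.

Expensive objects (generated datasets, fitted NLPCA models) are
session-scoped so the whole suite pays for each fit once.
"""

import numpy as np
import pytest

from quorumdim.embed import build_histograms, equal_occupancy_edges
from quorumdim.nlpca import fit_nlpca
from quorumdim.pca import fit_pca
from quorumdim.preprocess import (
    apply_area_correction,
    exclude_aberrant,
    fit_area_correction,
)
from quorumdim.synthetic import default_study_config, generate


@pytest.fixture(scope="session")
def qrr_dataset():
    """Paper-scale qrr-like synthetic dataset: (config, cells, truth)."""
    cfg = default_study_config("qrr", seed=1)
    cells, truth = generate(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def qrr_points(qrr_dataset):
    """Preprocessed, embedded histogram points for the qrr-like dataset."""
    _, cells, _ = qrr_dataset
    cells, _ = exclude_aberrant(cells)
    correction = fit_area_correction(cells)
    cells = apply_area_correction(cells, correction)
    scheme = equal_occupancy_edges(cells["green"].to_numpy())
    return build_histograms(cells, scheme)


@pytest.fixture(scope="session")
def qrr_pca(qrr_points):
    return fit_pca(qrr_points)


@pytest.fixture(scope="session")
def nlpca1(qrr_points):
    """1-component hierarchical model on the qrr-like points."""
    return fit_nlpca(qrr_points, 1, restarts=6, seed=11)


@pytest.fixture(scope="session")
def nlpca2(qrr_points):
    """2-component hierarchical model on the same points."""
    return fit_nlpca(qrr_points, 2, restarts=6, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_histogram_points(rng, n_points, n_bins=20, concentration=1.0):
    """Dirichlet-random histogram points, for distance/PCA property tests."""
    from quorumdim.embed import HistogramPoint

    P = rng.dirichlet(np.full(n_bins, concentration), size=n_points)
    return [
        HistogramPoint(condition_id=f"r{i}", p=p / p.sum(), q=np.sqrt(p / p.sum()),
                       n_cells=400)
        for i, p in enumerate(P)
    ]
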