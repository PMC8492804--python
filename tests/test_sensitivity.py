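import numpy as np
import pytest

from quorumdim.errors import FlatSurfaceError
from quorumdim.io import ConditionGrid
from quorumdim.scoord import SSurface, build_s_surface, axis_transform
from quorumdim.sensitivity import (
    flat_output_prior,
    gradient_magnitude,
    pushforward_histogram,
    sensitive_region_summary,
)


def analytic_surface(f, refine=200, n_nodes=9):
    """SSurface for S = f(u1, u2) on the unit square in transformed coords."""
    levels = tuple(np.linspace(0, 10, n_nodes))
    grid = ConditionGrid(c8_levels=levels, oc6_levels=levels)
    u = np.linspace(0, 1, refine)
    U1, U2 = np.meshgrid(u, u, indexing="ij")
    un = np.linspace(0, 1, n_nodes)
    N1, N2 = np.meshgrid(un, un, indexing="ij")
    return SSurface(
        grid=grid,
        node_s=f(N1, N2),
        u1_nodes=un,
        u2_nodes=un,
        u1_dense=u,
        u2_dense=u,
        dense_s=f(U1, U2),
    )


class TestGradientMagnitude:
    def test_linear_field(self):
        surf = analytic_surface(lambda u1, u2: u1)
        assert np.allclose(gradient_magnitude(surf), 1.0, atol=1e-12)

    def test_constant_field(self):
        surf = analytic_surface(lambda u1, u2: np.full_like(u1, 0.4))
        assert np.allclose(gradient_magnitude(surf), 0.0)

    def test_quadratic_bowl_matches_analytic(self):
        refine = 200
        surf = analytic_surface(lambda u1, u2: (u1**2 + u2**2) / 2, refine=refine)
        U1, U2 = np.meshgrid(surf.u1_dense, surf.u2_dense, indexing="ij")
        exact = np.hypot(U1, U2)
        h = 1 / (refine - 1)
        assert np.abs(gradient_magnitude(surf) - exact).max() < 2 * h


class TestFlatOutputPrior:
    def test_pushforward_is_uniform(self):
        surf = analytic_surface(lambda u1, u2: (np.sin(3 * u1) + u2**2) / 3)
        prior = flat_output_prior(surf, n_s_bins=20)
        push = pushforward_histogram(prior)
        assert np.abs(push - 1 / 20).max() < 1e-6
        assert prior.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(prior.mass >= 0)

    def test_linear_surface_gives_uniform_prior(self):
        refine = 200
        surf = analytic_surface(lambda u1, u2: u1, refine=refine)
        prior = flat_output_prior(surf, n_s_bins=20)
        dev = np.abs(prior.density - 1.0)
        assert dev.max() < 1 / refine + 1e-9

    def test_quadratic_1d_matches_change_of_variables(self):
        # S = u1^2 with uniform S forces the input marginal 2*u1
        refine = 400
        surf = analytic_surface(lambda u1, u2: u1**2, refine=refine)
        prior = flat_output_prior(surf, n_s_bins=20)
        du = prior.u1_centers[1] - prior.u1_centers[0]
        marginal = prior.mass.sum(axis=1) / du
        exact = 2 * prior.u1_centers
        assert np.abs(marginal - exact).max() < 2 / refine

    def test_constant_surface_raises(self):
        surf = analytic_surface(lambda u1, u2: np.full_like(u1, 0.5))
        with pytest.raises(FlatSurfaceError):
            flat_output_prior(surf)

    def test_invariant_under_affine_transform(self):
        # affine reparameterization of the output rescales the bins with it,
        # so the prior is unchanged cell by cell
        f = lambda u1, u2: (u1 + u2) / 2
        a = flat_output_prior(analytic_surface(f, refine=150), n_s_bins=20)
        b = flat_output_prior(
            analytic_surface(lambda u1, u2: 0.2 + 0.6 * f(u1, u2), refine=150),
            n_s_bins=20,
        )
        assert np.abs(a.mass - b.mass).max() < 1e-12

    def test_nonlinear_transform_reweights_by_jacobian(self):
        # flattening g(S) instead of S multiplies the prior by g'(S) (up to
        # normalization); with g = s^2 and a prior under which S is uniform,
        # the cellwise L1 distance converges to INT |1 - 2s| ds = 1/2
        f = lambda u1, u2: (u1 + u2) / 2
        a = flat_output_prior(analytic_surface(f, refine=150), n_s_bins=20)
        b = flat_output_prior(
            analytic_surface(lambda u1, u2: f(u1, u2) ** 2, refine=150), n_s_bins=20
        )
        l1 = np.abs(a.mass - b.mass).sum()
        assert l1 == pytest.approx(0.5, abs=0.01)

    def test_qrr_surface_prior_uniformity(self, qrr_dataset, qrr_points, nlpca1):
        from quorumdim.scoord import build_s_map

        cfg, _, _ = qrr_dataset
        smap = build_s_map(nlpca1, qrr_points,
                           zero_condition_id=cfg.grid.condition_id(0, 0))
        surf = build_s_surface(smap, cfg.grid, refine=200)
        prior = flat_output_prior(surf, n_s_bins=20)
        push = pushforward_histogram(prior)
        assert np.abs(push - 1 / 20).max() < 1e-6


class TestSensitiveRegion:
    def test_uniform_prior_takes_half_the_cells(self):
        surf = analytic_surface(lambda u1, u2: u1, refine=100)
        prior = flat_output_prior(surf, n_s_bins=10)
        region = sensitive_region_summary(prior, mass=0.5)
        assert region["cell_fraction"] == pytest.approx(0.5, abs=0.05)
        assert region["mass_captured"] >= 0.5

    def test_concentrated_prior_takes_one_cell(self):
        surf = analytic_surface(lambda u1, u2: u1, refine=50)
        prior = flat_output_prior(surf, n_s_bins=10)
        mass = np.zeros_like(prior.mass)
        mass[7, 9] = 1.0
        from dataclasses import replace

        point = replace(prior, mass=mass, density=mass / prior.cell_area)
        for m in (0.1, 0.5, 0.9):
            assert sensitive_region_summary(point, mass=m)["n_cells"] == 1

    def test_steep_zone_localized_at_low_concentrations(self):
        # sigmoidal drop near the low-concentration corner: the top-density
        # region must stay inside the low-c8, low-oc6 quadrant
        f = lambda u1, u2: 1 / (1 + np.exp((u1 + 0.5 * u2 - 0.25) / 0.06))
        surf = analytic_surface(f, refine=150)
        prior = flat_output_prior(surf, n_s_bins=20)
        region = sensitive_region_summary(prior, mass=0.8)
        # steep line u1 + 0.5*u2 = 0.25 (width ~0.06): the 80%-mass box stays
        # in the lower-left half of each axis (native units are 10*u here)
        assert region["c8_range"][1] < 6.0
        assert region["oc6_range"][1] < 8.0
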