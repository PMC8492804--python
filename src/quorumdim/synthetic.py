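"""Synthetic single-cell datasets with the structure the analysis assumes.

Each condition on a two-autoinducer grid gets a latent activation t in
[0, 1) computed from two Hill terms plus an interaction (crosstalk) term.
The per-cell green fluorescence is gamma-distributed with shape and scale
that vary linearly in t, so mean, variance and skewness all move together
along a single one-dimensional family — the property the nonlinear
dimension-reduction is designed to recover.  Cell areas are lognormal and a
small area-proportional leak is added to the green channel, so the
area-correction step has something real to remove.  Ground-truth t per
condition is returned for recovery tests.

The generator emulates the 1-D manifold structure, sample sizes and grids of
the measured datasets; it does not claim to reproduce the real histogram
shapes (which are poorly fit by standard families).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import ConditionGrid

QRR_GRID = ConditionGrid(
    c8_levels=(0, 7, 20, 50, 100, 200, 1000),
    oc6_levels=(0, 7, 15, 20, 50, 100, 500),
    c8_unit="pM",
    oc6_unit="nM",
)

LUX_GRID = ConditionGrid(
    c8_levels=(0, 10, 20, 50, 100, 200, 500),
    oc6_levels=(0, 10, 20, 30, 50, 100, 200, 500),
    c8_unit="nM",
    oc6_unit="nM",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults come from the study-condition presets.

    Latent:   t(c1, c2) = clamp01(w1*h1 + w2*h2 + w12*h1*h2),
              h_i = c_i^n_i / (K_i^n_i + c_i^n_i).
    Emission: green ~ Gamma(shape=a0 + a1*t, scale=th0 + th1*t) + lam*area,
              area ~ Lognormal(mu_area, sigma_area).
    """

    grid: ConditionGrid
    n_cells: int = 400
    # latent response
    k1: float = 40.0
    n1: float = 1.2
    k2: float = 30.0
    n2: float = 1.2
    w1: float = 0.5
    w2: float = 0.3
    w12: float = 0.2
    # gamma emission, linear in t
    alpha0: float = 9.0
    alpha1: float = -6.0
    theta0: float = 30.0
    theta1: float = -18.0
    # area model and leak into the green channel
    mu_area: float = np.log(40.0)
    sigma_area: float = 0.3
    leak: float = 0.3
    # optional second gamma component (non-gamma shapes for robustness tests)
    mixture_fraction: float = 0.0
    mixture_shape_factor: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 50:
            raise ValueError("n_cells must be >= 50")
        for t in (0.0, 1.0):
            if self.alpha0 + self.alpha1 * t <= 0:
                raise ValueError(f"gamma shape must stay positive (t={t})")
            if self.theta0 + self.theta1 * t <= 0:
                raise ValueError(f"gamma scale must stay positive (t={t})")
        if not 0 <= self.mixture_fraction < 1:
            raise ValueError("mixture_fraction must be in [0, 1)")

    def latent(self, c8: float, oc6: float) -> float:
        h1 = c8**self.n1 / (self.k1**self.n1 + c8**self.n1) if c8 > 0 else 0.0
        h2 = oc6**self.n2 / (self.k2**self.n2 + oc6**self.n2) if oc6 > 0 else 0.0
        t = self.w1 * h1 + self.w2 * h2 + self.w12 * h1 * h2
        return float(np.clip(t, 0.0, 1.0))


class SyntheticResult(NamedTuple):
    cells: pd.DataFrame
    truth: pd.DataFrame  # condition_id, c8, oc6, t_true


def default_study_config(reporter: str, seed: int = 0) -> SyntheticConfig:
    """Preset emulating one reporter's study conditions.

    qrr: activity is high with no autoinducer and shuts off as the latent
    rises (shape 9 -> 3, scale 30 -> 12, right-skewed throughout).
    lux: activity rises with the latent (shape 2.5 -> 6.5, scale 15 -> 40).
    """
    if reporter == "qrr":
        return SyntheticConfig(grid=QRR_GRID, seed=seed)
    if reporter == "lux":
        return SyntheticConfig(
            grid=LUX_GRID,
            k1=60.0,
            n1=1.3,
            k2=40.0,
            n2=1.2,
            alpha0=2.5,
            alpha1=4.0,
            theta0=15.0,
            theta1=25.0,
            seed=seed,
        )
    raise ValueError(f"reporter must be 'qrr' or 'lux', got {reporter!r}")


def null_config(reporter: str = "qrr", seed: int = 0) -> SyntheticConfig:
    """No condition dependence: every condition shares one distribution."""
    base = default_study_config(reporter, seed=seed)
    return replace(base, alpha1=0.0, theta1=0.0, leak=0.0)


def generate(config: SyntheticConfig) -> SyntheticResult:
    """Draw the full dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    rows = []
    truth_rows = []
    for cid, c8, oc6 in config.grid.iter_conditions():
        t = config.latent(c8, oc6)
        truth_rows.append({"condition_id": cid, "c8": c8, "oc6": oc6, "t_true": t})
        n = config.n_cells
        area = rng.lognormal(config.mu_area, config.sigma_area, size=n)
        shape = config.alpha0 + config.alpha1 * t
        scale = config.theta0 + config.theta1 * t
        expr = rng.gamma(shape, scale, size=n)
        if config.mixture_fraction > 0:
            second = rng.gamma(shape * config.mixture_shape_factor, scale, size=n)
            pick = rng.random(n) < config.mixture_fraction
            expr = np.where(pick, second, expr)
        green = expr + config.leak * area
        red = rng.gamma(5.0, 20.0, size=n) + 0.5 * area
        rows.append(
            pd.DataFrame(
                {
                    "condition_id": cid,
                    "c8": c8,
                    "oc6": oc6,
                    "green": green,
                    "red": red,
                    "area": area,
                }
            )
        )
    cells = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return SyntheticResult(cells, truth)
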