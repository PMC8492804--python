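"""Data cleaning: aberrant-cell exclusion and area-proportional correction.

Two steps precede histogramming.  First, within each input condition, cells
whose green fluorescence is extremely aberrant are removed using a robust
z-score (median / MAD) rule; with the default threshold this excludes well
under 1% of cells on realistic data.  Second, a small component proportional
to cell area is subtracted from the green channel.  At conditions where
reporter expression is very weak, green fluorescence correlates with cell
size rather than with reporter output; the area slope is therefore fit by
ordinary least squares pooled over the lowest-expressing conditions and then
subtracted everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

# consistency factor making MAD estimate sigma for a normal sample
_MAD_SCALE = 1.4826

DEFAULT_Z_MAX = 6.0
DEFAULT_LOW_EXPRESSION_QUANTILE = 0.2
MIN_REFERENCE_CELLS = 50


@dataclass(frozen=True)
class AreaCorrection:
    """Fitted area-proportional green-fluorescence correction."""

    slope: float  # fluorescence units per pixel of area
    intercept: float
    reference_conditions: tuple

    def __post_init__(self):
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if len(self.reference_conditions) == 0:
            raise ValueError("reference_conditions must be non-empty")


class ExclusionResult(NamedTuple):
    kept: pd.DataFrame
    excluded_fraction: float


def exclude_aberrant(cells: pd.DataFrame, z_max: float = DEFAULT_Z_MAX) -> ExclusionResult:
    """Remove per-condition outliers in green fluorescence.

    Within each condition the robust z-score ``|x - median| / (1.4826 * MAD)``
    is computed; cells with z > ``z_max`` are dropped.  If the MAD is zero
    while some values still differ from the median, the rule falls back to an
    interquartile-range criterion (|x - median| > z_max/1.349 * IQR).  A
    condition whose values are all identical loses no cells.
    """
    if z_max <= 0:
        raise ValueError("z_max must be positive")
    keep_mask = np.ones(len(cells), dtype=bool)
    green = cells["green"].to_numpy(dtype=float)
    for _, idx in cells.groupby("condition_id", sort=False).indices.items():
        x = green[idx]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad > 0:
            z = np.abs(x - med) / (_MAD_SCALE * mad)
            keep_mask[idx] = z <= z_max
        else:
            iqr = stats.iqr(x)
            if iqr > 0:
                # 1.349 IQRs ~ 2 sigma for a normal sample
                keep_mask[idx] = np.abs(x - med) <= z_max * iqr / 1.349
            # all-identical condition: nothing is aberrant
    kept = cells.loc[keep_mask].reset_index(drop=True)
    frac = 1.0 - len(kept) / len(cells) if len(cells) else 0.0
    return ExclusionResult(kept, float(frac))


def fit_area_correction(
    cells: pd.DataFrame,
    low_expression_quantile: float = DEFAULT_LOW_EXPRESSION_QUANTILE,
) -> AreaCorrection:
    """Fit the green-vs-area slope on the lowest-expressing conditions.

    Conditions whose mean green fluorescence lies at or below the
    ``low_expression_quantile`` of all condition means form the reference
    set; the slope is the pooled OLS slope of green on area over those cells.
    """
    if not 0 < low_expression_quantile < 1:
        raise ValueError("low_expression_quantile must be in (0, 1)")
    means = cells.groupby("condition_id")["green"].mean()
    if len(means) < 2:
        raise InsufficientDataError("need at least 2 conditions to pick a reference set")
    cutoff = means.quantile(low_expression_quantile)
    ref = tuple(means.index[means <= cutoff])
    if len(ref) < 2:
        raise InsufficientDataError(
            f"quantile {low_expression_quantile} selects {len(ref)} condition(s); need >= 2"
        )
    pooled = cells[cells["condition_id"].isin(ref)]
    if len(pooled) < MIN_REFERENCE_CELLS:
        raise InsufficientDataError(
            f"only {len(pooled)} pooled reference cells (< {MIN_REFERENCE_CELLS})"
        )
    res = stats.linregress(pooled["area"].to_numpy(), pooled["green"].to_numpy())
    return AreaCorrection(
        slope=float(res.slope), intercept=float(res.intercept), reference_conditions=ref
    )


def apply_area_correction(cells: pd.DataFrame, correction: AreaCorrection) -> pd.DataFrame:
    """Subtract ``slope * area`` from green fluorescence.

    The transformation is linear and exactly invertible: applying the same
    correction with the negated slope restores the input.  Corrected values
    may be negative; the equal-occupancy binning downstream handles that.
    """
    out = cells.copy()
    out["green"] = out["green"] - correction.slope * out["area"]
    return out
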