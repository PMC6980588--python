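"""Depth regression of dissolved inorganic carbon Δ¹⁴C.

Seawater DIC is the dominant carbon source for otolith aragonite, so the
depth profile of DIC Δ¹⁴C maps otolith-core values onto habitat depth.
Below the well-mixed surface layer, Δ¹⁴C declines roughly linearly with
depth; an OLS fit within the outer-shelf/upper-slope window (200–600 m by
default) gives the decline rate used to interpret core values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm


@dataclass(frozen=True)
class DepthRegressionReport:
    """OLS of Δ¹⁴C on depth over the selected window (inclusive bounds)."""

    slope: float  # ‰ per m
    intercept: float  # ‰
    r_squared: float
    p_value: float  # two-sided t test on the slope
    n: int
    slope_se: float
    window: tuple


def fit_depth_regression(profile, window=(200.0, 600.0)) -> DepthRegressionReport:
    """Fit Δ¹⁴C ~ depth by OLS using only points inside the closed window.

    ``profile`` is a DICProfile or any object with ``depth`` and ``d14c``
    array attributes. Points outside the window never influence the fit.
    """
    depth = np.asarray(profile.depth, dtype=float)
    d14c = np.asarray(profile.d14c, dtype=float)
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    mask = (depth >= lo) & (depth <= hi)
    if mask.sum() < 3:
        raise ValueError(f"only {int(mask.sum())} points inside [{lo}, {hi}] m; need >= 3")
    x = depth[mask]
    y = d14c[mask]
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return DepthRegressionReport(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(mask.sum()),
        slope_se=float(model.bse[1]),
        window=(lo, hi),
    )


def slope_per_100m(slope: float) -> float:
    """Convert a ‰-per-metre slope to ‰ per 100 m of depth."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    return slope * 100.0
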