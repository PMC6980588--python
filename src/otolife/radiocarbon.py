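"""Bomb-radiocarbon validation of otolith age estimates.

An otolith core records the Δ¹⁴C of the water the fish inhabited during its
first months of life. Plotting core Δ¹⁴C at the estimated birth year
(collection year minus opaque-zone count) against a dated coral/known-age
otolith reference curve turns the bomb pulse into a chronometer: ages that
are systematically wrong displace the cores off the curve, most visibly on
the steep 1960s rise.

Three analyses are provided: birth-year bookkeeping with consistency flags,
a residual test of the cores against the loess-fitted reference curve
(normality and variance-homogeneity pre-checks plus a one-sample mean-zero
test), and a sum-of-squared-residuals profile across purposeful age shifts
of ±1–3 years, whose minimum at shift 0 indicates unbiased ageing.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .loess import ExtrapolationError, LoessFit


@dataclass(frozen=True)
class RadiocarbonSample:
    """One otolith-core Δ¹⁴C measurement with its ageing metadata."""

    sample_id: str
    collection_date: object  # datetime.date, ISO string, or MM/DD/YYYY string
    tl_mm: float
    age_years: int
    d14c: float
    d14c_sd: float
    otolith_mass_mg: float | None = None
    d13c: float | None = None

    def __post_init__(self) -> None:
        if self.age_years < 1:
            raise ValueError("age_years must be >= 1")
        if self.d14c_sd <= 0:
            raise ValueError("d14c_sd must be > 0")

    @property
    def birth_year(self) -> int:
        return birth_year(self.collection_date, self.age_years)


def _year_of(date) -> int:
    if isinstance(date, (_dt.date, _dt.datetime)):
        return date.year
    if isinstance(date, (int, np.integer)):
        return int(date)
    if isinstance(date, float) and float(date).is_integer():
        return int(date)
    s = str(date).strip()
    for fmt in ("%Y-%m-%d", "%m/%d/%Y", "%Y"):
        try:
            return _dt.datetime.strptime(s, fmt).year
        except ValueError:
            continue
    raise ValueError(f"unparseable date {date!r}")


def birth_year(collection_date, age_years: int) -> int:
    """Year of formation = calendar year of collection − estimated age.

    Months are ignored: the published bookkeeping uses calendar years only.
    """
    if age_years < 0:
        raise ValueError("age_years must be >= 0")
    return _year_of(collection_date) - int(age_years)


def check_birth_years(samples, printed_years) -> list:
    """Recompute birth years and flag rows whose printed year disagrees.

    ``samples`` is an iterable of RadiocarbonSample and ``printed_years`` the
    corresponding published years of formation. Inconsistent rows are flagged,
    never corrected: with a date/age/year conflict there is no way to know
    which field is the typo.

    Returns a list of dicts (sample_id, computed_year, printed_year,
    consistent).
    """
    out = []
    for s, printed in zip(samples, printed_years):
        computed = s.birth_year
        out.append(
            {
                "sample_id": s.sample_id,
                "computed_year": computed,
                "printed_year": int(printed),
                "consistent": computed == int(printed),
            }
        )
    return out


@dataclass
class ResidualTestReport:
    """Outcome of comparing core Δ¹⁴C values against the reference curve."""

    n_comparable: int
    excluded_ids: list
    residuals: np.ndarray
    shapiro_p: float
    levene_p: float
    mean_zero_p: float
    consistent: bool  # mean-zero test not rejected at alpha
    alpha: float = 0.05


def _comparable_mask(fit: LoessFit, years: np.ndarray) -> np.ndarray:
    lo, hi = fit.x_range
    return (years >= lo) & (years <= hi)


def residual_test(fit: LoessFit, samples, alpha: float = 0.05) -> ResidualTestReport:
    """Test whether core Δ¹⁴C values are consistent with the reference curve.

    Residuals are observed Δ¹⁴C minus the loess prediction at each sample's
    birth year. Samples whose birth year falls outside the fitted range
    (e.g. pre-bomb birth years before the reference record starts) are
    excluded and reported, mirroring how a 1958 birth year just before the
    rise cannot be validated. Pre-checks are Shapiro–Wilk normality and a
    Levene test of variance homogeneity between early and late birth years
    (split at the median year); the consistency call is a one-sample t test
    of mean-zero residuals at the given alpha.
    """
    samples = list(samples)
    years = np.array([s.birth_year for s in samples], dtype=float)
    mask = _comparable_mask(fit, years)
    excluded = [s.sample_id for s, ok in zip(samples, mask) if not ok]
    if mask.sum() < 3:
        raise ValueError(f"only {int(mask.sum())} samples inside the reference range; need >= 3")
    obs = np.array([s.d14c for s in samples], dtype=float)[mask]
    yrs = years[mask]
    resid = obs - fit.predict(yrs)
    degenerate = float(np.std(resid)) == 0.0  # e.g. exactly on-curve samples
    shapiro_p = 1.0 if degenerate else float(stats.shapiro(resid).pvalue)
    early = resid[yrs <= np.median(yrs)]
    late = resid[yrs > np.median(yrs)]
    if degenerate or early.size < 2 or late.size < 2:
        levene_p = float("nan")
    else:
        levene_p = float(stats.levene(early, late).pvalue)
    if degenerate:
        mean_zero_p = 1.0 if abs(float(np.mean(resid))) < 1e-9 else 0.0
    else:
        mean_zero_p = float(stats.ttest_1samp(resid, 0.0).pvalue)
    return ResidualTestReport(
        n_comparable=int(mask.sum()),
        excluded_ids=excluded,
        residuals=resid,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        mean_zero_p=mean_zero_p,
        consistent=mean_zero_p >= alpha,
        alpha=alpha,
    )


@dataclass
class ShiftProfile:
    """SSR by purposeful age shift, for one residual definition."""

    mode: str  # "d14c" or "birth_year"
    ssr: dict  # shift (years, applied to ages) -> SSR
    n_samples: int
    flagged_ids: list  # samples needing clipping or inverse-prediction flags

    @property
    def min_shift(self) -> int:
        return min(self.ssr, key=self.ssr.get)


def _invert_rise(fit: LoessFit, d14c_values, grid_step: float = 0.05):
    """Inverse-predict birth years from Δ¹⁴C on the monotone rise segment.

    Values below the pre-rise plateau are assigned the rise-start year and
    flagged; values above the peak are assigned the peak year and flagged.
    Returns (years, flagged boolean array).
    """
    lo, hi = fit.x_range
    grid = np.arange(lo, hi + grid_step, grid_step)
    vals = fit.predict(grid)
    peak_idx = int(np.argmax(vals))
    pre = vals[: peak_idx + 1]
    # strictly increasing envelope of the pre-peak segment
    mono = np.maximum.accumulate(pre)
    keep = np.concatenate([[True], np.diff(mono) > 1e-9])
    vx = mono[keep]
    gy = grid[: peak_idx + 1][keep]
    targets = np.asarray(d14c_values, dtype=float)
    flagged = (targets < vx[0]) | (targets > vx[-1])
    years = np.interp(targets, vx, gy)
    return years, flagged


def ssr_bias_profile(
    fit: LoessFit,
    samples,
    shifts=range(-3, 4),
    mode: str = "d14c",
) -> ShiftProfile:
    """SSR across purposeful age shifts.

    Shifts are AGE shifts: a shift of +s makes every fish s years older, so
    its birth year moves s years earlier (birth_year − s). Shifted birth
    years falling outside the reference range are clipped to the range and
    the sample flagged.

    mode "d14c" (primary): SSR(s) = Σ_i (d14c_i − fit(birth_year_i − s))²,
    residuals on the Δ¹⁴C axis as in the standard bias-plot method.
    mode "birth_year": SSR(s) = Σ_i (inverse_fit(d14c_i) − (birth_year_i − s))²,
    residuals on the year axis via inverse prediction on the monotone rise.
    """
    if mode not in ("d14c", "birth_year"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = list(samples)
    years = np.array([s.birth_year for s in samples], dtype=float)
    obs = np.array([s.d14c for s in samples], dtype=float)
    lo, hi = fit.x_range
    ssr: dict = {}
    flagged: set = set()
    if mode == "birth_year":
        pred_years, inv_flags = _invert_rise(fit, obs)
        flagged.update(s.sample_id for s, f in zip(samples, inv_flags) if f)
    for s_shift in shifts:
        shifted = years - s_shift
        clip_mask = (shifted < lo) | (shifted > hi)
        flagged.update(s.sample_id for s, f in zip(samples, clip_mask) if f)
        shifted = np.clip(shifted, lo, hi)
        if mode == "d14c":
            resid = obs - fit.predict(shifted)
        else:
            resid = pred_years - shifted
        ssr[int(s_shift)] = float(resid @ resid)
    return ShiftProfile(mode=mode, ssr=ssr, n_samples=len(samples), flagged_ids=sorted(flagged))


def ssr_bias_profiles(fit: LoessFit, samples, shifts=range(-3, 4)) -> dict:
    """Both SSR definitions, keyed by mode."""
    return {
        mode: ssr_bias_profile(fit, samples, shifts=shifts, mode=mode)
        for mode in ("d14c", "birth_year")
    }


__all__ = [
    "RadiocarbonSample",
    "ResidualTestReport",
    "ShiftProfile",
    "birth_year",
    "check_birth_years",
    "residual_test",
    "ssr_bias_profile",
    "ssr_bias_profiles",
    "ExtrapolationError",
]
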