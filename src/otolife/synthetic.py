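"""Synthetic inputs with the statistical structure the analyses assume.

Four generators cover the data the pipeline consumes:

* a bomb-pulse marine Δ¹⁴C reference series (flat pre-bomb plateau, monotone
  rise through the 1960s to a mid-1970s peak, monotone post-peak decline),
  anchored to published Gulf of Mexico coral / known-age otolith values;
* a fished-population length-age sample drawn from the stable catch
  composition of the growth/selectivity/mortality model;
* paired integer age reads with reader error, for precision statistics;
* a dissolved-inorganic-carbon Δ¹⁴C depth profile: a well-mixed surface layer
  above a linear decline with depth.

Every generator takes an explicit integer seed and never touches global
random state; identical configs and seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .growth import GrowthParams, GridSpec, simulate_catch


@dataclass(frozen=True)
class BombCurveConfig:
    """Shape of the synthetic bomb-pulse Δ¹⁴C reference curve.

    Default anchors follow the regional series: a pre-bomb plateau near
    −55 ‰ (cored-otolith values of −60.7 ‰ were measured for 1958 birth
    years), a rise starting 1959, a peak near +140 ‰ in the mid-1970s
    (+139.05 ‰ measured at 1975), and a decline to ~+45 ‰ by 2015
    (+52.73 ‰ measured at 2008).
    """

    prebomb_level: float = -55.0  # ‰
    rise_start_year: float = 1959.0
    peak_year: float = 1974.0
    peak_level: float = 140.0  # ‰
    end_year: float = 2015.0
    end_level: float = 45.0  # ‰
    noise_sd: float = 6.0  # ‰
    n_points: int = 120
    seed: int = 0
    start_year: float | None = None  # first sampled year; default rise_start - 10

    def __post_init__(self) -> None:
        if not (self.rise_start_year < self.peak_year < self.end_year):
            raise ValueError("need rise_start_year < peak_year < end_year")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")

    @property
    def first_year(self) -> float:
        return self.start_year if self.start_year is not None else self.rise_start_year - 10.0


@dataclass
class ReferenceSeries:
    """Δ¹⁴C versus year of formation, with a source label per point."""

    year: np.ndarray
    d14c: np.ndarray
    source: np.ndarray

    def __post_init__(self) -> None:
        self.year = np.asarray(self.year, dtype=float)
        self.d14c = np.asarray(self.d14c, dtype=float)
        self.source = np.asarray(self.source)
        if self.year.size < 10:
            raise ValueError("a reference series needs >= 10 points")
        if not np.all(np.isfinite(self.year)) or not np.all(np.isfinite(self.d14c)):
            raise ValueError("non-finite values in reference series")

    def sorted_by_year(self) -> "ReferenceSeries":
        order = np.argsort(self.year, kind="stable")
        return ReferenceSeries(self.year[order], self.d14c[order], self.source[order])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"year": self.year, "d14c": self.d14c, "source": self.source})


def bomb_curve_mean(years, config: BombCurveConfig) -> np.ndarray:
    """Noiseless mean of the synthetic bomb curve at the given years.

    A monotone piecewise-cubic (PCHIP) interpolant through the plateau, peak
    and end anchors: exactly flat at ``prebomb_level`` before the rise start,
    monotone increasing to the peak, monotone decreasing to the end level,
    and clamped at the boundary values outside the anchor range.
    """
    y = np.atleast_1d(np.asarray(years, dtype=float))
    knots_x = np.array(
        [
            min(config.first_year, config.rise_start_year - 10.0) - 5.0,
            config.rise_start_year,
            config.peak_year,
            config.end_year,
        ]
    )
    knots_y = np.array(
        [config.prebomb_level, config.prebomb_level, config.peak_level, config.end_level]
    )
    interp = PchipInterpolator(knots_x, knots_y)
    out = interp(np.clip(y, knots_x[0], knots_x[-1]))
    return out if np.ndim(years) else float(out[0])


def generate_reference_series(config: BombCurveConfig) -> ReferenceSeries:
    """Sample a noisy reference series on an even year grid."""
    years = np.linspace(config.first_year, config.end_year, config.n_points)
    mean = bomb_curve_mean(years, config)
    rng = np.random.default_rng(config.seed)
    vals = mean + rng.normal(0.0, config.noise_sd, size=years.size) if config.noise_sd > 0 else mean
    # corals carry the record into the 2000s; known-age otoliths extend the decline
    source = np.where(years <= 2004.0, "coral", "otolith")
    return ReferenceSeries(year=years, d14c=np.asarray(vals, float), source=source)


@dataclass(frozen=True)
class ReaderErrorModel:
    """Gaussian ageing error on the age scale, rounded to integer years.

    ``sd_per_year`` scales the error SD with true age (older otoliths are
    harder to read); ``bias`` is a systematic shift applied to the second
    reader. Reads are floored at 1 y.
    """

    sd_per_year: float = 0.08
    bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_per_year < 0:
            raise ValueError("sd_per_year must be >= 0")


def generate_double_reads(true_ages, model: ReaderErrorModel) -> np.ndarray:
    """Two integer opaque-zone counts per fish; shape (n, 2).

    Empty input yields an empty (0, 2) array.
    """
    ages = np.asarray(true_ages, dtype=float)
    if ages.size == 0:
        return np.empty((0, 2), dtype=int)
    if np.any(ages < 1):
        raise ValueError("true ages must be >= 1")
    rng = np.random.default_rng(model.seed)
    sd = model.sd_per_year * ages
    r1 = ages + rng.normal(0.0, 1.0, ages.size) * sd
    r2 = ages + model.bias + rng.normal(0.0, 1.0, ages.size) * sd
    reads = np.column_stack([r1, r2])
    return np.maximum(np.round(reads), 1).astype(int)


def generate_population_sample(
    params: GrowthParams, n: int, seed: int, spec: GridSpec | None = None
):
    """Fishery length-age sample of n fish from the catch composition.

    Returns a pandas DataFrame with fish_id, age_years (integer) and tl_mm.
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    obs = simulate_catch(params, n, seed, spec)
    return pd.DataFrame(
        {
            "fish_id": [f"SIM-{i + 1:05d}" for i in range(n)],
            "age_years": obs[:, 0].astype(int),
            "tl_mm": obs[:, 1],
        }
    )


@dataclass(frozen=True)
class DicProfileConfig:
    """Shape of the synthetic DIC Δ¹⁴C depth profile.

    A bomb-enriched, well-mixed surface layer down to ``mixed_layer_depth``,
    then a linear decline with the given slope (the observed Gulf profile
    declines at −0.289 ‰ per metre over 200–600 m).
    """

    surface_level: float = 60.0  # ‰
    mixed_layer_depth: float = 200.0  # m
    slope: float = -0.289  # ‰ per m below the mixed layer
    max_depth: float = 1248.0  # m
    noise_sd: float = 5.0  # ‰
    n_points: int = 40
    seed: int = 0
    min_depth: float = 5.0  # m

    def __post_init__(self) -> None:
        if not self.mixed_layer_depth < self.max_depth:
            raise ValueError("mixed_layer_depth must be < max_depth")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


@dataclass
class DICProfile:
    """Seawater DIC Δ¹⁴C by depth, with a station label per bottle."""

    depth: np.ndarray
    d14c: np.ndarray
    station: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.d14c = np.asarray(self.d14c, dtype=float)
        if self.station is None:
            self.station = np.array(["DC-1"] * self.depth.size)
        self.station = np.asarray(self.station)
        if np.any(self.depth <= 0):
            raise ValueError("depths must be > 0")
        if not np.all(np.isfinite(self.d14c)):
            raise ValueError("non-finite d14c values")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"station": self.station, "depth_m": self.depth, "d14c": self.d14c}
        )


def dic_profile_mean(depths, config: DicProfileConfig) -> np.ndarray:
    """Noiseless DIC Δ¹⁴C mean: surface plateau then linear decline."""
    d = np.atleast_1d(np.asarray(depths, dtype=float))
    out = np.where(
        d <= config.mixed_layer_depth,
        config.surface_level,
        config.surface_level + config.slope * (d - config.mixed_layer_depth),
    )
    return out if np.ndim(depths) else float(out[0])


def generate_dic_profile(config: DicProfileConfig) -> DICProfile:
    """Sample a noisy DIC profile on an even depth grid across 3 stations."""
    depths = np.linspace(config.min_depth, config.max_depth, config.n_points)
    mean = dic_profile_mean(depths, config)
    rng = np.random.default_rng(config.seed)
    vals = mean + rng.normal(0.0, config.noise_sd, size=depths.size) if config.noise_sd > 0 else mean
    station = np.array([f"DC-{i % 3 + 1}" for i in range(depths.size)])
    return DICProfile(depth=depths, d14c=np.asarray(vals, float), station=station)
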