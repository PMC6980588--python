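"""CSV schemas and readers/writers shared by the pipeline stages.

All dates are normalised to ISO 8601 on input; MM/DD/YYYY (the convention of
the published core-sample table) is accepted. "NM", "--" and empty cells are
parsed as missing, never as zero.

Schemas
-------
fish records:      fish_id, age_years [, tl_mm, read1, read2, sample_date]
reference series:  year, d14c, source
core samples:      sample_id, analysis_id, tl_mm, oto_mass_mg, sample_date,
                   printed_year_of_formation, age_years, d13c, d14c, d14c_sd
DIC profile:       station, depth_m, d14c
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .radiocarbon import RadiocarbonSample
from .synthetic import DICProfile, ReferenceSeries

_NA_VALUES = ["NM", "nm", "--", "-", ""]


def _read_csv(path_or_buf) -> pd.DataFrame:
    return pd.read_csv(path_or_buf, na_values=_NA_VALUES, keep_default_na=True,
                       skipinitialspace=True)


def _normalise_date(s: pd.Series) -> pd.Series:
    """Parse ISO or MM/DD/YYYY dates to datetime.date, NaT-safe."""
    out = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
    remaining = out.isna() & s.notna()
    if remaining.any():
        out[remaining] = pd.to_datetime(s[remaining], format="%m/%d/%Y", errors="coerce")
    return out


def read_reference_series(path) -> ReferenceSeries:
    df = _read_csv(path)
    src = df["source"] if "source" in df.columns else pd.Series(["unknown"] * len(df))
    return ReferenceSeries(
        year=df["year"].to_numpy(float),
        d14c=df["d14c"].to_numpy(float),
        source=src.to_numpy(),
    )


def write_reference_series(series: ReferenceSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_core_samples(path) -> tuple[list, list]:
    """Read otolith-core Δ¹⁴C samples.

    Returns (samples, printed_years): RadiocarbonSample objects plus the
    published years of formation (NaN where absent) for consistency checks.
    """
    df = _read_csv(path)
    dates = _normalise_date(df["sample_date"])
    samples = []
    printed = []
    for i, row in df.iterrows():
        samples.append(
            RadiocarbonSample(
                sample_id=str(row["sample_id"]),
                collection_date=dates.iloc[i].date(),
                tl_mm=float(row["tl_mm"]),
                age_years=int(row["age_years"]),
                d14c=float(row["d14c"]),
                d14c_sd=float(row["d14c_sd"]),
                otolith_mass_mg=(
                    None if pd.isna(row.get("oto_mass_mg")) else float(row["oto_mass_mg"])
                ),
                d13c=None if pd.isna(row.get("d13c")) else float(row["d13c"]),
            )
        )
        printed.append(
            np.nan
            if pd.isna(row.get("printed_year_of_formation"))
            else int(row["printed_year_of_formation"])
        )
    return samples, printed


def load_published_core_samples() -> tuple[list, list]:
    """The 14 published Gulf of Mexico Warsaw grouper otolith-core samples."""
    with resources.files("otolife.data").joinpath("warsaw_otolith_cores.csv").open() as fh:
        return read_core_samples(fh)


def read_dic_profile(path) -> DICProfile:
    df = _read_csv(path)
    return DICProfile(
        depth=df["depth_m"].to_numpy(float),
        d14c=df["d14c"].to_numpy(float),
        station=df["station"].to_numpy() if "station" in df.columns else None,
    )


def write_dic_profile(profile: DICProfile, path) -> None:
    profile.to_frame().to_csv(path, index=False)


def read_fish_records(path) -> pd.DataFrame:
    df = _read_csv(path)
    if "sample_date" in df.columns:
        df["sample_date"] = _normalise_date(df["sample_date"]).dt.strftime("%Y-%m-%d")
    return df


def write_fish_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
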