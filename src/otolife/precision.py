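"""Between-reader ageing precision statistics.

Average percent error (APE, Beamish–Fournier), mean coefficient of variation
(CV, Chang, sample-SD form) and percent reader agreement within a tolerance.
For two readers CV = sqrt(2) * APE per fish, so the two statistics carry the
same information up to scale; agreement adds the tolerance dimension.

Fish with a missing read from any reader are excluded from all three
statistics (the published comparison uses the subsample read by both
readers).
"""

from __future__ import annotations

import numpy as np


def _as_read_matrix(readsets) -> np.ndarray:
    """Coerce input to an (n_fish, n_readers) float matrix, dropping
    fish with any missing (NaN) read."""
    try:
        import pandas as pd

        if isinstance(readsets, pd.DataFrame):
            readsets = readsets.to_numpy()
    except ImportError:  # pragma: no cover
        pass
    reads = np.asarray(readsets, dtype=float)
    if reads.ndim != 2:
        raise ValueError("readsets must be 2-d: one row per fish, one column per reader")
    reads = reads[~np.isnan(reads).any(axis=1)]
    if reads.shape[0] < 1:
        raise ValueError("need at least one fish with complete reads")
    if reads.shape[1] < 2:
        raise ValueError("need at least two readers")
    if np.any(reads < 1):
        raise ValueError("all reads must be >= 1")
    return reads


def average_percent_error(readsets) -> float:
    """Beamish–Fournier APE, percent.

    Per fish j with R reads x_ij and mean x̄_j:
    APE_j = (100/R) Σ_i |x_ij − x̄_j| / x̄_j; the statistic is the mean over
    fish.
    """
    reads = _as_read_matrix(readsets)
    xbar = reads.mean(axis=1)
    if np.any(xbar <= 0):
        raise ValueError("fish with non-positive mean age")
    ape_j = 100.0 / reads.shape[1] * np.abs(reads - xbar[:, None]).sum(axis=1) / xbar
    return float(ape_j.mean())


def mean_cv(readsets) -> float:
    """Chang mean CV, percent, with the (n−1)-denominator sample SD per fish."""
    reads = _as_read_matrix(readsets)
    xbar = reads.mean(axis=1)
    if np.any(xbar <= 0):
        raise ValueError("fish with non-positive mean age")
    s = reads.std(axis=1, ddof=1)
    return float((100.0 * s / xbar).mean())


def percent_agreement(readsets, tolerance: int = 0) -> float:
    """Share of fish (percent) whose two reads differ by at most ``tolerance``.

    Defined for exactly two readers.
    """
    reads = _as_read_matrix(readsets)
    if reads.shape[1] != 2:
        raise ValueError("percent agreement is defined for exactly 2 readers")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    diffs = np.abs(reads[:, 0] - reads[:, 1])
    return float(100.0 * np.mean(diffs <= tolerance))


def precision_summary(readsets) -> dict:
    """One-row summary: APE, CV, agreement at 0/±1/±2 y, and n fish used."""
    reads = _as_read_matrix(readsets)
    return {
        "ape_pct": average_percent_error(reads),
        "cv_pct": mean_cv(reads),
        "agree0_pct": percent_agreement(reads, 0),
        "agree1_pct": percent_agreement(reads, 1),
        "agree2_pct": percent_agreement(reads, 2),
        "n": int(reads.shape[0]),
    }
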