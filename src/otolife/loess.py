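"""Locally weighted polynomial regression (loess) with pointwise confidence bands.

Implements the classic Cleveland loess: for each query point the ``span``
fraction of nearest data points is selected, weighted with the tricube kernel,
and a local polynomial of the requested degree is fit by weighted least
squares. No robustness iterations are performed. The default configuration
(degree = 2, span = 0.20) matches the smoother used to fit marine bomb-pulse
radiocarbon reference series.

Because the fit at each query point is a linear functional of the responses,
an "equivalent kernel" row l(x) is available for every prediction; standard
errors follow as s·‖l(x)‖ with s² the residual variance estimated on
n − tr(L) degrees of freedom, where L is the smoother matrix at the data
points. Confidence bands are Student-t, optionally Bonferroni-corrected for a
family of m simultaneous comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class LoessError(ValueError):
    """Raised for ill-posed loess configurations or queries."""


class ExtrapolationError(LoessError):
    """Raised when a prediction is requested outside the fitted data range."""


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.clip(u, 0.0, 1.0) ** 3, 0.0, None) ** 3
    return w


@dataclass
class LoessFit:
    """A fitted loess curve, evaluable anywhere inside the data range."""

    x: np.ndarray
    y: np.ndarray
    degree: int = 2
    span: float = 0.20

    fitted_: np.ndarray = field(init=False, repr=False)
    residuals_: np.ndarray = field(init=False, repr=False)
    trace_l_: float = field(init=False, repr=False)
    sigma2_: float = field(init=False, repr=False)
    df_resid_: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise LoessError("x and y must be 1-d arrays of equal length")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y)):
            raise LoessError("non-finite values in loess input")
        order = np.argsort(self.x, kind="stable")
        self.x = self.x[order]
        self.y = self.y[order]
        n = self.x.size
        if self._window_size() < self.degree + 2:
            raise LoessError(
                f"span {self.span} covers {self._window_size()} of {n} points; "
                f"need at least degree + 2 = {self.degree + 2}"
            )
        # Smoother diagnostics at the data points (used for s^2 and CIs).
        fitted = np.empty(n)
        trace = 0.0
        sum_ll = 0.0
        for i in range(n):
            yhat, l_row = self._local_fit(self.x[i])
            fitted[i] = yhat
            trace += l_row[i]
            sum_ll += float(l_row @ l_row)
        self.fitted_ = fitted
        self.residuals_ = self.y - fitted
        self.trace_l_ = trace
        self.df_resid_ = max(n - trace, 1.0)
        self.sigma2_ = float(self.residuals_ @ self.residuals_) / self.df_resid_

    # -- internals ---------------------------------------------------------

    def _window_size(self) -> int:
        n = self.x.size
        return min(max(int(np.ceil(self.span * n)), self.degree + 2), n)

    def _local_fit(self, x0: float) -> tuple[float, np.ndarray]:
        """Weighted local polynomial fit at x0.

        Returns the prediction and the equivalent-kernel row over all n
        data points (zero outside the local window).
        """
        n = self.x.size
        k = self._window_size()
        d = np.abs(self.x - x0)
        # bandwidth = k-th smallest distance; ties beyond k get zero weight
        h = np.partition(d, k - 1)[k - 1]
        if h <= 0:
            h = max(np.max(d) * 1e-12, np.finfo(float).tiny)
        w = _tricube(d / h)
        idx = np.nonzero(w > 0)[0]
        if idx.size < self.degree + 1:
            # widen to the k nearest points with near-uniform weights
            idx = np.argsort(d, kind="stable")[:k]
            w = np.zeros(n)
            w[idx] = 1.0
        # centered Vandermonde for conditioning
        t = self.x[idx] - x0
        X = np.vander(t, self.degree + 1, increasing=True)
        wl = w[idx]
        XtW = X.T * wl
        A = XtW @ X
        try:
            ainv_row = np.linalg.solve(A, np.eye(self.degree + 1)[:, 0])
        except np.linalg.LinAlgError as exc:
            raise LoessError(f"singular local design at x0={x0!r}") from exc
        l_local = ainv_row @ XtW  # e1' (X'WX)^-1 X'W
        l_row = np.zeros(n)
        l_row[idx] = l_local
        return float(l_local @ self.y[idx]), l_row

    # -- public API --------------------------------------------------------

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    def _check_range(self, xq: np.ndarray) -> None:
        lo, hi = self.x_range
        if np.any(xq < lo) or np.any(xq > hi):
            bad = xq[(xq < lo) | (xq > hi)]
            raise ExtrapolationError(
                f"query {bad.tolist()} outside fitted range [{lo}, {hi}]"
            )

    def predict(self, xq) -> np.ndarray:
        """Fitted mean at query points (must lie inside the data range)."""
        xq_arr = np.atleast_1d(np.asarray(xq, dtype=float))
        self._check_range(xq_arr)
        out = np.array([self._local_fit(x0)[0] for x0 in xq_arr])
        return out if np.ndim(xq) else out[0]

    def predict_se(self, xq) -> np.ndarray:
        """Standard error of the fitted mean at query points."""
        xq_arr = np.atleast_1d(np.asarray(xq, dtype=float))
        self._check_range(xq_arr)
        rows = [self._local_fit(x0)[1] for x0 in xq_arr]
        se = np.array([np.sqrt(self.sigma2_ * float(r @ r)) for r in rows])
        return se if np.ndim(xq) else se[0]


def fit_loess(x, y=None, degree: int = 2, span: float = 0.20) -> LoessFit:
    """Fit a loess curve to (x, y) or to a reference-series-like object.

    Accepts either two arrays or a single object exposing ``year``/``d14c``
    attributes (e.g. a radiocarbon ReferenceSeries).
    """
    if y is None:
        x, y = x.year, x.d14c
    return LoessFit(np.asarray(x, float), np.asarray(y, float), degree=degree, span=span)


def predict_with_bonferroni_ci(
    fit: LoessFit,
    years,
    family_alpha: float = 0.05,
    m: int | None = None,
):
    """Loess predictions with Bonferroni-corrected pointwise confidence bands.

    The per-comparison level is family_alpha / m, so the band over the m query
    points has simultaneous coverage of at least 1 − family_alpha. With m = 1
    this reduces to the ordinary pointwise interval.

    Returns an array of shape (len(years), 3): columns (mean, lo, hi).
    """
    years_arr = np.atleast_1d(np.asarray(years, dtype=float))
    if m is None:
        m = years_arr.size
    if m < 1:
        raise LoessError("m must be >= 1")
    mean = fit.predict(years_arr)
    se = fit.predict_se(years_arr)
    tcrit = stats.t.ppf(1.0 - family_alpha / (2.0 * m), fit.df_resid_)
    out = np.column_stack([mean, mean - tcrit * se, mean + tcrit * se])
    return out
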