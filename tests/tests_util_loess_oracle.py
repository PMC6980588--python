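"""Shared brute-force local-regression oracle, independent of the package."""

import numpy as np


def brute_force_loess_quadratic(x, y, x0, span=0.20):
    """Local tricube-weighted quadratic fit at a single query point, solved
    through numpy's weighted polynomial fit rather than the package's
    normal-equation path."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    k = max(int(np.ceil(span * x.size)), 4)
    d = np.abs(x - x0)
    h = np.sort(d)[k - 1]
    w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
    sel = w > 0
    coef = np.polynomial.polynomial.polyfit(x[sel] - x0, y[sel], 2, w=np.sqrt(w[sel]))
    return coef[0]
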