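"""Local polynomial regression (LOESS) with tricube weights.

Plain per-point weighted least squares over the span-nearest neighbours,
no robustness iterations.  Written directly (rather than via
statsmodels.lowess) because degree-2 local fits are wanted and the fitted
values must be checkable against a per-point WLS oracle.
"""

from __future__ import annotations

import numpy as np


def loess_smooth(x, y, span: float = 0.25, degree: int = 2) -> np.ndarray:
    """Fitted LOESS values at each x.

    Parameters
    ----------
    x, y : 1-D arrays of equal length.
    span : fraction of points in each local neighbourhood, in (0, 1].
    degree : local polynomial degree (0 = local mean).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if n < degree + 2:
        raise ValueError(f"need at least degree+2={degree + 2} points, got {n}")
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)

    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(k)
        else:
            w = (1 - np.clip(d[idx] / dmax, 0, 1) ** 3) ** 3
        if (w > 0).sum() < degree + 1:
            raise ValueError(
                f"fewer than degree+1 positively weighted points at x={x[i]}")
        # local design in centred coordinates; fitted value = intercept
        t = x[idx] - x[i]
        A = np.vander(t, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], y[idx] * sw, rcond=None)
        fitted[i] = coef[0]
    return fitted
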