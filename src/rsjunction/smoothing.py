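"""Locally weighted polynomial regression (LOESS) with tricube weights.

Local quadratic fits by default; degree 1 reproduces classic lowess.  The
neighbourhood size is ``max(degree + 1, int(span * n))`` points, matching the
convention of standard lowess implementations so the two can be compared
directly at degree 1.
"""

from __future__ import annotations

import numpy as np


def loess(x, y, span: float = 0.2, degree: int = 2,
          xout=None) -> np.ndarray:
    """Smooth ``y`` over ``x`` by locally weighted least squares.

    Parameters
    ----------
    span : fraction of points in each local neighbourhood (0 < span <= 1).
    degree : polynomial degree of the local fit (1 or 2).
    xout : evaluation points; defaults to ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = x.size
    k = max(degree + 1, int(span * n))
    k = min(k, n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    xout = xs if xout is None else np.asarray(xout, dtype=float)

    out = np.empty(xout.size)
    for i, x0 in enumerate(xout):
        d = np.abs(xs - x0)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = ys[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        # weighted polynomial fit centred at x0 for conditioning
        t = xs[idx] - x0
        cols = [np.ones_like(t), t] + ([t ** 2] if degree == 2 else [])
        A = np.stack(cols, axis=1)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], ys[idx] * sw, rcond=None)
        out[i] = coef[0]
    if xout is xs:
        # return in the original x order
        inv = np.empty_like(order)
        inv[order] = np.arange(n)
        return out[inv]
    return out
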