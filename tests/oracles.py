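"""Independent reference implementations used only to check the package.

The natural-spline oracle solves the classic tridiagonal system for the
second derivatives M_i directly with dense linear algebra and evaluates the
piecewise cubic by hand — no call into the package's interpolation path or
into scipy's spline classes.
"""
from __future__ import annotations

import numpy as np


def natural_spline_oracle(t: np.ndarray, y: np.ndarray):
    """Return an evaluator for the natural cubic interpolating spline.

    Textbook construction: with h_i = t_{i+1} - t_i, the interior second
    derivatives solve

        h_{i-1} M_{i-1} + 2 (h_{i-1} + h_i) M_i + h_i M_{i+1}
            = 6 [ (y_{i+1}-y_i)/h_i - (y_i-y_{i-1})/h_{i-1} ]

    with M_0 = M_n = 0 (natural boundary).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t) - 1
    h = np.diff(t)
    A = np.zeros((n + 1, n + 1))
    b = np.zeros(n + 1)
    A[0, 0] = 1.0
    A[n, n] = 1.0
    for i in range(1, n):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2.0 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        b[i] = 6.0 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    M = np.linalg.solve(A, b)

    def evaluate(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty_like(x)
        for k, xv in enumerate(x):
            i = int(np.clip(np.searchsorted(t, xv, side="right") - 1, 0, n - 1))
            hi = h[i]
            a = (t[i + 1] - xv) / hi
            c = (xv - t[i]) / hi
            out[k] = (
                a * y[i]
                + c * y[i + 1]
                + ((a**3 - a) * M[i] + (c**3 - c) * M[i + 1]) * hi**2 / 6.0
            )
        return out

    return evaluate


def polyline_arclength_table(corners):
    """Cumulative arc length along a corner polyline (brute-force oracle)."""
    pts = np.asarray(corners, dtype=float)
    if len(pts) < 2:
        return np.zeros(max(len(pts), 1))
    steps = np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1))
    return np.concatenate([[0.0], np.cumsum(steps)])
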