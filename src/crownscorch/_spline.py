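"""Cubic smoothing spline with an R-style normalized smoothing parameter.

The fit minimizes  sum_i (y_i - f(x_i))^2 + lambda * int f''(u)^2 du  on x
rescaled to u in [0, 1], with cubic B-spline knots at every data point. The
user-facing parameter ``spar`` in [0, 1] maps to the roughness penalty via

    lambda = r * 256 ** (3 * spar - 1),   r = tr(X'X) / tr(Omega),

the convention used by R's smooth.spline, so spar ~ 0 is near-interpolation
and spar ~ 1 is near-linear. The penalty matrix Omega is exact: the second
derivative of a cubic B-spline is piecewise linear, so 2-point Gauss-Legendre
per knot interval integrates the products exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import solve

__all__ = ["smoothing_spline"]


class SmoothingSpline:
    """Callable fitted spline; evaluates on the original x scale."""

    def __init__(self, bspline: BSpline, x_min: float, x_range: float):
        self._bspline = bspline
        self._x_min = x_min
        self._x_range = x_range
        self.domain = (x_min, x_min + x_range)

    def __call__(self, x):
        u = (np.asarray(x, dtype=float) - self._x_min) / self._x_range
        out = self._bspline(np.clip(u, 0.0, 1.0))
        return out if out.ndim else float(out)


def smoothing_spline(x, y, spar: float = 0.65, weights=None) -> SmoothingSpline:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)[order]
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w * len(w) / w.sum()  # mean-1 normalization, as smooth.spline does
    if len(x) < 4:
        raise ValueError("smoothing_spline requires at least 4 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x values must be distinct")

    x_min, x_range = x[0], x[-1] - x[0]
    u = (x - x_min) / x_range

    # cubic B-spline basis with knots at all data sites
    t = np.concatenate([[0.0] * 3, u, [1.0] * 3])
    k = 3
    n_basis = len(t) - k - 1
    design = BSpline.design_matrix(u, t, k).toarray()

    # exact penalty: 2-pt Gauss-Legendre on each knot span of the pw-linear f''
    basis2 = BSpline(t, np.eye(n_basis), k).derivative(2)
    spans = np.unique(t)
    lo, hi = spans[:-1], spans[1:]
    half = (hi - lo) / 2
    mid = (hi + lo) / 2
    gauss = 1.0 / np.sqrt(3.0)
    omega = np.zeros((n_basis, n_basis))
    for sgn in (-gauss, gauss):
        pts = mid + sgn * half
        d = basis2(pts)  # (n_spans, n_basis)
        omega += (d * half[:, None]).T @ d

    xtwx = design.T @ (design * w[:, None])
    r = np.trace(xtwx) / max(np.trace(omega), 1e-300)
    lam = r * 256.0 ** (3.0 * spar - 1.0)

    lhs = xtwx + lam * omega
    rhs = design.T @ (w * y)
    coef = solve(lhs, rhs, assume_a="pos")
    return SmoothingSpline(BSpline(t, coef, k), x_min, x_range)
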