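"""Uniform B-spline basis evaluation with derivatives.

A KAN edge carries a univariate function parameterized as a linear combination
of B-splines on an extended uniform knot vector over a fixed input range.
With ``G`` grid points spanning the range and spline order ``k`` (degree), the
knot vector has ``G + 2k`` entries and supports ``G + k - 1`` basis functions.
Inputs outside the range are clamped to it (the spline is frozen at its edge
values; the derivative is zero there).
"""

from __future__ import annotations

import numpy as np


def make_knots(grid_size: int, order: int, x_range: tuple[float, float] = (-3.0, 3.0)) -> np.ndarray:
    """Extended uniform knot vector: ``grid_size`` points on the range plus ``order`` each side."""
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if order < 1:
        raise ValueError("order must be >= 1")
    lo, hi = x_range
    if lo >= hi:
        raise ValueError("empty x_range")
    h = (hi - lo) / (grid_size - 1)
    return lo + h * np.arange(-order, grid_size + order)


def n_basis(grid_size: int, order: int) -> int:
    return grid_size + order - 1


def bspline_basis(
    x: np.ndarray, knots: np.ndarray, order: int, with_deriv: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Evaluate all B-spline basis functions (and optionally derivatives) at ``x``.

    ``x`` may have any shape; the result has shape ``x.shape + (n_basis,)``.
    Inputs are clamped to the supported range ``[knots[order], knots[-order-1]]``;
    at clamped points the reported derivative is zero (matching the clamped
    function actually evaluated).
    """
    x = np.asarray(x, dtype=float)
    shape = x.shape
    xf = x.ravel()
    lo, hi = knots[order], knots[-order - 1]
    clamped = (xf < lo) | (xf > hi)
    # keep strictly inside so the degree-0 half-open intervals behave at the right edge
    eps = 1e-12 * max(1.0, abs(hi))
    xc = np.clip(xf, lo, hi - eps)

    t = knots
    m = len(t) - 1
    # degree 0
    B = np.zeros((xf.size, m))
    for j in range(m):
        B[:, j] = (t[j] <= xc) & (xc < t[j + 1])
    # Cox-de Boor recursion up to the requested degree
    B_prev = None
    for d in range(1, order + 1):
        B_prev = B
        ncols = m - d
        Bd = np.zeros((xf.size, ncols))
        for j in range(ncols):
            left = (xc - t[j]) / (t[j + d] - t[j]) * B[:, j]
            right = (t[j + d + 1] - xc) / (t[j + d + 1] - t[j + 1]) * B[:, j + 1]
            Bd[:, j] = left + right
        B = Bd
    nb = m - order
    out = B[:, :nb].reshape(*shape, nb)
    if not with_deriv:
        return out
    # derivative from the degree-(order-1) basis
    dB = np.zeros((xf.size, nb))
    for j in range(nb):
        dB[:, j] = order * (
            B_prev[:, j] / (t[j + order] - t[j])
            - B_prev[:, j + 1] / (t[j + order + 1] - t[j + 1])
        )
    dB[clamped] = 0.0
    return out, dB.reshape(*shape, nb)


def fit_spline_coefficients(
    f_values: np.ndarray, x: np.ndarray, knots: np.ndarray, order: int
) -> np.ndarray:
    """Least-squares coefficients so the spline matches ``f_values`` at ``x``."""
    B = bspline_basis(np.asarray(x, dtype=float), knots, order)
    coef, *_ = np.linalg.lstsq(B, np.asarray(f_values, dtype=float), rcond=None)
    return coef
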