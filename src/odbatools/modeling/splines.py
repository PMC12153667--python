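"""Cyclic cubic regression spline basis for circadian effects.

The basis is parameterized by the spline's values at K evenly spaced knots
on the period (mgcv-style "cc" construction): second derivatives at the
knots are obtained from the cyclic tridiagonal spline system, which makes
every basis function a periodic natural cubic spline with continuous value,
first and second derivative across the 0/24 wrap.  Because the columns are
cardinal (value-at-knot) functions, they sum to exactly 1 at any point —
interpolating the constant function — so one column is dropped when an
intercept is present.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cyclic_spline_basis", "cyclic_spline_knots"]


def cyclic_spline_knots(n_knots: int, period: float = 24.0) -> np.ndarray:
    return np.arange(n_knots) * period / n_knots


def _penalty_matrices(knots: np.ndarray, period: float) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic spline system B @ gamma = D @ f linking knot values to curvatures."""
    K = knots.size
    h = np.diff(np.append(knots, knots[0] + period))  # spacings, cyclic
    B = np.zeros((K, K))
    D = np.zeros((K, K))
    for j in range(K):
        jm, jp = (j - 1) % K, (j + 1) % K
        B[j, jm] += h[jm] / 6.0
        B[j, j] += (h[jm] + h[j]) / 3.0
        B[j, jp] += h[j] / 6.0
        D[j, jm] += 1.0 / h[jm]
        D[j, j] -= 1.0 / h[jm] + 1.0 / h[j]
        D[j, jp] += 1.0 / h[j]
    return B, D


def cyclic_spline_basis(x, n_knots: int = 10, period: float = 24.0) -> np.ndarray:
    """Evaluate the K cardinal cyclic-spline basis functions at ``x``.

    Parameters
    ----------
    x
        Points on the periodic axis (hours of day); reduced modulo ``period``.
    n_knots
        Number of knots K (= basis dimension before identifiability drop).

    Returns
    -------
    (len(x), K) array whose rows sum to 1.
    """
    if n_knots < 4:
        raise ValueError("need at least 4 knots for a cyclic cubic spline")
    x = np.atleast_1d(np.asarray(x, dtype=float)) % period
    knots = cyclic_spline_knots(n_knots, period)
    K = n_knots
    h = np.diff(np.append(knots, knots[0] + period))
    B, D = _penalty_matrices(knots, period)
    F = np.linalg.solve(B, D)  # gamma = F @ f

    j = np.minimum((x // (period / K)).astype(int), K - 1)
    jp = (j + 1) % K
    t_j = knots[j]
    hj = h[j]
    a = (t_j + hj - x) / hj
    b = (x - t_j) / hj

    basis = np.zeros((x.size, K))
    rows = np.arange(x.size)
    basis[rows, j] += a
    basis[rows, jp] += b
    curv = ((a**3 - a)[:, None] * F[j, :] + (b**3 - b)[:, None] * F[jp, :])
    basis += curv * (hj**2 / 6.0)[:, None]
    return basis
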