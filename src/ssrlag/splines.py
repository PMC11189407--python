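"""Cubic regression spline bases with exact roughness penalties.

Two basis families are provided, both parameterised by the function values at
``k`` knots (so coefficients are directly interpretable on the scale of the
smooth):

* :func:`cr_basis` — natural cubic regression spline on a knot grid, with the
  integrated squared second derivative as penalty.  The penalty null space is
  exactly the linear functions.
* :func:`cyclic_cr_basis` — the periodic variant (value and second derivative
  match at the two ends of the period), suitable for a month-of-year effect.
  Its penalty null space is the constants.

Both penalties are exact quadratic forms ``beta' S beta = integral f''(x)^2 dx``
for the interpolating (periodic) natural cubic spline, built from the classical
banded value/second-derivative relations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space


@dataclass(frozen=True)
class SmoothTermSpec:
    """Configuration of one penalized smooth term.

    Parameters
    ----------
    name
        Covariate name the smooth applies to.
    k
        Basis dimension (number of knots), ``k >= 3``.
    cyclic
        Periodic basis (use for month-of-year); requires ``period``.
    shrinkage
        Add a null-space penalty with its own smoothing parameter so the whole
        term can be shrunk to zero effective degrees of freedom.
    period
        Period of a cyclic covariate (12 for calendar months).
    """

    name: str
    k: int = 10
    cyclic: bool = False
    shrinkage: bool = True
    period: float | None = None

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError(f"smooth '{self.name}': basis dimension k={self.k} < 3")
        if self.cyclic and self.period is None:
            raise ValueError(f"smooth '{self.name}': cyclic basis needs a period")


def place_knots(x: np.ndarray, k: int) -> np.ndarray:
    """Knots at quantiles of the unique covariate values (endpoints included)."""
    ux = np.unique(np.asarray(x, dtype=float))
    if ux.size < k:
        raise ValueError(f"k={k} exceeds the {ux.size} distinct covariate values")
    knots = np.quantile(ux, np.linspace(0.0, 1.0, k))
    knots = np.unique(knots)
    if knots.size < k:  # heavily tied quantiles; fall back to even spread
        knots = np.linspace(ux[0], ux[-1], k)
    return knots


def _cr_FB(knots: np.ndarray):
    """Value -> interior second-derivative map for a natural cubic spline.

    Returns ``F`` ((k-2) x k) with ``delta_interior = F beta`` and the banded
    matrices ``B`` ((k-2) x (k-2)) and ``D`` ((k-2) x k) such that
    ``B delta_interior = D beta`` and the roughness penalty is ``D' B^-1 D``.
    """
    h = np.diff(knots)
    k = knots.size
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    F = np.linalg.solve(B, D)
    return F, B, D


def cr_basis(x: np.ndarray, knots: np.ndarray):
    """Natural cubic regression spline basis and its roughness penalty.

    Coefficients are the function values at the knots.  Values of ``x`` outside
    the knot range are evaluated by linear extrapolation of the end segments
    (natural boundary conditions make the spline linear beyond the ends).

    Returns
    -------
    X : (n, k) design matrix
    S : (k, k) penalty, the exact integral of the squared second derivative
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = knots.size
    F, B, D = _cr_FB(knots)
    S = D.T @ np.linalg.solve(B, D)
    S = (S + S.T) / 2.0

    Ffull = np.zeros((k, k))  # second derivatives at all knots (natural: ends 0)
    Ffull[1:-1, :] = F

    xc = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    h = knots[j + 1] - knots[j]
    am = (knots[j + 1] - xc) / h
    ap = (xc - knots[j]) / h
    cm = ((knots[j + 1] - xc) ** 3 / h - h * (knots[j + 1] - xc)) / 6.0
    cp = ((xc - knots[j]) ** 3 / h - h * (xc - knots[j])) / 6.0

    n = x.size
    X = np.zeros((n, k))
    rows = np.arange(n)
    X[rows, j] += am
    X[rows, j + 1] += ap
    X += cm[:, None] * Ffull[j, :] + cp[:, None] * Ffull[j + 1, :]

    # linear extension beyond the knot range (f'' = 0 there)
    below = x < knots[0]
    above = x > knots[-1]
    if below.any() or above.any():
        eps = (knots[-1] - knots[0]) * 1e-6
        for mask, x0 in ((below, knots[0]), (above, knots[-1])):
            if not mask.any():
                continue
            Xa, _ = _cr_eval_interior(np.array([x0, x0 + (eps if x0 == knots[0] else -eps)]), knots, Ffull)
            slope = (Xa[1] - Xa[0]) / (eps if x0 == knots[0] else -eps)
            X[mask, :] = Xa[0][None, :] + (x[mask] - x0)[:, None] * slope[None, :]
    return X, S


def _cr_eval_interior(x, knots, Ffull):
    k = knots.size
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    h = knots[j + 1] - knots[j]
    am = (knots[j + 1] - x) / h
    ap = (x - knots[j]) / h
    cm = ((knots[j + 1] - x) ** 3 / h - h * (knots[j + 1] - x)) / 6.0
    cp = ((x - knots[j]) ** 3 / h - h * (x - knots[j])) / 6.0
    X = np.zeros((x.size, k))
    rows = np.arange(x.size)
    X[rows, j] += am
    X[rows, j + 1] += ap
    X += cm[:, None] * Ffull[j, :] + cp[:, None] * Ffull[j + 1, :]
    return X, j


def cyclic_cr_basis(x: np.ndarray, knots: np.ndarray, period: float):
    """Cyclic cubic regression spline basis and penalty.

    ``knots`` are ``k`` strictly increasing values spanning less than one
    period; the spline wraps from ``knots[-1]`` back to ``knots[0] + period``.
    Inputs are mapped into the fundamental period, so evaluating one step past
    the last knot reproduces the first knot's value.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = knots.size
    if knots[-1] - knots[0] >= period:
        raise ValueError("cyclic knots must span less than one period")
    kx = np.concatenate([knots, [knots[0] + period]])
    h = np.diff(kx)  # k interval widths, cyclic

    # periodic value/second-derivative relations: B delta = D beta (both k x k)
    B = np.zeros((k, k))
    D = np.zeros((k, k))
    for i in range(k):
        im1 = (i - 1) % k
        ip1 = (i + 1) % k
        B[i, i] = (h[im1] + h[i]) / 3.0
        B[i, im1] += h[im1] / 6.0
        B[i, ip1] += h[i] / 6.0
        D[i, im1] += 1.0 / h[im1]
        D[i, i] += -1.0 / h[im1] - 1.0 / h[i]
        D[i, ip1] += 1.0 / h[i]
    F = np.linalg.solve(B, D)  # delta = F beta at every knot
    S = D.T @ F
    S = (S + S.T) / 2.0

    xm = knots[0] + np.mod(x - knots[0], period)
    j = np.clip(np.searchsorted(kx, xm, side="right") - 1, 0, k - 1)
    hj = kx[j + 1] - kx[j]
    am = (kx[j + 1] - xm) / hj
    ap = (xm - kx[j]) / hj
    cm = ((kx[j + 1] - xm) ** 3 / hj - hj * (kx[j + 1] - xm)) / 6.0
    cp = ((xm - kx[j]) ** 3 / hj - hj * (xm - kx[j])) / 6.0

    n = x.size
    X = np.zeros((n, k))
    rows = np.arange(n)
    jp1 = (j + 1) % k
    X[rows, j] += am
    X[rows, jp1] += ap
    X += cm[:, None] * F[j, :] + cp[:, None] * F[jp1, :]
    return X, S


def nullspace_penalty(S: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Projection onto the penalty null space, used as the shrinkage penalty.

    With an extra smoothing parameter on this matrix the components a roughness
    penalty cannot touch (constant/linear parts) can also be shrunk, letting a
    term's effective degrees of freedom reach zero.
    """
    w, U = np.linalg.eigh(S)
    thresh = tol * max(w.max(), 1.0)
    U0 = U[:, w < thresh]
    return U0 @ U0.T


def absorb_sum_to_zero(X: np.ndarray, penalties: list[np.ndarray]):
    """Reparameterise a smooth so its fitted values sum to zero.

    Returns the reduced (n, k-1) design, the transformed penalties and the
    (k, k-1) transform ``Z`` (columns orthonormal) with ``beta_full = Z beta``.
    """
    c = X.mean(axis=0, keepdims=True)
    Z = null_space(c)
    # fix signs for cross-platform determinism
    for j in range(Z.shape[1]):
        i = np.argmax(np.abs(Z[:, j]))
        if Z[i, j] < 0:
            Z[:, j] = -Z[:, j]
    Xz = X @ Z
    Sz = [(Z.T @ S @ Z + (Z.T @ S @ Z).T) / 2.0 for S in penalties]
    return Xz, Sz, Z
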