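"""Penalized B-spline building blocks (P-splines).

Cubic B-spline bases on equally spaced knots with a second-order
difference penalty on the coefficients.  Used by the smooth additive
learner and by the univariate smooth regression in the bias diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline


@dataclass
class BSplineBasis:
    """Cubic B-spline basis frozen to a training-data range.

    Inputs outside the training range are clamped to it before
    evaluation, so predictions on new data stay defined (flat
    extrapolation of the boundary basis values).
    """

    lo: float
    hi: float
    nbasis: int
    degree: int = 3

    def __post_init__(self) -> None:
        if self.hi <= self.lo:  # constant input; keep a token 1-wide range
            self.hi = self.lo + 1.0
        ninner = self.nbasis - self.degree + 1
        inner = np.linspace(self.lo, self.hi, ninner)
        self.knots = np.concatenate([
            np.repeat(inner[0], self.degree), inner,
            np.repeat(inner[-1], self.degree)])

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, self.degree,
                                     extrapolate=False).toarray()

    @classmethod
    def from_data(cls, x: np.ndarray, nbasis: int = 10) -> "BSplineBasis":
        x = np.asarray(x, dtype=float)
        return cls(lo=float(np.nanmin(x)), hi=float(np.nanmax(x)), nbasis=nbasis)


def difference_penalty(nbasis: int, order: int = 2) -> np.ndarray:
    """S = D'D for the order-th difference matrix D (P-spline penalty)."""
    D = np.diff(np.eye(nbasis), n=order, axis=0)
    return D.T @ D


def shrinkage_penalty(nbasis: int, order: int = 2,
                      scale: float = 0.1) -> np.ndarray:
    """Null-space ridge so a single smoothing parameter can zero a term.

    The difference penalty leaves polynomial components of degree <
    ``order`` unpenalized; adding ``scale`` times a projector onto that
    null space makes the combined penalty positive definite, letting a
    large smoothing parameter shrink the whole term to zero.
    """
    S = difference_penalty(nbasis, order)
    w, V = np.linalg.eigh(S)
    null = V[:, w < 1e-10 * w.max()]
    return scale * (null @ null.T)


@dataclass
class SmoothFit1D:
    """Penalized least-squares smooth of y on x with GCV-chosen lambda."""

    basis: BSplineBasis
    coef: np.ndarray
    intercept: float
    lam: float
    edf: float
    r2: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.basis.design(x) @ self.coef


def smooth_regression_1d(x: np.ndarray, y: np.ndarray, nbasis: int = 10,
                         lambdas: np.ndarray | None = None) -> SmoothFit1D:
    """Univariate penalized-spline regression with GCV smoothing selection.

    Returns the fitted smooth together with its effective degrees of
    freedom and coefficient of determination R^2 = 1 - SSE/SST.  A
    zero-variance response yields R^2 = NaN (undefined), never 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambdas is None:
        lambdas = np.logspace(-4, 6, 11)
    basis = BSplineBasis.from_data(x, nbasis=nbasis)
    B = basis.design(x)
    Bmean = B.mean(axis=0)
    Bc = B - Bmean
    ymean = y.mean()
    yc = y - ymean
    S = difference_penalty(nbasis) + shrinkage_penalty(nbasis)
    BtB = Bc.T @ Bc
    Bty = Bc.T @ yc
    n = y.size
    sst = float(yc @ yc)

    best = None
    for lam in lambdas:
        A = BtB + lam * S
        coef = np.linalg.solve(A, Bty)
        fitted = Bc @ coef
        sse = float(((yc - fitted) ** 2).sum())
        edf = 1.0 + float(np.trace(np.linalg.solve(A, BtB)))
        gcv = n * sse / max(n - edf, 1e-8) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, sse, edf)
    _, lam, coef, sse, edf = best
    r2 = np.nan if sst <= 0 else 1.0 - sse / sst
    return SmoothFit1D(basis=basis, coef=coef,
                       intercept=float(ymean - Bmean @ coef),
                       lam=float(lam), edf=edf, r2=r2)
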