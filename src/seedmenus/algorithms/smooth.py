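"""Binomial additive model with penalized univariate smooths.

One cubic P-spline smooth per covariate, fit by penalized IRLS.  Each
term carries a second-difference penalty plus a null-space shrinkage
penalty sharing the term's smoothing parameter, so a sufficiently large
smoothing parameter drives the whole term — including its linear
component — to zero (mirroring "select"-style extra penalization).
Per-term smoothing parameters are chosen by cyclic grid search
minimizing UBRE (deviance + 2 * edf).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base import TrainingData
from .splines import BSplineBasis, difference_penalty, shrinkage_penalty

_EPS = 1e-9


@dataclass
class PenalizedAdditiveModel:
    """Fitted penalized additive logistic model."""

    variables: tuple[str, ...]
    bases: dict[str, BSplineBasis]
    column_means: dict[str, np.ndarray]
    intercept: float
    coefs: dict[str, np.ndarray]
    lambdas: dict[str, float]
    edf: dict[str, float]
    deviance: float
    n_obs: int

    # --- contract ---------------------------------------------------------
    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(table), self.intercept)
        for code in self.variables:
            B = self.bases[code].design(table[code].to_numpy())
            eta += (B - self.column_means[code]) @ self.coefs[code]
        return eta

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Occurrence probability in [0, 1] at the given covariate rows."""
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-self.linear_predictor(table)))

    def parameter_count(self) -> float:
        """Total effective degrees of freedom (including the intercept)."""
        return 1.0 + float(sum(self.edf.values()))

    def term_complexity(self, code: str) -> float:
        """Effective degrees of freedom of one smooth term."""
        return float(self.edf[code])

    def term_importance(self) -> dict[str, float]:
        """Per-term importance = the term's edf (shrunk terms score ~0)."""
        return {c: float(self.edf[c]) for c in self.variables}

    def to_dict(self) -> dict:
        return {
            "kind": "smooth_additive",
            "variables": list(self.variables),
            "intercept": self.intercept,
            "bases": {c: {"lo": b.lo, "hi": b.hi, "nbasis": b.nbasis}
                      for c, b in self.bases.items()},
            "column_means": {c: m.tolist() for c, m in self.column_means.items()},
            "coefs": {c: v.tolist() for c, v in self.coefs.items()},
            "lambdas": self.lambdas,
            "edf": self.edf,
            "deviance": self.deviance,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PenalizedAdditiveModel":
        return cls(
            variables=tuple(d["variables"]),
            bases={c: BSplineBasis(**b) for c, b in d["bases"].items()},
            column_means={c: np.asarray(m) for c, m in d["column_means"].items()},
            intercept=d["intercept"],
            coefs={c: np.asarray(v) for c, v in d["coefs"].items()},
            lambdas=d["lambdas"], edf=d["edf"], deviance=d["deviance"],
            n_obs=d["n_obs"],
        )


def _pirls(Xblocks, S_blocks, lambdas, y, w, max_iter=30, tol=1e-7):
    """Penalized IRLS for the binomial additive model.

    ``Xblocks`` are centered per-term design blocks; an unpenalized
    intercept column is prepended.  Returns (beta, deviance, per-term edf).
    """
    n = y.size
    X = np.concatenate([np.ones((n, 1))] + Xblocks, axis=1)
    p = X.shape[1]
    S = np.zeros((p, p))
    ofs = 1
    for Sj, lam in zip(S_blocks, lambdas):
        k = Sj.shape[0]
        S[ofs:ofs + k, ofs:ofs + k] = lam * Sj
        ofs += k

    beta = np.zeros(p)
    ybar = np.clip(np.average(y, weights=w), 1e-3, 1 - 1e-3)
    beta[0] = np.log(ybar / (1 - ybar))
    dev_old = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        with np.errstate(over="ignore"):
            mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, _EPS, 1 - _EPS)
        wt = w * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        XtW = X.T * wt
        A = XtW @ X + S
        beta_new = np.linalg.solve(A, XtW @ z)
        dev = -2.0 * float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            beta = beta_new
            break
        beta, dev_old = beta_new, dev

    # final quantities at convergence
    eta = X @ beta
    with np.errstate(over="ignore"):
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _EPS, 1 - _EPS)
    wt = w * mu * (1 - mu)
    XtWX = (X.T * wt) @ X
    F = np.linalg.solve(XtWX + S, XtWX)
    diag = np.diag(F)
    dev = -2.0 * float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
    edfs = []
    ofs = 1
    for Sj in S_blocks:
        k = Sj.shape[0]
        edfs.append(float(diag[ofs:ofs + k].sum()))
        ofs += k
    return beta, dev, edfs


def fit_smooth_additive(spec, data: TrainingData, seed: int = 0,
                        nbasis: int = 10, min_presences: int = 20,
                        lambda_grid: np.ndarray | None = None,
                        n_cycles: int = 1) -> PenalizedAdditiveModel:
    """Fit the penalized additive logistic learner for one variable subset.

    ``seed`` is accepted for contract symmetry; the fit itself is a
    deterministic optimization.  Raises if fewer than ``min_presences``
    presence rows are available or labels are single-class.
    """
    data.require_both_classes()
    if data.n_presence < min_presences:
        raise ValueError(
            f"need at least {min_presences} presences, got {data.n_presence}")
    variables = tuple(spec.variables)
    y = data.labels.astype(float)
    w = data.weights
    if lambda_grid is None:
        lambda_grid = np.logspace(-2.0, 6.0, 7)

    bases: dict[str, BSplineBasis] = {}
    col_means: dict[str, np.ndarray] = {}
    Xblocks = []
    S_blocks = []
    for code in variables:
        x = data.table[code].to_numpy(dtype=float)
        basis = BSplineBasis.from_data(x, nbasis=nbasis)
        B = basis.design(x)
        m = B.mean(axis=0)
        bases[code] = basis
        col_means[code] = m
        Xblocks.append(B - m)
        S_blocks.append(difference_penalty(nbasis) + shrinkage_penalty(nbasis))

    lambdas = [1.0] * len(variables)
    beta, dev, edfs = _pirls(Xblocks, S_blocks, lambdas, y, w)
    best_score = dev + 2.0 * (1.0 + sum(edfs))
    # cyclic per-term grid search on UBRE
    for _ in range(n_cycles):
        for j in range(len(variables)):
            for lam in lambda_grid:
                if lam == lambdas[j]:
                    continue
                trial = list(lambdas)
                trial[j] = lam
                b, d, e = _pirls(Xblocks, S_blocks, trial, y, w)
                score = d + 2.0 * (1.0 + sum(e))
                if score < best_score - 1e-9:
                    best_score, lambdas = score, trial
                    beta, dev, edfs = b, d, e

    coefs = {}
    ofs = 1
    for code in variables:
        coefs[code] = beta[ofs:ofs + nbasis]
        ofs += nbasis
    return PenalizedAdditiveModel(
        variables=variables, bases=bases, column_means=col_means,
        intercept=float(beta[0]), coefs=coefs,
        lambdas={c: float(l) for c, l in zip(variables, lambdas)},
        edf={c: e for c, e in zip(variables, edfs)},
        deviance=dev, n_obs=int(y.size))
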