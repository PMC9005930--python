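"""Maximum-entropy presence/background learner.

The model estimates a log-linear relative-intensity surface over a
feature expansion of the covariates (linear, quadratic, pairwise
product and hinge features), fit as an L1-regularized logistic
discrimination of presences against background.  The *raw* output is
the Gibbs distribution exp(beta . f(x)) normalized to sum to one over
the background sample; the *logistic* output rescales raw values with
the exponential-entropy constant c = e^H so that typical habitat maps
onto interpretable [0, 1] suitabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .base import TrainingData

DEFAULT_FEATURES = frozenset({"linear", "quadratic", "product", "hinge"})
_ZERO_TOL = 1e-8


@dataclass
class MaxentFeatureMapper:
    """Frozen feature expansion: variable ranges + hinge knots."""

    variables: tuple[str, ...]
    features: frozenset
    lo: dict[str, float]
    hi: dict[str, float]
    hinge_knots: dict[str, np.ndarray]

    @classmethod
    def from_data(cls, table: pd.DataFrame, variables, features,
                  n_hinge: int = 20) -> "MaxentFeatureMapper":
        lo, hi, knots = {}, {}, {}
        for v in variables:
            x = table[v].to_numpy(dtype=float)
            lo[v] = float(np.min(x))
            hi[v] = float(np.max(x))
            if "hinge" in features and hi[v] > lo[v]:
                qs = np.linspace(0.05, 0.95, max(n_hinge // 2, 1))
                knots[v] = np.quantile(x, qs)
            else:
                knots[v] = np.empty(0)
        return cls(tuple(variables), frozenset(features), lo, hi, knots)

    def _scaled(self, table: pd.DataFrame, v: str) -> np.ndarray:
        x = table[v].to_numpy(dtype=float)
        span = self.hi[v] - self.lo[v]
        if span <= 0:
            return np.zeros(len(table))
        return np.clip((x - self.lo[v]) / span, 0.0, 1.0)

    def transform(self, table: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, str]]]:
        """Feature matrix plus (variable, feature-name) labels per column."""
        cols, labels = [], []
        scaled = {v: self._scaled(table, v) for v in self.variables}
        for v in self.variables:
            if "linear" in self.features:
                cols.append(scaled[v]); labels.append((v, f"linear:{v}"))
            if "quadratic" in self.features:
                cols.append(scaled[v] ** 2); labels.append((v, f"quad:{v}"))
        if "product" in self.features:
            for i, a in enumerate(self.variables):
                for b in self.variables[i + 1:]:
                    cols.append(scaled[a] * scaled[b])
                    labels.append((f"{a}*{b}", f"prod:{a}*{b}"))
        if "hinge" in self.features:
            for v in self.variables:
                x = table[v].to_numpy(dtype=float)
                span = self.hi[v] - self.lo[v]
                for k in self.hinge_knots[v]:
                    denom_f = max(self.hi[v] - k, 1e-12)
                    cols.append(np.clip((x - k) / denom_f, 0.0, 1.0))
                    labels.append((v, f"hingef:{v}@{k:.6g}"))
                    denom_r = max(k - self.lo[v], 1e-12)
                    cols.append(np.clip((k - x) / denom_r, 0.0, 1.0))
                    labels.append((v, f"hinger:{v}@{k:.6g}"))
        if not cols:
            raise ValueError("no usable features (all covariates constant?)")
        return np.column_stack(cols), labels


@dataclass
class MaxentModel:
    """Fitted maximum-entropy presence/background model."""

    variables: tuple[str, ...]
    mapper: MaxentFeatureMapper
    coef: np.ndarray
    feature_labels: list[tuple[str, str]]
    log_z: float          # log partition over the fitting background
    n_background: int
    entropy: float
    train_table: pd.DataFrame
    train_labels: np.ndarray
    seed: int

    def _eta(self, table: pd.DataFrame) -> np.ndarray:
        F, _ = self.mapper.transform(table)
        return F @ self.coef

    def raw(self, table: pd.DataFrame) -> np.ndarray:
        """Raw output: relative intensity normalized over the background.

        Sums to 1 over the background sample the model was fit with.
        """
        return np.exp(self._eta(table) - self.log_z)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Logistic-scaled suitability in [0, 1] (c = e^H rescaling)."""
        r = self.raw(table)
        c = np.exp(self.entropy)
        return np.clip(c * r / (1.0 + c * r), 0.0, 1.0)

    def parameter_count(self) -> int:
        """Number of coefficients above the zero tolerance."""
        return int(np.sum(np.abs(self.coef) > _ZERO_TOL))

    def term_complexity(self, code: str) -> float:
        """Number of active features involving the given variable."""
        mask = [code in var.split("*") for var, _ in self.feature_labels]
        return int(np.sum(np.abs(self.coef[mask]) > _ZERO_TOL))

    def term_importance(self, rng: np.random.Generator | None = None) -> dict[str, float]:
        """Permutation importance: drop in presence-vs-background AUC.

        Each variable's raw column is permuted across the training rows
        and the decrease in discrimination (AUC of eta scores) recorded;
        negative drops are clipped to 0.
        """
        from ..metrics import auc as _auc
        if rng is None:
            rng = np.random.default_rng(self.seed)
        y = self.train_labels
        eta = self._eta(self.train_table)
        base = _auc(eta[y == 1], eta[y == 0])
        out = {}
        for v in self.variables:
            perm = self.train_table.copy()
            perm[v] = rng.permutation(perm[v].to_numpy())
            eta_p = self._eta(perm)
            out[v] = max(base - _auc(eta_p[y == 1], eta_p[y == 0]), 0.0)
        return out

    def to_dict(self) -> dict:
        return {
            "kind": "maxent_like",
            "variables": list(self.variables),
            "coef": self.coef.tolist(),
            "feature_labels": [list(t) for t in self.feature_labels],
            "log_z": self.log_z, "n_background": self.n_background,
            "entropy": self.entropy,
            "mapper": {
                "features": sorted(self.mapper.features),
                "lo": self.mapper.lo, "hi": self.mapper.hi,
                "hinge_knots": {k: v.tolist()
                                for k, v in self.mapper.hinge_knots.items()},
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaxentModel":
        """Rebuild a prediction-capable model from :meth:`to_dict` output.

        Training rows are not serialized, so permutation importance is
        unavailable on the reconstructed model.
        """
        m = d["mapper"]
        mapper = MaxentFeatureMapper(
            variables=tuple(d["variables"]),
            features=frozenset(m["features"]), lo=m["lo"], hi=m["hi"],
            hinge_knots={k: np.asarray(v) for k, v in m["hinge_knots"].items()})
        return cls(variables=tuple(d["variables"]), mapper=mapper,
                   coef=np.asarray(d["coef"]),
                   feature_labels=[tuple(t) for t in d["feature_labels"]],
                   log_z=d["log_z"], n_background=d["n_background"],
                   entropy=d["entropy"], train_table=pd.DataFrame(),
                   train_labels=np.empty(0, dtype=np.int8), seed=0)


def fit_maxent_like(spec, presence: pd.DataFrame, background: pd.DataFrame,
                    regularization: float = 1.0,
                    features: frozenset = DEFAULT_FEATURES,
                    seed: int = 0, n_hinge: int = 20,
                    min_presences: int = 10) -> MaxentModel:
    """Fit the maximum-entropy learner for one variable subset.

    ``presence`` and ``background`` are covariate tables (background may
    include presence cells).  ``regularization`` multiplies the default
    L1 penalty; larger values give sparser models.
    """
    if len(presence) < min_presences:
        raise ValueError(f"need at least {min_presences} presences")
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    if regularization <= 0:
        raise ValueError("regularization multiplier must be positive")
    variables = tuple(spec.variables)
    both = pd.concat([presence[list(variables)], background[list(variables)]],
                     ignore_index=True)
    mapper = MaxentFeatureMapper.from_data(both, variables, features,
                                           n_hinge=n_hinge)
    F, labels = mapper.transform(both)
    if np.allclose(F.std(axis=0), 0.0):
        raise ValueError("no usable features (all covariates constant)")
    y = np.concatenate([np.ones(len(presence)), np.zeros(len(background))])
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / regularization, solver="liblinear",
        max_iter=500, random_state=int(seed) % (2 ** 31))
    clf.fit(F, y)
    coef = clf.coef_.ravel().copy()

    Fb, _ = mapper.transform(background[list(variables)])
    eta_b = Fb @ coef
    m = eta_b.max()
    log_z = m + np.log(np.exp(eta_b - m).sum())
    p_b = np.exp(eta_b - log_z)
    entropy = float(-(p_b * np.log(np.clip(p_b, 1e-300, None))).sum())
    return MaxentModel(
        variables=variables, mapper=mapper, coef=coef, feature_labels=labels,
        log_z=float(log_z), n_background=len(background), entropy=entropy,
        train_table=both, train_labels=y.astype(np.int8),
        seed=int(seed) % (2 ** 31))
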