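"""Random-forest presence/absence learner."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .base import TrainingData


@dataclass
class ForestModel:
    """Classification forest; suitability = presence-class probability."""

    variables: tuple[str, ...]
    forest: RandomForestClassifier
    train_table: pd.DataFrame
    train_labels: np.ndarray
    seed: int

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.variables)].to_numpy(dtype=float)
        return self.forest.predict_proba(X)[:, 1]

    def parameter_count(self):
        """Forests have no likelihood-based parameter count."""
        return None

    def term_complexity(self, code: str):
        return None

    def term_importance(self, rng: np.random.Generator | None = None,
                        n_repeats: int = 3) -> dict[str, float]:
        """Mean decrease in accuracy when each term is permuted.

        Accuracy is measured at the 0.5 vote threshold on the training
        sample; each variable's column is permuted ``n_repeats`` times and
        the mean accuracy drop (clipped at 0) is returned.
        """
        if rng is None:
            rng = np.random.default_rng(self.seed)
        X = self.train_table[list(self.variables)].to_numpy(dtype=float)
        y = self.train_labels
        base = float(np.mean((self.forest.predict_proba(X)[:, 1] >= 0.5) == y))
        out = {}
        for j, code in enumerate(self.variables):
            drops = []
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                acc = float(np.mean(
                    (self.forest.predict_proba(Xp)[:, 1] >= 0.5) == y))
                drops.append(base - acc)
            out[code] = max(float(np.mean(drops)), 0.0)
        return out

    def partial_dependence(self, code: str, grid: np.ndarray,
                           background: pd.DataFrame | None = None,
                           max_background: int = 50,
                           rng: np.random.Generator | None = None) -> np.ndarray:
        """Data-averaged partial dependence of suitability on one term."""
        if background is None:
            background = self.train_table
        if len(background) > max_background:
            if rng is None:
                rng = np.random.default_rng(self.seed)
            idx = rng.choice(len(background), size=max_background, replace=False)
            background = background.iloc[idx]
        X = background[list(self.variables)].to_numpy(dtype=float)
        j = list(self.variables).index(code)
        grid = np.asarray(grid, dtype=float)
        Xg = np.repeat(X[None, :, :], grid.size, axis=0)
        Xg[:, :, j] = grid[:, None]
        probs = self.forest.predict_proba(Xg.reshape(-1, X.shape[1]))[:, 1]
        return probs.reshape(grid.size, X.shape[0]).mean(axis=1)


def fit_tree_ensemble(spec, data: TrainingData, n_trees: int = 1000,
                      seed: int = 0) -> ForestModel:
    """Fit the random-forest learner for one variable subset."""
    if n_trees < 1:
        raise ValueError("n_trees must be at least 1")
    data.require_both_classes()
    variables = tuple(spec.variables)
    X = data.table[list(variables)].to_numpy(dtype=float)
    y = data.labels
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed) % (2 ** 31), n_jobs=1)
    forest.fit(X, y, sample_weight=data.weights)
    return ForestModel(variables=variables, forest=forest,
                       train_table=data.table[list(variables)].copy(),
                       train_labels=y.copy(), seed=int(seed) % (2 ** 31))
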