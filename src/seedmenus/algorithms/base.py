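"""Shared containers for the presence/background fitting contract."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TrainingData:
    """Covariate table + 0/1 labels (+ per-row weights) for one fit.

    Rows are presence (label 1) and pseudo-absence/background (label 0)
    cells; columns of ``table`` are covariate codes.
    """

    table: pd.DataFrame
    labels: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.table) != self.labels.size or self.labels.size != self.weights.size:
            raise ValueError("table, labels and weights must align")

    @property
    def n_presence(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_absence(self) -> int:
        return int((self.labels == 0).sum())

    def require_both_classes(self) -> None:
        if self.n_presence == 0 or self.n_absence == 0:
            raise ValueError("labels must contain both classes")

    def subset(self, mask: np.ndarray) -> "TrainingData":
        mask = np.asarray(mask, dtype=bool)
        return TrainingData(self.table.iloc[mask].reset_index(drop=True),
                            self.labels[mask], self.weights[mask])


def make_training_data(stack, presence_cells, absence_cells, codes,
                       balance_weights: bool = False) -> TrainingData:
    """Assemble a :class:`TrainingData` from stack cells.

    With ``balance_weights`` the absence rows are down-weighted so total
    absence weight equals total presence weight (the usual treatment for
    regression-style learners fit against a large background).
    """
    presence_cells = np.asarray(presence_cells, dtype=np.int64)
    absence_cells = np.asarray(absence_cells, dtype=np.int64)
    cells = np.concatenate([presence_cells, absence_cells])
    table = stack.table(cells=cells, codes=list(codes)).reset_index(drop=True)
    labels = np.concatenate([np.ones(presence_cells.size, dtype=np.int8),
                             np.zeros(absence_cells.size, dtype=np.int8)])
    weights = np.ones(cells.size)
    if balance_weights and absence_cells.size > 0 and presence_cells.size > 0:
        weights[labels == 0] = presence_cells.size / absence_cells.size
    return TrainingData(table, labels, weights)
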