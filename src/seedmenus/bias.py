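"""Systematic sampling-bias diagnostic.

If occurrence records cluster near roads and other developed features,
the fitted habitat maps may inherit that accessibility signal.  The
diagnostic aggregates the per-species habitat-probability and
standard-error layers to their cross-species cell means, computes each
cell's Euclidean distance to the nearest developed feature, fits a
flexible univariate smooth of aggregated value on distance, and reports
the smooth's coefficient of determination together with an
eight-equal-width-bin distance summary.  A near-zero R-squared is the
expected signature of an unbiased model suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .algorithms.splines import smooth_regression_1d
from .ensembles import EnsemblePrediction
from .grids import GridSpec


@dataclass
class BiasReport:
    """Smooth-regression R-squared values and the binned distance summary."""

    r2_prob: float
    r2_se: float
    bins_prob: pd.DataFrame
    bins_se: pd.DataFrame
    n_cells: int

    def summary(self) -> dict:
        return {"r2_prob": self.r2_prob, "r2_se": self.r2_se,
                "n_cells": self.n_cells}


def aggregate_layers(predictions: list[EnsemblePrediction]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Cellwise mean probability and mean SE across species ensembles."""
    if len(predictions) == 0:
        raise ValueError("need at least one species ensemble")
    shapes = {p.overall.shape for p in predictions}
    if len(shapes) != 1:
        raise ValueError("ensemble rasters disagree on grid shape")
    prob = np.mean(np.stack([p.overall for p in predictions]), axis=0)
    se = np.mean(np.stack([p.se for p in predictions]), axis=0)
    return prob, se


def distance_to_features(feature_mask: np.ndarray, cell_km: float = 1.0
                         ) -> np.ndarray:
    """Euclidean distance (km) from each cell centre to the nearest feature.

    Zero on feature cells themselves.
    """
    feature_mask = np.asarray(feature_mask, dtype=bool)
    if not feature_mask.any():
        raise ValueError("feature mask is empty")
    return ndimage.distance_transform_edt(~feature_mask) * cell_km


def _binned(distance: np.ndarray, values: np.ndarray, n_bins: int = 8
            ) -> pd.DataFrame:
    edges = np.linspace(distance.min(), distance.max(), n_bins + 1)
    idx = np.clip(np.digitize(distance, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        v = values[idx == b]
        finite = v[np.isfinite(v)]
        stats = (
            {"mean": float(finite.mean()),
             "q25": float(np.quantile(finite, 0.25)),
             "median": float(np.quantile(finite, 0.5)),
             "q75": float(np.quantile(finite, 0.75))}
            if finite.size else
            {"mean": np.nan, "q25": np.nan, "median": np.nan, "q75": np.nan})
        rows.append({"bin": b, "lo": edges[b], "hi": edges[b + 1],
                     "n": int(v.size), **stats})
    return pd.DataFrame(rows)


def bias_regression(aggregated_prob: np.ndarray, distance: np.ndarray,
                    aggregated_se: np.ndarray | None = None,
                    n_bins: int = 8, min_cells: int = 50,
                    subsample: int | None = None, seed: int = 0) -> BiasReport:
    """Regress aggregated layers on distance-to-development.

    Fits a penalized-spline smooth (GCV-chosen smoothness) of each
    aggregated layer on distance over all jointly valid cells and reports
    R-squared = 1 - SSE/SST (NaN when the response has zero variance),
    plus ``n_bins`` equal-width distance-bin summaries.  ``subsample``
    optionally caps the number of cells used in the smooth for speed.
    """
    prob = np.asarray(aggregated_prob, dtype=float).ravel()
    dist = np.asarray(distance, dtype=float).ravel()
    if aggregated_se is None:
        se = np.full_like(prob, np.nan)
    else:
        se = np.asarray(aggregated_se, dtype=float).ravel()
    ok = np.isfinite(prob) & np.isfinite(dist)
    if ok.sum() < min_cells:
        raise ValueError(f"need at least {min_cells} valid cells")
    prob, dist = prob[ok], dist[ok]
    se = se[ok]

    fit_idx = np.arange(prob.size)
    if subsample is not None and prob.size > subsample:
        rng = np.random.default_rng(seed)
        fit_idx = rng.choice(prob.size, size=subsample, replace=False)

    r2_prob = smooth_regression_1d(dist[fit_idx], prob[fit_idx]).r2
    if np.isfinite(se).all() and se.size:
        r2_se = smooth_regression_1d(dist[fit_idx], se[fit_idx]).r2
        bins_se = _binned(dist, se, n_bins)
    else:
        r2_se, bins_se = np.nan, _binned(dist, np.full_like(dist, np.nan),
                                         n_bins)
    return BiasReport(r2_prob=float(r2_prob), r2_se=float(r2_se),
                      bins_prob=_binned(dist, prob, n_bins),
                      bins_se=bins_se, n_cells=int(prob.size))
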