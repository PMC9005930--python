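"""Candidate selection, TSS-weighted ensembling, importance and curves.

Per algorithm family, the cross-validated variable subsets are filtered
(mean Boyce > 0, mean AUC > 0.5), ranked by mean TSS (AICc breaking
near-ties for the likelihood-based families) and the top ``n_keep``
retained as candidates with TSS-proportional weights.  The family
habitat map is the weighted cellwise mean of candidate run-mean maps;
the overall ensemble is the plain mean of the (up to three) family
maps, with an SE layer from the spread across all candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import CVResult, MetricSet

LIKELIHOOD_FAMILIES = ("smooth_additive", "maxent_like")


@dataclass
class CandidateSet:
    """Top-ranked evaluated specs for one family, with TSS weights."""

    algorithm_family: str
    candidates: list[CVResult]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.candidates) != self.weights.size:
            raise ValueError("weights must align with candidates")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class EnsemblePrediction:
    """Per-species ensemble habitat product."""

    species_id: str
    family_rasters: dict[str, np.ndarray]
    overall: np.ndarray
    se: np.ndarray
    threshold: float = np.nan      # species-level max-SSS threshold
    mean_metrics: MetricSet | None = None


def select_candidates(results: list[CVResult], n_keep: int = 10,
                      tss_tie: float = 0.01) -> CandidateSet:
    """Select and weight approximately ``n_keep`` well-performing models.

    Filters to mean Boyce > 0 and mean AUC > 0.5, ranks by mean TSS
    descending; for the likelihood-based families, models whose TSS is
    within ``tss_tie`` of each other are ordered by lower mean AICc.
    Weights are mean TSS normalized to sum 1.  If nothing survives the
    filters the single best-TSS model is kept with a warning.
    """
    if len(results) == 0:
        raise ValueError("no evaluated specs to select from")
    family = results[0].spec.algorithm_family
    ok = [r for r in results
          if np.isfinite(r.mean.boyce) and r.mean.boyce > 0
          and r.mean.auc > 0.5]
    if not ok:
        warnings.warn("no spec passed the Boyce/AUC filters; keeping the "
                      "single best-TSS model", stacklevel=2)
        best = max(results, key=lambda r: r.mean.tss)
        return CandidateSet(family, [best], np.array([1.0]))

    ranked = sorted(ok, key=lambda r: -r.mean.tss)
    if family in LIKELIHOOD_FAMILIES:
        # bubble near-ties (|dTSS| < tss_tie) toward lower AICc
        changed = True
        while changed:
            changed = False
            for i in range(len(ranked) - 1):
                a, b = ranked[i], ranked[i + 1]
                if (abs(a.mean.tss - b.mean.tss) < tss_tie
                        and np.isfinite(b.mean.aicc)
                        and (not np.isfinite(a.mean.aicc)
                             or b.mean.aicc < a.mean.aicc)):
                    ranked[i], ranked[i + 1] = b, a
                    changed = True
    kept = ranked[:n_keep]
    tss = np.array([max(r.mean.tss, 0.0) for r in kept])
    if tss.sum() <= 0:
        weights = np.full(len(kept), 1.0 / len(kept))
    else:
        weights = tss / tss.sum()
    return CandidateSet(family, kept, weights)


def predict_family_ensemble(cs: CandidateSet) -> np.ndarray:
    """TSS-weighted cellwise mean of the candidates' run-mean habitat maps."""
    stackd = np.stack([c.mean_prediction for c in cs.candidates])
    return np.tensordot(cs.weights, stackd, axes=1)


def se_layer(candidate_sets, mode: str = "se") -> np.ndarray:
    """Cellwise spread across all candidate predictions.

    ``mode='se'``: sample standard deviation across the m candidate maps
    divided by sqrt(m) (the error of the ensemble mean); ``mode='sd'``:
    the plain standard deviation.  A single candidate yields a zero
    layer with a warning.
    """
    if isinstance(candidate_sets, CandidateSet):
        candidate_sets = [candidate_sets]
    preds = [c.mean_prediction for cs in candidate_sets for c in cs.candidates]
    if len(preds) == 0:
        raise ValueError("no candidates")
    if len(preds) == 1:
        warnings.warn("single candidate; SE layer is identically zero",
                      stacklevel=2)
        return np.zeros_like(preds[0])
    arr = np.stack(preds)
    sd = arr.std(axis=0, ddof=1)
    if mode == "sd":
        return sd
    if mode != "se":
        raise ValueError("mode must be 'se' or 'sd'")
    return sd / np.sqrt(arr.shape[0])


def overall_ensemble(family_rasters: dict[str, np.ndarray] | list[np.ndarray]
                     ) -> np.ndarray:
    """Unweighted cellwise mean of the per-family ensemble rasters."""
    if isinstance(family_rasters, dict):
        rasters = list(family_rasters.values())
    else:
        rasters = list(family_rasters)
    if len(rasters) == 0:
        raise ValueError("no family rasters")
    shape = rasters[0].shape
    for r in rasters:
        if r.shape != shape:
            raise ValueError("family rasters disagree on grid shape")
    return np.mean(np.stack(rasters), axis=0)


def relative_importance(candidate_sets: list[CandidateSet],
                        codes: list[str] | None = None) -> pd.Series:
    """Cross-family relative importance, normalized to sum 100.

    Per family, each covariate's raw importance is the mean of its
    per-candidate importance (edf for the smooth additive family,
    permutation metrics for the others) over the candidates in which it
    appears; codes absent from every candidate of a family get 0.  Each
    family's vector is normalized to sum 100, the vectors are averaged
    across families, and the result renormalized to 100.
    """
    if codes is None:
        codes = sorted({c for cs in candidate_sets
                        for r in cs.candidates for c in r.mean_importance})
    fam_rows = []
    for cs in candidate_sets:
        raw = {}
        for code in codes:
            vals = [r.mean_importance[code] for r in cs.candidates
                    if code in r.mean_importance]
            raw[code] = float(np.mean(vals)) if vals else 0.0
        v = pd.Series(raw, index=codes, dtype=float)
        total = v.sum()
        if total <= 0:
            raise ValueError(
                f"all-zero importances for family {cs.algorithm_family!r}")
        fam_rows.append(100.0 * v / total)
    combined = pd.concat(fam_rows, axis=1).mean(axis=1)
    return 100.0 * combined / combined.sum()


def response_curves(candidate_sets: list[CandidateSet],
                    importance: pd.Series | None = None,
                    top_k: int = 9) -> dict[str, pd.DataFrame]:
    """Model-averaged response curves for the top predictors.

    For each of the ``top_k`` most important covariates, the candidates'
    stored per-run-mean response sweeps are averaged (TSS-weighted)
    within each family and pooled across families on a common covariate
    grid.  Returns a mapping code -> DataFrame with columns ``value``,
    one column per family, and ``pooled``.
    """
    if importance is None:
        importance = relative_importance(candidate_sets)
    # zero-importance codes are exactly those absent from every candidate
    ranked = importance[importance > 0].sort_values(ascending=False)
    top = list(ranked.index[:top_k])
    out = {}
    for code in top:
        fam_cols = {}
        grid_ref = None
        for cs in candidate_sets:
            parts, wts = [], []
            for r, w in zip(cs.candidates, cs.weights):
                if code in r.curves:
                    g, curve = r.curves[code]
                    grid_ref = g if grid_ref is None else grid_ref
                    parts.append(np.interp(grid_ref, g, curve))
                    wts.append(w)
            if parts:
                wts = np.asarray(wts) / np.sum(wts)
                fam_cols[cs.algorithm_family] = np.tensordot(
                    wts, np.stack(parts), axes=1)
        if not fam_cols:
            raise ValueError(f"covariate {code!r} absent from every candidate")
        df = pd.DataFrame({"value": grid_ref, **fam_cols})
        df["pooled"] = df[list(fam_cols)].mean(axis=1)
        out[code] = df
    return out
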