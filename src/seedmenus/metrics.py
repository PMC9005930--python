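"""Discrimination/calibration metrics and the cross-validation harness.

Metrics: rank-based AUC (Mann-Whitney), the true skill statistic at a
threshold, the threshold maximizing sensitivity + specificity, the
continuous Boyce index, and small-sample-corrected AIC for the
likelihood-based learners.  :func:`cross_validate` wires them into the
repeated presence-thinning / pseudo-absence / holdout evaluation loop
used to score every candidate variable subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .algorithms import FAMILY_FITTERS, make_training_data
from .algorithms.forest import ForestModel
from .algorithms.maxent import MaxentModel
from .algorithms.smooth import PenalizedAdditiveModel
from .occurrences import sample_pseudo_absences, thin_presences


def derive_seed(master: int, *keys: int) -> int:
    """Deterministic child seed from a master seed and integer keys."""
    ss = np.random.SeedSequence([int(master) % (2 ** 31)] + [int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def auc(pos_scores, neg_scores) -> float:
    """Area under the ROC curve via the Mann-Whitney pair statistic.

    Equals (wins + 0.5 * ties) / (n_pos * n_neg) over all presence /
    absence score pairs; tie-exact through midranks.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class MetricSet:
    """One evaluation's metric bundle.

    ``tss = sensitivity + specificity - 1`` at ``threshold_used``; ``aicc``
    is NaN for learners without a likelihood.
    """

    auc: float = np.nan
    tss: float = np.nan
    boyce: float = np.nan
    aicc: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    threshold_used: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("auc", "tss", "boyce", "aicc", "sensitivity", "specificity",
                 "threshold_used")}


def tss_at(labels, scores, threshold: float) -> MetricSet:
    """Sensitivity, specificity and TSS classifying ``score >= threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be within [0, 1]")
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    pred = scores >= threshold
    sens = float(pred[pos].mean())
    spec = float((~pred[neg]).mean())
    return MetricSet(sensitivity=sens, specificity=spec,
                     tss=sens + spec - 1.0, threshold_used=float(threshold))


def max_sss_threshold(labels, scores) -> tuple[float, float]:
    """Threshold maximizing sensitivity + specificity, and the TSS there.

    Scans the midpoints between adjacent sorted unique scores plus the
    endpoints {0, 1}; among maximizers the smallest threshold is returned.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    cands = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    cands = np.unique(np.clip(cands, 0.0, 1.0))
    best_t, best_tss = 0.0, -np.inf
    for t in cands:
        m = tss_at(labels, scores, t)
        if m.tss > best_tss + 1e-12:
            best_t, best_tss = float(t), float(m.tss)
    return best_t, best_tss


def boyce_index(presence_suitability, background_suitability,
                n_windows: int = 101, window_width: float = 0.1,
                bins: str = "width") -> float:
    """Continuous Boyce index.

    Moving windows across [0, 1] (``bins='width'``: ``n_windows`` windows
    of fixed ``window_width``; ``bins='quantile'``: ``n_windows``
    contiguous background-quantile bins).  Per window the
    predicted-to-expected ratio P/E = (fraction of presences in window) /
    (fraction of background in window) is computed, zero-background
    windows are skipped, and the Spearman rank correlation between window
    midpoint and P/E is returned.
    """
    p = np.asarray(presence_suitability, dtype=float)
    b = np.asarray(background_suitability, dtype=float)
    if b.size == 0:
        raise ValueError("background must be non-empty")
    if np.any((p < 0) | (p > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("suitabilities must lie in [0, 1]")
    if bins == "width":
        lows = np.linspace(0.0, 1.0 - window_width, n_windows)
        highs = lows + window_width
    elif bins == "quantile":
        qs = np.quantile(b, np.linspace(0, 1, n_windows + 1))
        lows, highs = qs[:-1], qs[1:]
    else:
        raise ValueError("bins must be 'width' or 'quantile'")
    mids, ratios = [], []
    for i, (lo, hi) in enumerate(zip(lows, highs)):
        last = i == len(lows) - 1
        in_p = (p >= lo) & ((p < hi) | (last & (p <= hi)))
        in_b = (b >= lo) & ((b < hi) | (last & (b <= hi)))
        nb = in_b.sum()
        if nb == 0:
            continue
        mids.append((lo + hi) / 2.0)
        ratios.append((in_p.mean()) / (nb / b.size))
    if len(mids) < 3:
        raise ValueError("fewer than 3 usable windows")
    if np.std(ratios) == 0:  # constant P/E carries no rank signal
        return 0.0
    rho = stats.spearmanr(mids, ratios).statistic
    return float(rho)


def aicc(model, presence: pd.DataFrame | None = None,
         background: pd.DataFrame | None = None) -> float:
    """Small-sample-corrected AIC for a fitted learner.

    * maxent-like: log likelihood is the sum over presences of the log
      raw output normalized over ``background``; K is the number of
      non-zero coefficients; n the number of presences.
    * smooth additive: binomial deviance-based AIC with total edf as K
      and the fitting sample size as n.
    * tree ensemble: no likelihood — returns NaN (n/a marker).

    Returns +inf when n <= K + 1 (degenerate correction), flagging the
    model for exclusion from ranking.
    """
    if isinstance(model, ForestModel):
        return float("nan")
    if isinstance(model, MaxentModel):
        if presence is None:
            raise ValueError("presence table required for maxent AICc")
        vars_ = list(model.variables)
        eta_p = model._eta(presence[vars_])
        if background is not None:
            eta_b = model._eta(background[vars_])
            m = eta_b.max()
            log_z = m + np.log(np.exp(eta_b - m).sum())
        else:
            log_z = model.log_z
        lnl = float((eta_p - log_z).sum())
        k = float(model.parameter_count())
        n = len(presence)
    elif isinstance(model, PenalizedAdditiveModel):
        k = float(model.parameter_count())
        n = model.n_obs
        lnl = -model.deviance / 2.0
    else:
        raise TypeError(f"unsupported model type {type(model)!r}")
    if k < 1:
        k = 1.0
    if n <= k + 1:
        return float("inf")
    return 2.0 * k - 2.0 * lnl + 2.0 * k * (k + 1.0) / (n - k - 1.0)


# --------------------------------------------------------------------------
# cross-validation harness
# --------------------------------------------------------------------------

@dataclass
class SpeciesData:
    """Prepared modelling inputs for one species."""

    species_id: str
    stack: object                 # CovariateStack
    presence_cells: np.ndarray    # QC'd + rasterized, not yet thinned
    lifespan: str = "perennial"

    def __post_init__(self) -> None:
        self.presence_cells = np.asarray(self.presence_cells, dtype=np.int64)


@dataclass
class CVResult:
    """Cross-validated summary for one variable subset."""

    spec: object
    runs: pd.DataFrame
    mean: MetricSet
    mean_prediction: np.ndarray | None = None     # (nrows, ncols)
    mean_importance: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)    # code -> (grid, mean curve)
    n_runs: int = 0


def _holdout_split(n: int, holdout: float, rng) -> np.ndarray:
    """Boolean holdout mask with at least one held-out and one kept row."""
    n_hold = int(np.clip(round(n * holdout), 1, n - 1))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=n_hold, replace=False)] = True
    return mask


def _fit_one(spec, stack, train_presence, train_absence, fit_kwargs, run_seed):
    family = spec.algorithm_family
    codes = list(spec.variables)
    if family == "maxent_like":
        presence_tbl = stack.table(cells=train_presence, codes=codes)
        background_tbl = stack.table(cells=train_absence, codes=codes)
        model = FAMILY_FITTERS[family](spec, presence_tbl, background_tbl,
                                       seed=run_seed, **fit_kwargs)
        return model, presence_tbl, background_tbl
    balance = family == "smooth_additive"
    data = make_training_data(stack, train_presence, train_absence, codes,
                              balance_weights=balance)
    model = FAMILY_FITTERS[family](spec, data, seed=run_seed, **fit_kwargs)
    return model, data.table.iloc[:len(train_presence)], \
        data.table.iloc[len(train_presence):]


def cross_validate(spec, species: SpeciesData, n_runs: int = 50,
                   holdout: float = 0.2, seed: int = 0,
                   thin_block_km: float = 10.0, thin_max_per_block: int = 3,
                   n_absence_override: int | None = None,
                   fit_kwargs: dict | None = None,
                   collect_prediction: bool = True,
                   collect_importance: bool = True,
                   collect_curves: bool = True, curve_grid_size: int = 100,
                   max_retries: int = 5) -> CVResult:
    """Evaluate one variable subset across repeated replicates.

    Each run draws a fresh spatially thinned presence set and a fresh
    pseudo-absence sample (seeded from ``seed`` and the run id), holds
    out a stratified ``holdout`` fraction of both classes, fits on the
    remainder and evaluates on the holdout: AUC, TSS at the max-SSS
    threshold, the Boyce index against the run's background, and AICc
    from the training fit.  Optionally accumulates the run-mean habitat
    map, permutation/edf importances and per-variable response curves.
    """
    fit_kwargs = dict(fit_kwargs or {})
    stack = species.stack
    grid = stack.grid
    family = spec.algorithm_family
    codes = list(spec.variables)
    valid = stack.valid_cells
    full_table = stack.table(cells=valid, codes=codes) if (
        collect_prediction) else None

    curve_grids = {}
    if collect_curves:
        for c in codes:
            vals = stack.layers[c].ravel()[valid]
            curve_grids[c] = np.linspace(np.nanmin(vals), np.nanmax(vals),
                                         curve_grid_size)

    rows = []
    pred_sum = np.zeros(valid.size) if collect_prediction else None
    imp_sum: dict[str, float] = {c: 0.0 for c in codes}
    curve_sum = {c: np.zeros(curve_grid_size) for c in curve_grids}
    n_ok = 0

    for run in range(n_runs):
        for attempt in range(max_retries):
            run_seed = derive_seed(seed, run, attempt)
            rng = np.random.default_rng(derive_seed(seed, run, attempt, 1))
            thinned = thin_presences(species.presence_cells, grid,
                                     block_km=thin_block_km,
                                     max_per_block=thin_max_per_block,
                                     seed=derive_seed(seed, run, attempt, 2))
            import warnings as _warnings
            with _warnings.catch_warnings():
                # the cap-to-available warning repeats every run at desk
                # scale; it is unit-tested where it matters
                _warnings.simplefilter("ignore", UserWarning)
                absences = sample_pseudo_absences(
                    stack, thinned, family, n_override=n_absence_override,
                    seed=derive_seed(seed, run, attempt, 3))
            hold_p = _holdout_split(thinned.size, holdout, rng)
            hold_a = _holdout_split(absences.size, holdout, rng)
            train_p, test_p = thinned[~hold_p], thinned[hold_p]
            train_a, test_a = absences[~hold_a], absences[hold_a]
            if test_p.size and test_a.size and train_p.size and train_a.size:
                break
        else:
            raise RuntimeError("could not draw a two-class holdout")

        model, train_ptbl, train_btbl = _fit_one(
            spec, stack, train_p, train_a, fit_kwargs, run_seed)

        s_p = model.predict(stack.table(cells=test_p, codes=codes))
        s_a = model.predict(stack.table(cells=test_a, codes=codes))
        labels = np.concatenate([np.ones(s_p.size), np.zeros(s_a.size)])
        scores = np.concatenate([s_p, s_a])
        thr, tss = max_sss_threshold(labels, scores)
        frag = tss_at(labels, scores, thr)
        bg_scores = model.predict(stack.table(cells=absences, codes=codes))
        try:
            boyce = boyce_index(s_p, bg_scores)
        except ValueError:
            boyce = np.nan
        a = aicc(model, presence=train_ptbl, background=train_btbl)
        rows.append({"run": run, "auc": auc(s_p, s_a), "tss": tss,
                     "boyce": boyce, "aicc": a,
                     "sensitivity": frag.sensitivity,
                     "specificity": frag.specificity, "threshold_used": thr})

        if collect_prediction:
            pred_sum += model.predict(full_table)
        if collect_importance:
            for c, v in model.term_importance().items():
                imp_sum[c] = imp_sum.get(c, 0.0) + float(v)
        if collect_curves:
            for c in codes:
                g = curve_grids[c]
                if isinstance(model, ForestModel):
                    curve_sum[c] += model.partial_dependence(c, g)
                else:
                    base = {cc: np.full(g.size,
                                        float(train_btbl[cc].mean()))
                            for cc in codes}
                    base[c] = g
                    curve_sum[c] += model.predict(pd.DataFrame(base))
        n_ok += 1

    runs = pd.DataFrame(rows)
    with np.errstate(invalid="ignore"):
        mean = MetricSet(
            auc=float(runs["auc"].mean()), tss=float(runs["tss"].mean()),
            boyce=float(runs["boyce"].mean(skipna=True)),
            aicc=float(runs["aicc"].replace(np.inf, np.nan).mean(skipna=True)),
            sensitivity=float(runs["sensitivity"].mean()),
            specificity=float(runs["specificity"].mean()),
            threshold_used=float(runs["threshold_used"].mean()))

    mean_pred = None
    if collect_prediction:
        mean_pred = np.full(grid.shape, np.nan)
        mean_pred.ravel()[valid] = pred_sum / n_ok
    curves = {c: (curve_grids[c], curve_sum[c] / n_ok) for c in curve_grids}
    return CVResult(spec=spec, runs=runs, mean=mean, mean_prediction=mean_pred,
                    mean_importance={c: imp_sum[c] / n_ok for c in imp_sum},
                    curves=curves, n_runs=n_ok)
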