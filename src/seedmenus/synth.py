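"""Synthetic landscapes, virtual species, occurrence samples and traits.

Real ensemble habitat modelling starts from occurrence databases and
regional covariate rasters; everything here generates stand-ins with a
*known* ground truth so the pipeline can be exercised and validated end
to end:

* spatially autocorrelated covariate fields (smoothed Gaussian noise)
  with exact, user-requested pairwise correlations;
* virtual species whose occurrence probability follows a logistic
  response to a chosen covariate subset;
* occurrence records sampled from that probability surface, optionally
  distorted toward easily-accessed cells to emulate roadside sampling
  bias;
* a compact trait table emulating the attribute columns a priority
  species list contributes to a seed menu.

The module also bundles, verbatim, the published per-species performance
and covariate-importance table for the 49 Mojave Desert restoration
species (:func:`load_table2_fixture`) as a results fixture.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import COVARIATE_CODES, CovariateStack, GridSpec
from .occurrences import OccurrenceSet

TABLE2_SHA256 = "527897866ed46d647d4f1cb28753e98dbb4a432565f149057578edad9b3ffa5c"

#: Importance columns of the packaged results fixture, in printed order.
TABLE2_IMPORTANCE_COLUMNS = (
    "AHM", "CMD", "WP", "SP", "Tmax", "Tmin", "Trange",
    "HLI", "Slope", "TPI", "Text", "AMP_MAXN", "SWS",
)


# --------------------------------------------------------------------------
# landscape generation
# --------------------------------------------------------------------------

def make_landscape(nrows: int, ncols: int, cell_km: float = 1.0,
                   n_covariates: int = 14, autocorrelation_range: float = 10.0,
                   correlation_pairs: list[tuple[str, str, float]] | None = None,
                   seed: int = 0, codes: list[str] | None = None) -> CovariateStack:
    """Generate a stack of spatially autocorrelated covariate layers.

    Each layer is Gaussian white noise smoothed with a Gaussian kernel
    whose radius (sigma, in cells) is ``autocorrelation_range``, then
    standardised to zero mean / unit variance over the grid.  Layers are
    empirically whitened before target correlations are imposed by linear
    mixing, so any requested pairwise Pearson r is achieved essentially
    exactly (well within +-0.1).

    Raises ``ValueError`` for duplicate codes or when the requested
    correlation pairs do not form a positive semi-definite correlation
    matrix.
    """
    if nrows < 8 or ncols < 8:
        if not (nrows >= 4 and ncols >= 4 and n_covariates <= 2):
            # tiny grids are permitted only for degenerate smoke cases
            raise ValueError("grid must be at least 8 x 8")
    if codes is None:
        if not 1 <= n_covariates <= len(COVARIATE_CODES):
            raise ValueError(
                f"n_covariates must be between 1 and {len(COVARIATE_CODES)}")
        codes = list(COVARIATE_CODES[:n_covariates])
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate covariate codes")
    unknown = set(codes) - set(COVARIATE_CODES)
    if unknown:
        raise ValueError(f"unknown covariate codes: {sorted(unknown)}")
    k = len(codes)

    target = np.eye(k)
    for a, b, r in (correlation_pairs or []):
        if a not in codes or b not in codes:
            raise ValueError(f"correlation pair ({a}, {b}) uses unknown code")
        i, j = codes.index(a), codes.index(b)
        target[i, j] = target[j, i] = float(r)
    # positive definiteness check (semi-definite boundary rejected too:
    # mixing needs a Cholesky factor)
    try:
        L = np.linalg.cholesky(target)
    except np.linalg.LinAlgError as exc:
        raise ValueError("requested correlations are not achievable "
                         "(matrix not positive definite)") from exc

    rng = np.random.default_rng(seed)
    n = nrows * ncols
    fields = np.empty((k, n))
    for i in range(k):
        white = rng.standard_normal((nrows, ncols))
        smooth = ndimage.gaussian_filter(white, sigma=autocorrelation_range,
                                         mode="reflect")
        fields[i] = smooth.ravel()
    # centre, then empirically whiten so the imposed mixing is exact
    fields -= fields.mean(axis=1, keepdims=True)
    cov = fields @ fields.T / n
    Lc = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
    white_fields = np.linalg.solve(Lc, fields)
    mixed = L @ white_fields
    mixed /= mixed.std(axis=1, keepdims=True)

    layers = {c: mixed[i].reshape(nrows, ncols) for i, c in enumerate(codes)}
    grid = GridSpec(nrows=nrows, ncols=ncols, cell_km=cell_km)
    return CovariateStack(grid, layers)


def make_road_mask(grid: GridSpec, n_roads: int = 3, seed: int = 0) -> np.ndarray:
    """Boolean raster of synthetic linear 'developed' features.

    Draws ``n_roads`` straight lines (random orientation and offset)
    through the grid, one cell wide, emulating a road network for the
    sampling-bias diagnostic.
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros(grid.shape, dtype=bool)
    for _ in range(n_roads):
        if rng.random() < 0.5:  # roughly horizontal
            r0 = rng.integers(0, grid.nrows)
            drift = rng.uniform(-0.5, 0.5)
            cols = np.arange(grid.ncols)
            rows = np.clip(np.round(r0 + drift * cols).astype(int), 0,
                           grid.nrows - 1)
        else:
            c0 = rng.integers(0, grid.ncols)
            drift = rng.uniform(-0.5, 0.5)
            rows = np.arange(grid.nrows)
            cols = np.clip(np.round(c0 + drift * rows).astype(int), 0,
                           grid.ncols - 1)
        mask[rows, cols] = True
    return mask


# --------------------------------------------------------------------------
# virtual species
# --------------------------------------------------------------------------

@dataclass
class VirtualSpecies:
    """A simulated species with a known logistic habitat response."""

    species_id: str
    response_vars: list[str]
    coefficients: np.ndarray
    intercept: float
    true_probability: np.ndarray  # (nrows, ncols), NaN on masked cells
    grid: GridSpec


def make_virtual_species(stack: CovariateStack, response_vars: list[str],
                         coefficients, intercept: float = 0.0,
                         species_id: str = "virtual") -> VirtualSpecies:
    """Define a virtual species by a logistic response to stack layers.

    ``true_probability = expit(intercept + sum_j beta_j * layer_j)`` at
    every non-masked cell.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if len(response_vars) != coefficients.size:
        raise ValueError("response_vars and coefficients differ in length")
    for code in response_vars:
        if code not in stack:
            raise ValueError(f"unknown covariate code {code!r}")
    eta = np.full(stack.grid.shape, float(intercept))
    for code, beta in zip(response_vars, coefficients):
        eta = eta + beta * stack.layers[code]
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(-eta))
    prob[~stack.mask] = np.nan
    return VirtualSpecies(species_id=species_id,
                          response_vars=list(response_vars),
                          coefficients=coefficients, intercept=float(intercept),
                          true_probability=prob, grid=stack.grid)


# --------------------------------------------------------------------------
# occurrence sampling
# --------------------------------------------------------------------------

def sample_occurrences(vs: VirtualSpecies, n_target: int,
                       access_bias_strength: float = 0.0,
                       access_raster: np.ndarray | None = None,
                       uncertainty_km_distribution: tuple[float, float] = (0.3, 0.2),
                       seed: int = 0, source: str = "synthetic") -> OccurrenceSet:
    """Sample occurrence records from a virtual species.

    Cells are drawn (with replacement — records are independent point
    observations; rasterisation later dedups cells) with probability
    proportional to ``true_probability * exp(access_bias_strength *
    access_score)``.  Record coordinates are jittered uniformly within the
    cell and positional uncertainties drawn from a truncated normal.
    """
    if n_target < 1:
        raise ValueError("n_target must be at least 1")
    if access_bias_strength > 0 and access_raster is None:
        raise ValueError("access raster required when bias strength > 0")
    grid = vs.grid
    p = np.nan_to_num(vs.true_probability.ravel(), nan=0.0).astype(float)
    if access_bias_strength > 0:
        score = np.asarray(access_raster, dtype=float).ravel()
        w = p * np.exp(access_bias_strength * score)
    else:
        w = p.copy()
    total = w.sum()
    if total <= 0:
        raise ValueError("no non-masked cell has positive probability")
    rng = np.random.default_rng(seed)
    cells = rng.choice(grid.n_cells, size=n_target, replace=True, p=w / total)
    rows, cols = grid.rowcol_from_flat(cells)
    cx, cy = grid.cell_center(rows, cols)
    x = cx + rng.uniform(-0.5, 0.5, size=n_target) * grid.cell_km
    y = cy + rng.uniform(-0.5, 0.5, size=n_target) * grid.cell_km
    mu, sd = uncertainty_km_distribution
    unc = np.abs(rng.normal(mu, sd, size=n_target))
    records = pd.DataFrame({
        "species_id": vs.species_id, "x": x, "y": y,
        "uncertainty_km": unc, "source": source,
    })
    return OccurrenceSet(species_id=vs.species_id, records=records)


def truth_holdout_auc(vs: VirtualSpecies, suitability: np.ndarray,
                      n: int = 2000, seed: int = 0) -> float:
    """Held-out AUC of a suitability map against the generator's truth.

    Draws a fresh evaluation sample from the known occurrence process —
    presence cells with probability proportional to ``true_probability``
    and absence cells proportional to its complement — and scores the
    supplied map's discrimination between them.  Only a synthetic
    species admits this ground-truth evaluation; it is independent of
    any sample used for fitting.
    """
    from .metrics import auc as _auc
    p = np.nan_to_num(vs.true_probability.ravel(), nan=0.0)
    q = np.nan_to_num(1.0 - vs.true_probability.ravel(), nan=0.0)
    rng = np.random.default_rng(seed)
    pres = rng.choice(p.size, size=n, replace=True, p=p / p.sum())
    absn = rng.choice(q.size, size=n, replace=True, p=q / q.sum())
    s = np.asarray(suitability).ravel()
    ok_p = np.isfinite(s[pres])
    ok_a = np.isfinite(s[absn])
    return _auc(s[pres][ok_p], s[absn][ok_a])


# --------------------------------------------------------------------------
# trait table
# --------------------------------------------------------------------------

_GROWTH_FORMS = ("shrub", "forb", "grass", "cactus", "tree")
_LIFESPANS = ("annual", "perennial")
_PROPAGATION = ("seed", "container stock", "cuttings", "bareroot")
_MONTHS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")

TRAIT_COLUMNS = (
    "growth_form", "lifespan", "bloom_months", "pollinator_count",
    "larval_host", "adult_host", "tortoise_forage", "tortoise_cover",
    "known_colonizer", "propagation_method",
)


def make_trait_table(species_ids: list[str], seed: int = 0) -> pd.DataFrame:
    """Generate a restoration-trait table with one row per species.

    Columns cover growth form, lifespan, bloom phenology, pollinator
    counts, larval/adult pollinator host status, tortoise forage/cover
    value, disturbance-colonizer status and propagation method — the
    attribute families a priority species list contributes to seed-menu
    outputs.  Values are drawn from small categorical sets; deterministic
    for a given (ids, seed).
    """
    if len(species_ids) == 0:
        raise ValueError("species id list must be non-empty")
    if len(set(species_ids)) != len(species_ids):
        raise ValueError("duplicate species ids")
    rng = np.random.default_rng(seed)
    rows = []
    for sid in species_ids:
        start = int(rng.integers(0, 11))
        span = int(rng.integers(1, 4))
        bloom = "-".join([_MONTHS[start], _MONTHS[min(start + span, 11)]])
        rows.append({
            "species_id": sid,
            "growth_form": _GROWTH_FORMS[rng.integers(0, len(_GROWTH_FORMS))],
            "lifespan": _LIFESPANS[rng.integers(0, 2)],
            "bloom_months": bloom,
            "pollinator_count": int(rng.integers(0, 40)),
            "larval_host": bool(rng.random() < 0.3),
            "adult_host": bool(rng.random() < 0.6),
            "tortoise_forage": bool(rng.random() < 0.5),
            "tortoise_cover": bool(rng.random() < 0.4),
            "known_colonizer": bool(rng.random() < 0.35),
            "propagation_method": _PROPAGATION[rng.integers(0, len(_PROPAGATION))],
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# packaged results fixture
# --------------------------------------------------------------------------

def load_table2_fixture() -> pd.DataFrame:
    """Load the packaged 49-species performance/importance table.

    Returns the published per-species sample sizes, ensemble AUC and TSS,
    and the 14 relative-importance columns, exactly as printed.  The
    packaged CSV is integrity-checked against a recorded SHA-256 before
    parsing; a mismatch raises ``ValueError``.
    """
    raw = (resources.files("seedmenus") / "data" / "table2.csv").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE2_SHA256:
        raise ValueError("packaged results fixture failed its checksum")
    df = pd.read_csv(StringIO(raw.decode("utf-8")))
    if len(df) != 49:
        raise ValueError("results fixture must have exactly 49 rows")
    return df


def table2_summary(df: pd.DataFrame | None = None) -> dict[str, float]:
    """Headline statistics of the packaged results fixture.

    Mean/min/max discrimination scores, the mean summer-precipitation
    importance, and the number of species whose summed temperature
    importance (Tmax + Tmin + Trange) exceeds summed precipitation
    importance (WP + SP).
    """
    if df is None:
        df = load_table2_fixture()
    temp = df[["Tmax", "Tmin", "Trange"]].sum(axis=1)
    prec = df[["WP", "SP"]].sum(axis=1)
    return {
        "n_species": int(len(df)),
        "mean_auc": float(df["AUC"].mean()),
        "mean_tss": float(df["TSS"].mean()),
        "min_auc": float(df["AUC"].min()),
        "max_auc": float(df["AUC"].max()),
        "mean_sp_importance": float(df["SP"].mean()),
        "n_temperature_dominant": int((temp > prec).sum()),
    }
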