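# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the places where the design was genuinely open.

## The modelling problem

Inputs are presence-only occurrence records for each species, a stack
of environmental covariate rasters on a shared 1-km grid, and a species
trait table. The product is, per species, a habitat-probability raster
in [0, 1] with a standard-error layer; across species, trait-annotated
site-specific species lists ("seed menus") and a coverage map.

Covariates use the standard regional vocabulary: summer/winter
precipitation (SP, WP), temperature extremes and range (Tmax, Tmin,
Trange), annual heat:moisture index (AHM = (MAT + 10)/(MAP/1000), MAT
in °C, MAP in mm), climatic moisture deficit (CMD), NDVI amplitude and
maximum (AMP, MAXN), soil water stress (SWS), surface texture (ATI;
printed as "Text" in the packaged results table), heat load index
(HLI), slope, and topographic position index (TPI). Only AHM has a
closed formula; all others are consumed as supplied rasters. TPI is
treated as an opaque input layer. AMP and MAXN are mutually exclusive
by species lifespan: MAXN enters models for perennials, AMP for
annuals.

## Occurrence preparation

* QC drops records with reported positional uncertainty > 1 km
  (records with *missing* uncertainty are kept), records on
  water/masked cells, and records outside the grid, with per-rule
  counts reported.
* Records collapse to unique presence cells at grid resolution.
* Spatial thinning partitions the grid into 10 km x 10 km blocks
  anchored at the raster origin and keeps at most 3 presence cells per
  block, drawn uniformly. "10 km² area" is read as a 10-km block side
  — the usual grid-sampling interpretation at landscape scale; the
  alternative (3.16-km squares) is configurable via `thin_block_km`.
* Pseudo-absences: 10,000 uniform cells for the smooth additive family
  (excluded from presences, down-weighted so total absence weight
  equals presence weight) and for the maxent-like background (presences
  *not* excluded); one absence per presence for the forest. Requests
  above the candidate pool are capped with a warning — on desk-scale
  grids the cap always binds, making the background "all valid cells".

## Model space

All covariate subsets of size 1..6 are enumerated, excluding any
subset containing a pair with |Pearson r| > 0.7 over jointly valid
cells (14 free covariates → 6,475 subsets; one forbidden pair →
5,681). The same correlation screen applies to all three families. A
seeded uniform subsample (`spec_cap`) keeps desk-scale runs tractable;
the subsample is drawn once per species and shared by the families.

## The three learners

All satisfy one contract: `predict` in [0, 1], deterministic under
(data, seed), per-term complexity/importance, serializable.

**Penalized additive smooths.** Binomial GAM with one univariate cubic
P-spline per covariate (10 basis functions, second-difference penalty)
fit by penalized IRLS. Each term's penalty adds a ridge on the
difference-penalty null space scaled by the same smoothing parameter,
so λ → ∞ removes the term entirely (shrink-to-zero selection); a
term's effective degrees of freedom (edf) is tr of its block of
(XᵀWX + S)⁻¹XᵀWX. Per-term λ is chosen by cyclic grid search
(log-spaced 10⁻²..10⁶, 7 points, one cycle) minimizing UBRE
(deviance + 2·edf). REML was not implemented; UBRE gives the same
qualitative shrink-to-zero behaviour at a fraction of the cost and the
selection criterion is not contract-visible.

**Random forest.** scikit-learn classification forest (default 1000
trees; desk profiles use fewer), suitability = presence-class vote
fraction. Importance is the mean decrease in 0.5-threshold accuracy
under per-variable permutation (3 repeats, seeded). Response curves use
data-averaged partial dependence over a 50-row seeded background
subsample.

**Maximum entropy.** Log-linear intensity over a feature expansion —
linear, quadratic, pairwise products, and forward/reverse hinges at 10
interior quantile knots per variable, all scaled to [0, 1] — fit as an
L1-regularized logistic discrimination of presences against background
(liblinear, C = 1/regularization-multiplier, default 1). The raw
output normalizes exp(βᵀf(x)) to sum to 1 over the fitting background;
the logistic output rescales with c = e^H (H = entropy of the raw
distribution). Parameter count = coefficients with |β| > 1e−8;
importance = drop in training presence/background AUC under
per-variable permutation. This is a from-scratch implementation of the
published maximum-entropy SDM formulation, not a wrapper.

## Evaluation

* AUC is the tie-corrected Mann–Whitney statistic (rank-based).
* TSS is reported at the threshold maximizing sensitivity +
  specificity, scanned over midpoints of adjacent unique scores plus
  {0, 1}, smallest maximizer wins. The threshold used for TSS is not
  dictated by the workflow being reproduced; max-SSS is the standard
  choice and matches the app-facing threshold option.
* Continuous Boyce index: 101 moving windows of width 0.1 (fixed-width
  default; quantile bins available), P/E per window with
  zero-background windows skipped, Spearman correlation of window
  midpoint vs P/E. A constant P/E profile returns 0.
* AICc: maxent-like, lnL = Σ ln(raw) over presences with raw
  normalized on the training background, K = non-zero coefficients,
  n = presences; smooth additive, deviance-based AIC with total edf as
  K and fitting rows as n; +∞ when n ≤ K + 1; forests have no
  likelihood (NaN).
* Cross-validation: each run draws a fresh thinned presence set and
  fresh pseudo-absences (child seeds derived from the master seed and
  run id via `SeedSequence`), withholds a stratified 20% of each class
  (at least one row per side), fits on the remainder and evaluates on
  the holdout. Runs whose holdout would be single-class are redrawn
  (bounded retries). Per-candidate habitat maps, importances and
  response sweeps are accumulated as run means during CV, so no fitted
  model needs to be retained.

## Ensembling

Candidates per family: filter mean Boyce > 0 and mean AUC > 0.5, rank
by mean TSS, break |ΔTSS| < 0.01 ties by lower mean AICc for the two
likelihood families, keep the top ~10 (configurable), weight by
TSS/ΣTSS. If nothing passes the filters the single best-TSS model is
kept with a warning. The published workflow lists the metrics but not
the decision rule; this committed rule is fully configurable. The
family map is the weighted cellwise mean of candidate run-mean maps;
the overall map is the unweighted mean of family maps. The SE layer is
the cellwise sample SD across *all* candidates divided by √m (the
error of the ensemble mean; plain SD via `se_mode="sd"`). Importance:
per family, mean raw importance over the candidates containing the
code (0 if absent from all), normalized to 100 per family, averaged
across families, renormalized — this normalize-then-average recipe
reproduces rows summing to ~100 as printed in the packaged table.
Response curves: per-candidate sweeps (others fixed at training means;
partial dependence for forests) averaged TSS-weighted within family
and pooled across families for the top nine predictors.

## Seed menus

Point sites read their containing cell; polygon sites summarise valid
cells whose centres fall inside (mean by default; min gives the
conservative variant — the deployed tool's polygon rule is not
documented, so both ship). Multipart geometries are rejected with
guidance. A species is included iff probability ≥ threshold at every
site; the comparison is inclusive per the documented "0.4 or higher"
wording. Threshold kinds: fixed, species-specific max-SSS (computed
from each overall map against a seeded 2,000-cell background sample),
or sensitivity=specificity. Menus report per-site probabilities *and*
their minimum. The coverage map counts species clearing their
threshold per cell.

## Bias diagnostic

Aggregated habitat probability and SE (cellwise means across species)
are regressed on Euclidean distance-to-development (exact distance
transform of the road/feature mask) with a univariate penalized spline
(10 basis functions, GCV-chosen λ); R² = 1 − SSE/SST, NaN for a
zero-variance response. The regression uses all valid cells (optional
seeded subsample for speed), plus an 8-equal-width-bin distance
summary (n, mean, quartiles per bin) for violin-style display.

## Synthetic data: what it emulates and what it does not

Covariate layers are Gaussian white noise smoothed with a Gaussian
kernel (σ = `autocorrelation_range` cells), empirically whitened and
linearly mixed so requested pairwise correlations are achieved
essentially exactly, then standardized. Virtual species follow an
exact logistic response to a chosen covariate subset. Occurrences draw
cells with replacement ∝ true probability × exp(bias × access score),
with within-cell coordinate jitter and truncated-normal positional
uncertainties (mean 0.3, SD 0.2 km). Roads are random one-cell-wide
lines; the access score is −distance/max(distance).

Default study conditions: 64×64 km grid (recovery) or 48×48
(conformance/bias), 1-km cells, 8 (recovery) or 4–6 covariates,
|β| = 2–3 on two causal covariates, intercept −8, 300 occurrence
records per species. The intercept makes ~3–5% of the landscape
suitable — a deliberately *range-restricted* species, matching the
specialist character of priority restoration taxa. This matters:
presence-vs-random-background AUC is bounded by prevalence, and a
broad-ranged virtual species (intercept ≥ −3, ≥ 20% suitable) caps
holdout AUC near 0.75 no matter how good the model — the same
mechanism that gives the most widespread real shrubs the lowest
published AUCs. Passing recovery tests on rare species therefore does
not certify performance for very common ones.

Other realism gaps: covariates are stationary Gaussian fields (no
elevation gradients, no playas/mountain mask), roads are straight and
independent of terrain, species responses are exactly logistic with no
interactions, and records are temporally unstructured. The bias
experiment aggregates over 4 virtual species because a single smooth
habitat map chance-aligns with the smooth distance field on a small
grid; aggregation cancels chance alignment but not a shared access
bias — the same logic as aggregating over 49 real species.

Ground-truth validation: `truth_holdout_auc` scores a habitat map
against fresh presence draws (∝ p) and absence draws (∝ 1 − p) from
the generator — an evaluation only a synthetic species admits, and the
right recovery metric because it is independent of the pseudo-absence
machinery being tested.

## Reduced-scale profiles and reproducibility

The full regional-scale design (14 covariates, ≤ 6 terms, 50 CV runs, ~10
candidates, 1000 trees, 10,000 background) is cluster work: ~6k
subsets × 3 families × 50 runs per species. The shipped desk profiles
scale down to 8 covariates / ≤ 4 terms / spec cap 24 / 10 runs / 5
candidates / 200 trees (recovery, ~3 min) and 6 covariates / ≤ 3
terms / cap 10 / 4 runs / 80 trees × 4 species (bias experiment, ~2
min); every constant is a config field, so the full-scale settings are
one YAML away. One master seed fans out to every draw through
`derive_seed(master, *keys)` (a `SeedSequence` wrapper); identical
config + seed reproduces CSV outputs byte-identically and rasters to
1e−12.

## Known limitations

* The smooth-additive λ search is a coarse per-term grid, not full
  REML; edf values are accurate for the selected λ but the selection
  itself is approximate.
* The maxent-like default regularization is a single global L1
  multiplier, not the per-feature-class schedule of the reference
  implementation; "program defaults" are approximated.
* No spatially blocked cross-validation; holdouts are random, so
  autocorrelation inflates desk-scale holdout scores slightly.
* Polygon extraction uses cell-centre membership, so slivers smaller
  than a cell can select no cells (rejected with a clear error).
* GeoTIFF I/O writes plain multi-band TIFF with a JSON metadata tag
  and a text legend sidecar; CRS handling is a tag, not a projection
  engine — no reprojection or resampling.
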