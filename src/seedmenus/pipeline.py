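"""End-to-end orchestration of the per-species ensemble pipeline.

Stages (each also exposed as a CLI subcommand):

* simulate — generate the synthetic stack, virtual species occurrences,
  trait table and road mask;
* prep     — occurrence QC + rasterisation to presence cells;
* fit      — enumerate the model space and cross-validate every spec,
  caching per-spec metrics, run-mean habitat maps, importances and
  response sweeps;
* ensemble — candidate selection, TSS-weighted family ensembles,
  overall ensemble + SE, importance table, response curves, and the
  species-specific max-SSS threshold;
* menu / coverage / diagnose — the decision-support products.

Running the stages in sequence with the same config and seed is
byte-reproducible and equal to a single ``run-all``.
"""

from __future__ import annotations

import json
import logging
import zlib
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .config import RunConfig
from .ensembles import (CandidateSet, EnsemblePrediction, overall_ensemble,
                        predict_family_ensemble, relative_importance,
                        response_curves, se_layer, select_candidates)
from .grids import (CovariateStack, correlation_matrix, read_stack,
                    write_probability_raster, write_stack)
from .menu import (SiteSet, ThresholdRule, apply_threshold, build_menu,
                   coverage_map, extract_at_sites, menu_to_csv)
from .metrics import (CVResult, SpeciesData, auc, cross_validate,
                      derive_seed, max_sss_threshold)
from .model_space import cap_specs, enumerate_models, lifespan_filter
from .occurrences import OccurrenceSet, qc_filter, rasterize_presences
from .bias import aggregate_layers, bias_regression, distance_to_features

log = logging.getLogger("seedmenus")


# --------------------------------------------------------------------------
# simulate
# --------------------------------------------------------------------------

def simulate(config: RunConfig) -> dict:
    """Generate all pipeline inputs with known ground truth."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    seed = config.master_seed

    stack = synth.make_landscape(
        sim.nrows, sim.ncols, sim.cell_km, sim.n_covariates,
        sim.autocorrelation_range, seed=derive_seed(seed, 1))
    write_stack(stack, out / "stack.tif")

    roads = synth.make_road_mask(stack.grid, n_roads=sim.n_roads,
                                 seed=derive_seed(seed, 2))
    write_probability_raster(stack.grid, roads.astype(float),
                             out / "roads.tif", name="road")
    dist = distance_to_features(roads, cell_km=stack.grid.cell_km)
    access = -dist / max(dist.max(), 1e-9)  # high near development

    rng = np.random.default_rng(derive_seed(seed, 3))
    species_meta = {}
    all_records = []
    for i in range(sim.n_species):
        sid = f"species{i + 1:02d}"
        causal = list(rng.choice(stack.codes, size=sim.n_causal, replace=False))
        betas = rng.uniform(sim.beta_low, sim.beta_high, size=sim.n_causal) \
            * rng.choice([-1.0, 1.0], size=sim.n_causal)
        vs = synth.make_virtual_species(stack, causal, betas,
                                        intercept=sim.intercept, species_id=sid)
        occ = synth.sample_occurrences(
            vs, sim.n_occurrences,
            access_bias_strength=sim.access_bias_strength,
            access_raster=access if sim.access_bias_strength > 0 else None,
            seed=derive_seed(seed, 4, i))
        all_records.append(occ.records)
        species_meta[sid] = {"response_vars": causal,
                             "coefficients": betas.tolist(),
                             "lifespan": "perennial"}
    pd.concat(all_records, ignore_index=True).to_csv(
        out / "occurrences.csv", index=False)
    traits = synth.make_trait_table(sorted(species_meta),
                                    seed=derive_seed(seed, 5))
    traits.to_csv(out / "traits.csv", index=False)
    (out / "species_truth.json").write_text(json.dumps(species_meta, indent=2))
    config.to_yaml(out / "config_used.yaml")
    log.info("simulate: %d species on %dx%d grid in %.1fs",
             sim.n_species, sim.nrows, sim.ncols, time.time() - t0)
    return {"stack": stack, "species_meta": species_meta, "traits": traits}


# --------------------------------------------------------------------------
# prep
# --------------------------------------------------------------------------

def prep(config: RunConfig) -> dict[str, np.ndarray]:
    """QC occurrences and rasterise to presence cells, per species."""
    out = Path(config.output_dir)
    stack = read_stack(_stack_path(config))
    occ_path = config.occurrences_path or out / "occurrences.csv"
    records = pd.read_csv(occ_path)
    presence = {}
    reports = []
    for sid, sub in records.groupby("species_id"):
        occ = OccurrenceSet(species_id=str(sid), records=sub)
        clean, report = qc_filter(occ, stack)
        cells = rasterize_presences(clean, stack.grid)
        presence[str(sid)] = cells
        reports.append({"species_id": sid, **report,
                        "n_presence_cells": cells.size})
    prep_dir = out / "prep"
    prep_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(reports).to_csv(prep_dir / "qc_report.csv", index=False)
    rows = [{"species_id": sid, "cell": int(c)}
            for sid, cells in presence.items() for c in cells]
    pd.DataFrame(rows).to_csv(prep_dir / "presence_cells.csv", index=False)
    return presence


# --------------------------------------------------------------------------
# fit
# --------------------------------------------------------------------------

def _stack_path(config: RunConfig) -> Path:
    return Path(config.stack_path or Path(config.output_dir) / "stack.tif")


def _family_fit_kwargs(config: RunConfig, family: str) -> dict:
    f = config.fit
    if family == "tree_ensemble":
        return {"n_trees": f.n_trees}
    if family == "maxent_like":
        return {"regularization": f.maxent_regularization,
                "min_presences": max(f.min_presences // 2, 5)}
    return {"nbasis": f.gam_nbasis, "min_presences": f.min_presences}


def fit_species(config: RunConfig, stack: CovariateStack, species_id: str,
                presence_cells: np.ndarray, lifespan: str,
                ) -> dict[str, list[CVResult]]:
    """Cross-validate every eligible spec for one species, per family."""
    corr = correlation_matrix(stack)
    seed = config.master_seed
    results: dict[str, list[CVResult]] = {}
    sp_data = SpeciesData(species_id=species_id, stack=stack,
                          presence_cells=presence_cells, lifespan=lifespan)
    sp_key = zlib.crc32(species_id.encode()) % (2 ** 16)
    for fam_i, family in enumerate(config.fit.families):
        specs = enumerate_models(stack.codes, corr,
                                 max_terms=config.model_space.max_terms,
                                 r_cut=config.model_space.r_cut,
                                 algorithm_family=family)
        if "AMP" in stack.codes and "MAXN" in stack.codes:
            specs = lifespan_filter(specs, lifespan)
        specs = cap_specs(specs, config.model_space.spec_cap,
                          seed=derive_seed(seed, sp_key, 99))
        t0 = time.time()
        fam_results = []
        for j, spec in enumerate(specs):
            fam_results.append(cross_validate(
                spec, sp_data, n_runs=config.cv.n_runs,
                holdout=config.cv.holdout,
                thin_block_km=config.cv.thin_block_km,
                thin_max_per_block=config.cv.thin_max_per_block,
                seed=derive_seed(seed, sp_key, fam_i, j),
                fit_kwargs=_family_fit_kwargs(config, family)))
        results[family] = fam_results
        log.info("fit %s/%s: %d specs x %d runs in %.1fs", species_id, family,
                 len(specs), config.cv.n_runs, time.time() - t0)
    return results


# --------------------------------------------------------------------------
# ensemble
# --------------------------------------------------------------------------

def ensemble_species(config: RunConfig, stack: CovariateStack,
                     species_id: str,
                     fam_results: dict[str, list[CVResult]],
                     presence_cells: np.ndarray) -> dict:
    """Candidates, family + overall ensembles, importance, curves, threshold."""
    seed = config.master_seed
    candidate_sets: list[CandidateSet] = []
    family_rasters: dict[str, np.ndarray] = {}
    for family, results in fam_results.items():
        cs = select_candidates(results, n_keep=config.ensemble.n_keep)
        candidate_sets.append(cs)
        family_rasters[family] = predict_family_ensemble(cs)
    overall = overall_ensemble(family_rasters)
    se = se_layer(candidate_sets, mode=config.ensemble.se_mode)
    importance = relative_importance(candidate_sets, codes=stack.codes)
    curves = response_curves(candidate_sets, importance=importance,
                             top_k=min(9, len(stack.codes)))

    # species-level max-SSS threshold from the overall map: presence cells
    # vs a seeded random background sample
    sp_key = zlib.crc32(species_id.encode()) % (2 ** 16)
    rng = np.random.default_rng(derive_seed(seed, sp_key, 7))
    bg = rng.choice(stack.valid_cells,
                    size=min(2000, stack.valid_cells.size), replace=False)
    flat = overall.ravel()
    scores = np.concatenate([flat[presence_cells], flat[bg]])
    labels = np.concatenate([np.ones(presence_cells.size), np.zeros(bg.size)])
    ok = np.isfinite(scores)
    thr, _tss = max_sss_threshold(labels[ok], scores[ok])
    species_auc = auc(flat[presence_cells][np.isfinite(flat[presence_cells])],
                      flat[bg][np.isfinite(flat[bg])])

    pred = EnsemblePrediction(species_id=species_id,
                              family_rasters=family_rasters, overall=overall,
                              se=se, threshold=thr)
    return {"prediction": pred, "candidate_sets": candidate_sets,
            "importance": importance, "curves": curves,
            "ensemble_auc": species_auc}


def write_species_outputs(config: RunConfig, species_id: str, bundle: dict,
                          fam_results: dict[str, list[CVResult]]) -> None:
    out = Path(config.output_dir) / "species" / species_id
    out.mkdir(parents=True, exist_ok=True)
    pred: EnsemblePrediction = bundle["prediction"]
    grid = _grid_of(config)
    write_probability_raster(grid, pred.overall, out / "overall.tif")
    write_probability_raster(grid, pred.se, out / "se.tif", name="se")
    for fam, ras in pred.family_rasters.items():
        write_probability_raster(grid, ras, out / f"{fam}.tif")
    bundle["importance"].rename("importance").to_csv(out / "importance.csv")
    rows = []
    for fam, results in fam_results.items():
        for r in results:
            rows.append({"species_id": species_id, "family": fam,
                         "spec_id": r.spec.spec_id, **r.mean.as_dict()})
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    curve_frames = []
    for code, df in bundle["curves"].items():
        d = df.copy()
        d.insert(0, "code", code)
        curve_frames.append(d)
    pd.concat(curve_frames, ignore_index=True).to_csv(
        out / "response_curves.csv", index=False)
    (out / "summary.json").write_text(json.dumps({
        "species_id": species_id, "threshold_max_sss": pred.threshold,
        "ensemble_auc": bundle["ensemble_auc"],
        "master_seed": config.master_seed}, indent=2))


def _grid_of(config: RunConfig):
    return read_stack(_stack_path(config)).grid


# --------------------------------------------------------------------------
# menu / coverage / diagnose
# --------------------------------------------------------------------------

def _load_species_rasters(config: RunConfig) -> tuple[dict, dict, object]:
    base = Path(config.output_dir) / "species"
    rasters, thresholds = {}, {}
    grid = None
    for d in sorted(base.iterdir()):
        if not (d / "overall.tif").exists():
            continue
        st = read_stack(d / "overall.tif")
        rasters[d.name] = st.layers["probability"]
        grid = st.grid
        summary = json.loads((d / "summary.json").read_text())
        thresholds[d.name] = summary["threshold_max_sss"]
    if not rasters:
        raise FileNotFoundError(f"no species rasters under {base}")
    return rasters, thresholds, grid


def _threshold_rule(config: RunConfig, thresholds: dict) -> ThresholdRule:
    if config.threshold.kind == "fixed":
        return ThresholdRule(kind="fixed",
                             fixed_value=config.threshold.fixed_value)
    return ThresholdRule(kind=config.threshold.kind, per_species=thresholds)


def menu_stage(config: RunConfig, sites: SiteSet | None = None,
               selected_traits: list[str] | None = None) -> pd.DataFrame:
    """Extract site probabilities, apply the threshold rule, join traits."""
    out = Path(config.output_dir)
    rasters, thresholds, grid = _load_species_rasters(config)
    if sites is None:
        sites_path = config.sites_path or out / "sites.csv"
        sites = SiteSet.from_csv(sites_path)
    rule = _threshold_rule(config, thresholds)
    probs = extract_at_sites(rasters, grid, sites)
    inclusion = apply_threshold(probs, rule)
    traits_path = config.traits_path or out / "traits.csv"
    traits = pd.read_csv(traits_path)
    if selected_traits is None:
        selected_traits = [c for c in traits.columns if c != "species_id"]
    menu = build_menu(inclusion, traits, selected_traits)
    menu_to_csv(menu, out / "seed_menu.csv", metadata={
        "threshold_rule": config.threshold.kind,
        "fixed_value": config.threshold.fixed_value,
        "sites": ",".join(s.site_id for s in sites.sites),
        "master_seed": config.master_seed})
    return menu


def coverage_stage(config: RunConfig) -> np.ndarray:
    """Coverage map: per-cell count of species clearing their threshold."""
    rasters, thresholds, grid = _load_species_rasters(config)
    rule = _threshold_rule(config, thresholds)
    count = coverage_map(rasters, rule)
    write_probability_raster(grid, count.astype(float),
                             Path(config.output_dir) / "coverage.tif",
                             name="n_species")
    return count


def diagnose_stage(config: RunConfig):
    """Aggregate layers, distance to development, bias smooth regression."""
    out = Path(config.output_dir)
    base = out / "species"
    preds = []
    grid = None
    for d in sorted(base.iterdir()):
        if not (d / "overall.tif").exists():
            continue
        st_p = read_stack(d / "overall.tif")
        st_s = read_stack(d / "se.tif")
        grid = st_p.grid
        preds.append(EnsemblePrediction(
            species_id=d.name, family_rasters={},
            overall=st_p.layers["probability"], se=st_s.layers["se"]))
    roads = read_stack(out / "roads.tif").layers["road"].astype(bool)
    prob, se = aggregate_layers(preds)
    dist = distance_to_features(roads, cell_km=grid.cell_km)
    report = bias_regression(prob, dist, aggregated_se=se)
    report.bins_prob.to_csv(out / "bias_bins_prob.csv", index=False)
    report.bins_se.to_csv(out / "bias_bins_se.csv", index=False)
    (out / "bias_report.json").write_text(json.dumps(report.summary(), indent=2))
    return report


# --------------------------------------------------------------------------
# parameter-recovery experiment
# --------------------------------------------------------------------------

def recovery_experiment(seed: int = 1, causal: tuple[str, str] = ("SP", "Tmax"),
                        betas: tuple[float, float] = (3.0, -2.5),
                        intercept: float = -8.0, n_occurrences: int = 300,
                        config: RunConfig | None = None) -> dict:
    """Reduced-scale end-to-end validation with known ground truth.

    Generates a 64x64, 8-covariate landscape and one virtual species
    responding to two causal covariates, samples occurrences, runs the
    reduced pipeline (<=4 terms, 10 CV runs, 5 candidates per family)
    and reports (a) the rank of the causal covariates in the relative
    importance table and (b) the overall ensemble's held-out AUC against
    a fresh ground-truth presence/absence sample.
    """
    from .synth import (make_landscape, make_virtual_species,
                        sample_occurrences, truth_holdout_auc)
    from .config import demo_config
    if config is None:
        config = demo_config(seed=seed)
    stack = make_landscape(64, 64, 1.0, 8, 4.0, seed=derive_seed(seed, 11))
    vs = make_virtual_species(stack, list(causal), list(betas),
                              intercept=intercept, species_id="recovery")
    occ = sample_occurrences(vs, n_occurrences, seed=derive_seed(seed, 12))
    clean, _ = qc_filter(occ, stack)
    cells = rasterize_presences(clean, stack.grid)
    fam_results = fit_species(config, stack, "recovery", cells, "perennial")
    bundle = ensemble_species(config, stack, "recovery", fam_results, cells)
    importance = bundle["importance"].sort_values(ascending=False)
    ranks = {c: int(np.flatnonzero(importance.index == c)[0]) + 1
             for c in causal}
    auc_truth = truth_holdout_auc(vs, bundle["prediction"].overall,
                                  seed=derive_seed(seed, 13))
    return {"importance": importance, "causal_ranks": ranks,
            "truth_auc": float(auc_truth), "bundle": bundle,
            "stack": stack, "species": vs, "presence_cells": cells}


# --------------------------------------------------------------------------
# sampling-bias experiment
# --------------------------------------------------------------------------

def bias_experiment(seed: int = 1, access_bias_strength: float = 5.0,
                    n_species: int = 4,
                    config: RunConfig | None = None) -> dict:
    """Pipeline-end sensitivity check of the sampling-bias diagnostic.

    Builds one landscape with a synthetic road network and several
    virtual species, then runs the reduced pipeline twice on the *same*
    landscape and seeds: once with occurrences sampled purely from each
    species' habitat probability and once with sampling additionally
    weighted toward easily accessed (near-road) cells.  The diagnostic
    regresses the cross-species aggregated habitat probability on
    distance-to-development; aggregation over species cancels chance
    alignment of any single smooth habitat map with the distance field,
    while a shared access bias — every species over-sampled near the
    same roads — does not cancel.  Returns both conditions' R-squared.
    """
    from .config import (CVConfig, EnsembleConfig, FitConfig,
                         ModelSpaceConfig, RunConfig as _RC)
    from .synth import (make_landscape, make_road_mask, make_virtual_species,
                        sample_occurrences)
    if config is None:
        config = _RC(master_seed=seed,
                     model_space=ModelSpaceConfig(max_terms=3, spec_cap=10),
                     cv=CVConfig(n_runs=4), fit=FitConfig(n_trees=80),
                     ensemble=EnsembleConfig(n_keep=4))
    stack = make_landscape(48, 48, 1.0, 6, 4.0, seed=derive_seed(seed, 21))
    roads = make_road_mask(stack.grid, n_roads=4, seed=derive_seed(seed, 22))
    dist = distance_to_features(roads, cell_km=stack.grid.cell_km)
    access = -dist / max(dist.max(), 1e-9)

    rng = np.random.default_rng(derive_seed(seed, 24))
    species = []
    for i in range(n_species):
        causal = list(rng.choice(stack.codes, size=2, replace=False))
        betas = rng.uniform(2.0, 3.0, size=2) * rng.choice([-1.0, 1.0], 2)
        species.append(make_virtual_species(stack, causal, betas,
                                            intercept=-8.0,
                                            species_id=f"bias{i:02d}"))

    r2 = {}
    for label, strength in (("unbiased", 0.0), ("biased",
                                                access_bias_strength)):
        preds = []
        for i, vs in enumerate(species):
            occ = sample_occurrences(
                vs, 300, access_bias_strength=strength,
                access_raster=access if strength > 0 else None,
                seed=derive_seed(seed, 23, i))
            clean, _ = qc_filter(occ, stack)
            cells = rasterize_presences(clean, stack.grid)
            fam_results = fit_species(config, stack, vs.species_id, cells,
                                      "perennial")
            bundle = ensemble_species(config, stack, vs.species_id,
                                      fam_results, cells)
            preds.append(bundle["prediction"])
        prob, se = aggregate_layers(preds)
        r2[label] = bias_regression(prob, dist, aggregated_se=se)
    return {"r2_prob_unbiased": r2["unbiased"].r2_prob,
            "r2_prob_biased": r2["biased"].r2_prob,
            "r2_se_unbiased": r2["unbiased"].r2_se,
            "r2_se_biased": r2["biased"].r2_se,
            "reports": r2}


# --------------------------------------------------------------------------
# run-all
# --------------------------------------------------------------------------

def run_all(config: RunConfig, do_simulate: bool = True) -> dict:
    """simulate -> prep -> fit -> ensemble -> menu/coverage/diagnose."""
    t0 = time.time()
    if do_simulate:
        simulate(config)
    stack = read_stack(_stack_path(config))
    presence = prep(config)
    out = Path(config.output_dir)
    bundles = {}
    for sid, cells in presence.items():
        lifespan = config.lifespans.get(sid, "perennial")
        fam_results = fit_species(config, stack, sid, cells, lifespan)
        bundle = ensemble_species(config, stack, sid, fam_results, cells)
        write_species_outputs(config, sid, bundle, fam_results)
        bundles[sid] = bundle
    if not (out / "sites.csv").exists() and config.sites_path is None:
        # default demo sites: two valid cell centres
        g = stack.grid
        r1, c1 = g.nrows // 3, g.ncols // 3
        r2, c2 = 2 * g.nrows // 3, 2 * g.ncols // 3
        (x1, y1), (x2, y2) = (g.cell_center(r1, c1), g.cell_center(r2, c2))
        pd.DataFrame({"site_id": ["siteA", "siteB"],
                      "x": [x1, x2], "y": [y1, y2]}).to_csv(
            out / "sites.csv", index=False)
    menu = menu_stage(config)
    coverage = coverage_stage(config)
    report = diagnose_stage(config)
    log.info("run-all finished in %.1fs", time.time() - t0)
    return {"bundles": bundles, "menu": menu, "coverage": coverage,
            "bias_report": report}
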