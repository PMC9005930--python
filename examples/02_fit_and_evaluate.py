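"""Fit the three learner families on one species and cross-validate.

Each family (penalized additive smooths, random forest, maximum
entropy) is evaluated over repeated replicates: fresh thinned presences
and pseudo-absences per run, 20% stratified holdout, AUC / TSS at the
max-SSS threshold / Boyce / AICc.
"""

import warnings

warnings.simplefilter("ignore")

import seedmenus as sm
from seedmenus.model_space import ModelSpec

stack = sm.make_landscape(48, 48, n_covariates=4, autocorrelation_range=3.0,
                          seed=3)
species = sm.make_virtual_species(stack, ["SP", "Tmax"], [3.0, -3.0],
                                  intercept=-8.0, species_id="demo")
occ = sm.sample_occurrences(species, 300, seed=5)
clean, _ = sm.qc_filter(occ, stack)
data = sm.SpeciesData("demo", stack,
                      sm.rasterize_presences(clean, stack.grid))

print("family            AUC    TSS   Boyce   threshold")
for family in ("smooth_additive", "tree_ensemble", "maxent_like"):
    kw = {"n_trees": 200} if family == "tree_ensemble" else {}
    res = sm.cross_validate(ModelSpec(family, ("SP", "Tmax")), data,
                            n_runs=5, seed=31, fit_kwargs=kw,
                            collect_curves=False, collect_prediction=False)
    m = res.mean
    print(f"{family:<16} {m.auc:.3f}  {m.tss:.3f}  {m.boyce:.3f}   "
          f"{m.threshold_used:.3f}")
# AUC ~0.85-0.9: each family separates held-out presences from random
# background cells; TSS is the sensitivity+specificity skill at the
# threshold maximizing their sum.
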