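"""Summarise the packaged 49-species performance/importance table.

The package bundles, verbatim, the published per-species ensemble AUC,
TSS and covariate relative importances for the 49 Mojave Desert
priority restoration species.
"""

import seedmenus as sm

df = sm.load_table2_fixture()
s = sm.table2_summary(df)
print(f"species: {s['n_species']}")
print(f"mean AUC {s['mean_auc']:.3f} (range {s['min_auc']:.3f}-"
      f"{s['max_auc']:.3f}); mean TSS {s['mean_tss']:.3f}")
print(f"mean summer-precipitation importance: "
      f"{s['mean_sp_importance']:.2f} (largest single covariate)")
print(f"temperature outweighs precipitation for "
      f"{s['n_temperature_dominant']} of {s['n_species']} species")
lo = df.loc[df['AUC'].idxmin()]
hi = df.loc[df['AUC'].idxmax()]
print(f"lowest AUC: {lo['species']} ({lo['AUC']}, n={lo['n']}) — a very "
      "broad-ranged shrub is hard to tell from random background")
print(f"highest AUC: {hi['species']} ({hi['AUC']}, n={hi['n']})")
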