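"""Build a seed menu: stack species maps, threshold at sites, join traits.

Uses three toy species habitat rasters and two restoration sites; a
species enters the menu only when its habitat probability meets the
threshold at every site (inclusive AND rule).
"""

import numpy as np
import pandas as pd

import seedmenus as sm

grid = sm.GridSpec(nrows=5, ncols=5, cell_km=1.0)
rng = np.random.default_rng(8)
rasters = {sp: rng.uniform(size=(5, 5)) for sp in ("larrea", "ambrosia",
                                                   "sphaeralcea")}

sites = sm.SiteSet.from_coordinates(pd.DataFrame({
    "site_id": ["north", "south"], "x": [1.5, 3.5], "y": [-0.5, -4.5]}))
probs = sm.extract_at_sites(rasters, grid, sites)
print("habitat probability at sites:")
print(probs.round(3).to_string())

rule = sm.ThresholdRule(kind="fixed", fixed_value=0.25)
inclusion = sm.apply_threshold(probs, rule)
traits = sm.make_trait_table(list(rasters), seed=1)
menu = sm.build_menu(inclusion, traits,
                     ["growth_form", "lifespan", "pollinator_count"])
print("\nseed menu (threshold 0.25 at ALL sites):")
print(menu.to_string(index=False))

coverage = sm.coverage_map(rasters, rule)
print(f"\ncoverage: {coverage.min()}-{coverage.max()} species per cell "
      "clear the threshold across the landscape")
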