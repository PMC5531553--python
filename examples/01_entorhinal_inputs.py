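"""Generate the entorhinal input populations and inspect their spatial code.

Builds the default 183-cell, four-module grid population plus weakly
spatially modulated (WSM) cells, and prints the population-vector (PV)
correlation structure that determines which place fields a downstream
readout can support: grid-only PVs decorrelate within ~20 cm but
re-correlate near the grid spacing (~45 cm), while adding WSM cells
removes that secondary peak.
"""

import numpy as np

from gridplace.environment import DEFAULT_ENV
from gridplace import spatial_inputs as si

env = DEFAULT_ENV
pop = si.sample_grid_population(183, env, seed=0)
print(f"grid population: {pop.n_cells} cells, "
      f"{np.isin(pop.module, [1, 2]).mean():.0%} in the two small-spacing modules")
for m in (1, 2, 3, 4):
    sel = pop.module == m
    print(f"  module {m}: {sel.sum():3d} cells, "
          f"spacing {pop.spacing_cm[sel].mean():5.1f} cm, "
          f"field radius {pop.field_sigma_cm[sel].mean():4.1f} cm")

gmaps = si.grid_population_maps(pop, env)
wmaps = si.wsm_population_maps(183, sigma_n_cm=6.0, env=env, seed=1)

for name, maps in [("grid-only", gmaps),
                   ("grid + equal WSM", np.concatenate([gmaps, wmaps]))]:
    pv = si.pv_distance_correlation(maps, env, max_dist_cm=60)
    d = pv.distance_cm
    trough = pv.mean_corr[(d >= 20) & (d <= 28)].mean()
    peak45 = pv.mean_corr[(d >= 38) & (d <= 52)].max()
    print(f"{name:18s}: PV corr at 20-28 cm = {trough:+.3f}, "
          f"max at 38-52 cm = {peak45:+.3f} "
          f"(secondary-peak prominence {peak45 - trough:+.3f})")

print("\nA positive secondary PV-correlation peak near the grid spacing is "
      "what forces grid-driven place fields to stay small; WSM input "
      "flattens it.")
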