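"""Recurrent bump-attractor CA3: field size follows the connectivity kernel.

Simulates the integrate-and-fire network (1/5 scale: 400 E, 100 I cells)
along a 40-s random trajectory.  Each cell's external input covers only a
~160 cm^2 footprint (sigma_ext = 4 cm), yet recurrent excitation widens
the measured place fields several-fold, growing with the kernel width
sigma_W; removing the spatial input from subsets of cells degrades the
fields sub-linearly.
"""

import numpy as np

from gridplace.environment import DEFAULT_ENV
from gridplace import recurrent as rc
from gridplace.fieldstats import detect_fields

env = DEFAULT_ENV
params = rc.RecurrentNetParams.reduced()
traj = rc.generate_trajectory(env, duration_s=40.0, seed=0)
centers = rc.assign_place_centers(params.n_e, env, seed=1)
footprint = np.pi * (params.sigma_ext_cm * np.sqrt(2 * np.log(5))) ** 2
print(f"trajectory: {traj.duration_s:.0f} s at {traj.speed_cm_s:.0f} cm/s "
      f"({traj.path_length_cm():.0f} cm of path); "
      f"external-input footprint {footprint:.0f} cm^2")

df = rc.kernel_width_sweep(params, [5.0, 10.0, 20.0], traj, env, seed=77)
print("\nkernel width sweep:")
for _, r in df.iterrows():
    print(f"  sigma_W = {r.sigma_w_cm:4.0f} cm: median field "
          f"{r.median_field_size_cm2:5.0f} cm^2 "
          f"({r.median_field_size_cm2 / footprint:.1f}x the footprint), "
          f"{r.mean_fields_per_place_cell:.2f} fields/place cell, "
          f"{r.n_place_cells} place cells")

weights = rc.build_recurrent_weights(params, centers, seed=2)
lc = rc.input_lesion_curve(params, weights, centers, traj,
                           [0, 100, 200], n_rep=1, seed=5, env=env)
print("\nremoving the spatial input from n cells (of 400):")
for n, eps in lc.groupby("n_lesioned").eps.mean().items():
    linear = 0.5 * n / params.n_e
    print(f"  n = {n:3d}: eps = {eps:.3f} (linear reference {linear:.3f})")
print("the nonzero error at n=0 reflects suprathreshold firing in regions "
      "too small (<200 cm^2) to count as fields")
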