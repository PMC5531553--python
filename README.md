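# gridplace

Models of the entorhinal-to-hippocampal transformation that ask a specific
quantitative question: **how can CA3 place cells acquire firing fields of
realistic size** (on the order of 1000–4000 cm², as recorded in dorsal CA3)
**when their dominant spatial input — grid cells — has a periodic population
code that only supports small fields?**

The package is written for computational neuroscientists who want to
regenerate, probe, or extend the three models at desk scale from Python:

1. **Linear-readout separability** (`gridplace.readout`).  A purported place
   cell computes `h(r) = wᵀp(r)` from the input population vector (PV) and
   fires where `h ≥ c`.  Producing one circular field of radius *R* is a
   binary classification of the 80×40 = 3200 location-bin PVs, solved with a
   max-margin linear classifier (LinearSVC).  Solutions exist even for large
   fields, but lesioning inputs shows they are fragile: the grid PV at the
   field center is nearly orthogonal to PVs 20–28 cm away yet correlated
   with PVs near the grid spacing (~45 cm), so large-field solutions balance
   on that periodic structure.
2. **Hebbian feedforward EC→DG→CA3 network** (`gridplace.feedforward`).
   1100 EC inputs (by default 1/6 grid cells, 5/6 weakly spatially modulated
   cells), 12000 DG and 2500 CA3 cells with k-winner-take-all dynamics
   (k = round(a·N); a = 0.0078 in DG, 0.032 in CA3).  The fixed EC→DG→CA3
   pathway teaches CA3 during learning; the plastic EC→CA3 weights follow
   the hetero-associative covariance rule `w_ij = Σ_r [p_j(r) − p̄_j] q_i(r)`;
   after learning CA3 is driven by EC alone.  Mixed input produces large
   fields, ~1/3 of CA3 active, and the characteristic MEC/LEC lesion and
   stability patterns.
3. **Recurrent bump-attractor CA3** (`gridplace.recurrent`).  2000 excitatory
   and 500 inhibitory integrate-and-fire neurons; each E cell gets a narrow
   Gaussian external current (σ_ext = 4 cm) at its assigned place center,
   recurrent excitation `W^EE_ij ∝ exp(−|r_i − r_j|²/2σ_W²)`, and global
   inhibition.  Recurrence widens firing fields far beyond the input
   footprint; the kernel width σ_W sets the field size up to ~20 cm, beyond
   which the bump destabilizes.

A shared analysis layer (`gridplace.fieldstats`) provides rate maps from
spikes (occupancy-normalized, 5-cm Gaussian smoothing), place-field
detection (≥20% of peak, contiguous area > 200 cm²), Skaggs spatial
information, and the lesion error rate
`ε = ½(miss rate in-field + false-alarm rate out-field)` (0.5 = chance).
`gridplace.spatial_inputs` generates the inputs: four grid modules with
spacing means {38.8, 48.4, 65, 98.4} cm (87% of cells in the two small
modules), fields `p(r) = A·exp[−ln5·(d/σ)²]` with σ = 0.32·spacing, and WSM
cells as min-max-normalized smoothed spatial noise.

## Worked example

`python examples/02_readout_separability.py` fits readouts for a small and
a large field on the default 183-cell grid population and prints:

```
R =   10 cm (   314 cm^2): train acc 1.0000, eps at 10% lesion = 0.0053 -> robust (sub-linear)
R =   35 cm (  3848 cm^2): train acc 1.0000, eps at 10% lesion = 0.1275 -> fragile (super-linear)
...
competitive-learning ceiling (threshold lowered until a second field appears): 306 cm^2
minimal single spacing for a robust 35-cm field: 1.6 m
```

Both field sizes are linearly separable, but after silencing 10% of the
grid cells the large-field solution misclassifies ~13% of bins (worse than
the linear-decay reference of 5%), while the small field barely degrades.
The competitive-learning ceiling — set `w` to the PV at the field center
and lower the threshold until a second field appears — lands at ~314 cm²,
the classic "too small" field.  Only when all grid cells share a spacing of
at least 1.6 m (pushing the secondary PV-correlation peak out of the
arena's reach) does a robust 35-cm field become possible.

The other examples narrate the input statistics
(`01_entorhinal_inputs.py`), the feedforward network with its lesion and
stability experiments (`03_feedforward_network.py`), and the recurrent
bump network (`04_recurrent_bump_network.py`).

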