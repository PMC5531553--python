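# Methods

## Environment and conventions

All models share a 2 × 1 m rectangular arena discretized into 80 × 40 =
3200 square bins of 2.5 cm.  Coordinates are continuous centimetres with
the origin at the lower-left corner; bin (ix, iy) covers the half-open
square [ix·2.5, (ix+1)·2.5) × [iy·2.5, (iy+1)·2.5) and rates are evaluated
at bin centers (no within-bin averaging; the bins are much smaller than any
field).  Rate maps are arrays of shape (ny, nx); population matrices are
(n_bins, n_cells) in row-major bin order.  Every generator is a pure
function of its parameters and a seed.

## Entorhinal inputs

**Grid cells.**  Field centers lie on an ideal hexagonal lattice with
lattice vectors of length *s* at angles θ and θ + 60°, extended one grid
spacing beyond every wall so the nearest field center is defined for every
bin (the margin is configurable; periodicity tests use larger margins).
The rate at r is `A_j · exp[−ln5 · (d(r)/σ)²]`, where d is the distance to
the nearest center j, σ = 0.32·s, and the per-field peaks A_j are
Normal(1, 0.1) clipped at zero (clipping only affects ~10⁻²³ of draws; it
guards degenerate negatives).  The rate is A_j at the center and A_j/5 at
the field border, matching the conventional place-field boundary.  The
population has four modules with spacing means {38.8, 48.4, 65, 98.4} cm
(sd 8 cm) and orientation means {15, 30, 45, 60}° (sd 3°).  Only the
combined 87% weight of modules 1+2 is constrained by data; the default
split (0.52, 0.35, 0.08, 0.05) is a configurable choice that respects it.
Spatial offsets are per-cell independent, uniform over one lattice unit
cell.

**Weakly spatially modulated (WSM) cells** stand in for the many EC
neurons with low but nonzero spatial information; we make no claim about
what they actually respond to, only about their spatial statistics.  Each
map is per-bin uniform(0, 1) noise smoothed with an isotropic Gaussian of
sd σ_N (default 6 cm, swept 1–16 cm; reflecting boundary so normalization
is not biased by edge dimming) and then min-max normalized to [0, 1].
Note a consequence of the renormalization: the median spatial information
is *not* monotone in σ_N — it falls from ~0.23 bits at σ_N = 1 cm to a
minimum near 3–4 cm and rises again for very wide kernels, whose maps have
large coherent high/low regions.  The tests assert the decreasing branch
and the default-versus-salt-and-pepper contrast, not global monotonicity.

**PV correlation.**  `pv_distance_correlation` reports the mean Pearson
correlation (across cells) between PVs at location pairs, binned by
separation.  Constant PVs are excluded and counted.  For populations that
mix cell classes with different mean rates the curve has an elevated
baseline (the class-mean profile correlates with itself everywhere), so
the periodic grid structure is best read as the *prominence* of the
spacing-distance peak over the 20–30 cm trough.

## Linear readout (separability analysis)

One place field of radius R at r₀ is the binary labelling "bin center
within R of r₀"; the readout must satisfy `wᵀp(r) ≥ c` in-field and
`< c` out-field (ties count as in-field).  We fit sklearn's LinearSVC with
fitted intercept, no class reweighting (≈50 in-field vs ≈3150 out-field
bins is part of the problem), and C = 2.0.  The regularization strength is
the one genuinely free knob: C = 2 is large enough that every target field
in the default environment is separated exactly, yet small enough that the
solution stays distributed across inputs instead of concentrating on a few
support dimensions — at C ≳ 100 the mixed grid+WSM solution for a 35-cm
field becomes spuriously brittle under lesions, and at C = 1 the grid-only
35-cm problem is no longer exactly separable.  `margin` is reported as
1/‖w‖.

**Lesions** set the rate of chosen input cells to zero at all locations;
the binary map is recomputed at fixed (w, c) and scored against the target
labels with the error rate ε (below).  The linear reference — a readout
whose error grows linearly from (0, 0) to (all inputs, 0.5) — separates
"robust" (sub-linear) from "fragile" (super-linear) solutions.

**Competitive-learning ceiling.**  Competitive learning converges to
weight vectors equal to input PVs, so the activation map is the PV
autocorrelation around r₀.  We lower the threshold over a 400-point
quantile grid of activation values and report the largest single connected
active region before a second region appears (~314 cm² for the default
grid population).

**Minimal robust spacing.**  For single-spacing populations (183 cells,
random offsets, orientation sd 3°, swept 0.6–2.4 m) a solution counts as
robust when (a) the mean ε over 20 draws of a 10% lesion stays below the
linear reference 0.05, and (b) the spacing exceeds the arena's reach from
the field — max distance from the field center to a corner plus R
(146.8 cm for a centered 35-cm field) — so the secondary PV-correlation
peak cannot re-activate the cell anywhere inside the walls.  Clause (b) is
the geometric content of "the second autocorrelation peak must fall
outside the environment"; a lesion threshold alone places the fragile-to-
robust transition diffusely between 1.2 and 1.4 m with large seed
variance, while the two-part criterion yields 1.6 m stably.  Both clauses
are configurable.

## Feedforward EC→DG→CA3 network

Sizes 1100/12000/2500 (EC/DG/CA3); each DG cell receives 352 EC afferents,
each CA3 cell 7 DG and 352 EC afferents, chosen uniformly without
replacement with fixed uniform(0, 1) weights.  Sparsities a_DG = 0.0078
and a_CA3 = 0.032 give k = round(a·N) = 94 and 80 winners; k-WTA keeps the
k most activated cells at their activation value (ties broken by index
order) and silences the rest.  The EC mix defaults to 1/6 grid cells
(183 of 1100); for lesion/stability experiments the EC is split into an
MEC half (one third grid, two thirds WSM, always stable) and an LEC half
(WSM, possibly unstable).

**Learning** drives CA3 through EC→DG→CA3 at every bin and sets the
plastic weights by hetero-association, `w_ij = Σ_r [p_j(r) − p̄_j] q_i(r)`,
restricted to each CA3 cell's 352 EC afferents; weights are signed and
unclipped.

**Retrieval** uses EC alone: `h_i(r) = Σ_j w_ij p_j(r)` followed by CA3
k-WTA, with negative winning activations rectified to zero.  Because the
learned weights are covariances, driving them with raw rates adds a
spatially uniform per-cell bias `Σ_j w_ij p̄_j`; under winner-take-all
competition that bias manufactures cells which win at up to ~98% of all
bins and whose percolated "fields" invert the σ_N trend.  Retrieval
therefore mean-centers the presented maps — equivalent to giving each CA3
cell a static threshold equal to its bias, the usual companion of a
covariance rule.  Centering uses the maps actually presented, so lesioned
(all-zero) cells contribute nothing.

**Analysis conventions.**  A cell is active if it wins anywhere (nonzero
peak); a place cell has ≥1 accepted field.  The lesion error ε compares
each place cell's lesioned *field map* (accepted fields only) with its own
intact field map and averages over the intact network's place cells, so an
unperturbed network scores exactly zero.  (The recurrent model deliberately
uses a different observed map — see below.)  Stability between visits is
the Pearson correlation of 5-cm-smoothed CA3 maps, averaged over cells
active in both visits; second-visit LEC maps are the min-max-normalized
mixture α·M₁ + (1−α)·M₂ of the training map and an independent map.  One
σ_N serves both MEC and LEC WSM cells.

**Reduced scale.**  Experiments and tests run a proportionally reduced
circuit (factor 4: 276/3000/625 cells, fan-ins 88 and 7, identical
sparsities), which preserves the trends and the ~1/3 active fraction; the
full-scale network is the default for production runs (~30 s to train on
one core).

## Recurrent CA3 network

Leaky integrate-and-fire dynamics (dimensionless membrane, threshold 1,
reset 0, τ_cell = 20 ms) with exponential synaptic currents
(τ_E = 5 ms, τ_I = 10 ms), forward-Euler dt = 1 ms, synaptic increments
taking effect the step after the presynaptic spike.  E→E weights follow
the Gaussian kernel `(1/2πσ_W)·exp(−|r_i−r_j|²/2σ_W²)` on the randomly
assigned place centers (self-connections excluded; σ_W = 0 is the
feedforward limit); I→E, E→I, I→I are all-to-all uniform(0, max) with
maxima 0.05, 0.1, 0.17.  The external current
`(gain/2πσ_ext)·exp(−|r_i−r(t)|²/2σ_ext²)`, σ_ext = 4 cm, abstracts a
grid-derived spatial drive.

The neuron constants and operating point are not dictated by the
architecture, so they are explicit parameters chosen once: input gain 2.0,
excitatory bias 0.04 (subthreshold: the no-input network from rest is
silent), and an interneuron bias of −0.3 (a rheobase offset).  The last is
load-bearing: with a zero interneuron bias the I→E loop clamps total
excitatory activity so tightly that field size is flat in σ_W, whereas the
offset frees enough recurrent excitation that the median field grows with
σ_W up to ~20 cm and then fragments into multiple regions — the regime the
model is about.  A second documented operating point
(`RecurrentNetParams.self_sustaining`: excitatory bias 0.055, interneuron
bias −0.1) makes the network condense into a localized wandering bump with
*no* external input (spike-weighted dispersion ~25 cm versus ~64 cm for
uniform scatter); at the default point activity is input-anchored and dies
when the drive is removed.  Runaway excitation is detected by a ceiling on
the 1-s mean population rate (400 Hz default) and raises an error rather
than returning garbage.

Reduced networks (400 E / 100 I) multiply all synaptic weights by
N_ref/N so total synaptic drive is preserved; tests and examples use this
scale with 40-s trajectories, production runs the full 2000/500 network
for 160 s (~20 s of compute).

**Trajectory.**  Constant speed 7 cm/s for 160 s with a slowly diffusing
heading (noise 0.3 rad/√s) and wall reflection.  Note the arithmetic: 160 s
at 7 cm/s is 1120 cm of path, which can cross at most a few hundred of the
3200 bins — raw bin coverage is ~15%.  The 5-cm analysis kernel extends
the rate estimate to >90% of bins for typical seeds, which is the sense in
which this short walk "samples" the arena; field areas measured from such
coverage are underestimates of the true fields, uniformly across
conditions, so within-experiment comparisons (kernel sweeps, lesion
curves) remain valid.

**Input lesions** remove the external current of chosen cells (the cells
stay in the network).  ε compares each place cell's suprathreshold firing
(≥20% of peak) with its own baseline accepted-field map — so ε > 0 even
with no lesion, because firing in regions smaller than 200 cm² counts as
erroneous by construction.

## Shared analysis layer

Rate maps from spikes divide spike counts by occupancy time per bin and
smooth with a 5-cm-sd Gaussian ("width" read as the sd, consistent with
σ_N).  Unvisited bins are excluded: smoothing renormalizes the kernel over
visited bins and leaves bins with no visited neighbour inside the kernel
support as missing.  Fields are maximal contiguous regions (8-connected by
default, 4-connected available) of bins ≥20% of the cell's peak with area
strictly greater than 200 cm² (≥33 bins of 6.25 cm²).  Spatial information
is `Σ_r p(r)·(λ/λ̄)·log₂(λ/λ̄)` with 0·log 0 = 0, occupancy uniform over
visited bins, undefined (error) for zero-mean maps.  Field detection and
spatial information are invariant to positive rescaling of the map.

## Design notes and limitations

* The package is a library: the importable API plus the `examples/`
  scripts are the interface; there is no shell CLI, since every workflow
  here is a Python experiment, not a pipeline step.
* The three models are deliberately not coupled: the recurrent network's
  Gaussian external current *abstracts* a grid-to-place transformation
  rather than consuming the feedforward model's output.  Chaining them is
  an extension, not something the package claims to reproduce.
* The synthetic WSM generator reproduces the spatial autocorrelation of
  weakly tuned EC cells, not their causes (objects, odours, borders); all
  conclusions that depend only on PV statistics transfer, claims about
  specific sensory channels do not.  Temporal coding (theta, phase
  precession), dorsoventral topography, CA1, and boundary-vector-cell
  models are out of scope.
* k-WTA tie-breaking by index order makes degenerate inputs deterministic;
  with continuous-valued inputs ties have measure zero.
* Passing tests at reduced scale show the mechanisms and trends, not
  quantitative agreement with any specific recording dataset; absolute
  field sizes additionally depend on trajectory coverage (recurrent model)
  and network scale (feedforward model).
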