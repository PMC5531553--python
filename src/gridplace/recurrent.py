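"""Recurrent bump-attractor CA3 network of integrate-and-fire neurons.

Each of the n_E excitatory cells is assigned a random place-field center
r_i and receives a narrowly tuned external current (an abstraction of a
grid-cell-derived spatial drive) of width sigma_ext:

    I_ext_i(t) = gain / (2 pi sigma_ext) * exp(-|r_i - r(t)|^2 / (2 sigma_ext^2))

Recurrent excitation follows a Gaussian kernel in place-preference space,

    W^EE_ij = scale / (2 pi sigma_W) * exp(-|r_i - r_j|^2 / (2 sigma_W^2)),

while I->E, E->I and I->I connections are all-to-all with uniform random
weights, providing global inhibitory feedback.  Membrane dynamics are
leaky integrate-and-fire,

    dv_i/dt = -v_i / tau_cell + I_bias + I^E_i - I^I_i + I_ext_i,

with exponentially decaying synaptic currents incremented by W on
presynaptic spikes (forward Euler, increments take effect the step after
the spike).  Because cells are recurrently excited by neighbours whose
external input is centred elsewhere, firing fields grow beyond the
footprint of the external input; sigma_W controls the field size.

The membrane is dimensionless (threshold 1, reset 0); currents are in
threshold units per ms.  The neuron constants and operating-point knobs
(bias currents, input gain) are model choices exposed in the parameter
dataclass; results depend on the dynamical regime, not their exact values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .environment import DEFAULT_ENV, Environment
from .fieldstats import detect_fields, error_rate, rate_map_from_spikes

__all__ = [
    "RecurrentNetParams",
    "Trajectory",
    "SpikeRecord",
    "RecurrentWeights",
    "SimulationUnstable",
    "assign_place_centers",
    "build_recurrent_weights",
    "external_current",
    "generate_trajectory",
    "simulate",
    "rate_maps_from_record",
    "bump_dispersion",
    "kernel_width_sweep",
    "input_lesion_curve",
]


class SimulationUnstable(RuntimeError):
    """Raised when the population rate exceeds the configured ceiling."""


@dataclass(frozen=True)
class RecurrentNetParams:
    """Sizes, neuron constants and coupling of the recurrent CA3 model."""

    n_e: int = 2000
    n_i: int = 500
    tau_cell_ms: float = 20.0
    tau_e_ms: float = 5.0           # decay of excitatory-source currents
    tau_i_ms: float = 10.0          # decay of inhibitory-source currents
    v_th: float = 1.0
    v_reset: float = 0.0
    i_bias_e: float = 0.04
    i_bias_i: float = -0.3
    sigma_ext_cm: float = 4.0
    sigma_w_cm: float = 10.0
    w_max_i_to_e: float = 0.05
    w_max_e_to_i: float = 0.1
    w_max_i_to_i: float = 0.17
    dt_ms: float = 1.0
    input_gain: float = 2.0         # global gain on the external current
    # Density compensation: weights are multiplied by these factors so a
    # smaller network keeps the same total recurrent / inhibitory drive as
    # the reference (2000 E, 500 I) network.
    e_weight_scale: float = 1.0
    i_weight_scale: float = 1.0
    max_rate_hz: float = 400.0      # blow-up ceiling on the mean E rate

    def __post_init__(self) -> None:
        if min(self.tau_cell_ms, self.tau_e_ms, self.tau_i_ms, self.dt_ms) <= 0:
            raise ValueError("time constants and dt must be positive")
        if self.sigma_ext_cm <= 0:
            raise ValueError("sigma_ext_cm must be positive")
        if self.sigma_w_cm < 0:
            raise ValueError("sigma_w_cm must be >= 0")

    @classmethod
    def reduced(cls, factor: int = 5, **overrides) -> "RecurrentNetParams":
        """Smaller network (default 400 E / 100 I) with density-compensated
        weights, for fast experimentation."""
        return cls(
            n_e=2000 // factor,
            n_i=500 // factor,
            e_weight_scale=float(factor),
            i_weight_scale=float(factor),
            **overrides,
        )

    @classmethod
    def self_sustaining(cls, factor: int = 5, **overrides) -> "RecurrentNetParams":
        """Operating point with tonic suprathreshold bias.

        At the default (input-anchored) operating point the excitatory bias
        is subthreshold and activity requires the external spatial drive.
        Raising the bias slightly above rheobase and weakening the
        interneuron offset puts the network in a regime where, even without
        any external input, recurrent excitation plus global inhibition
        condenses the tonic drive into a localized activity bump.  Used to
        demonstrate bump maintenance; place-field experiments use the
        default point.
        """
        overrides.setdefault("i_bias_e", 0.055)
        overrides.setdefault("i_bias_i", -0.1)
        return cls.reduced(factor, **overrides)


@dataclass
class Trajectory:
    """Virtual-animal path sampled at the integration step."""

    positions_cm: np.ndarray   # (n_steps, 2)
    dt_ms: float
    speed_cm_s: float

    @property
    def n_steps(self) -> int:
        return len(self.positions_cm)

    @property
    def duration_s(self) -> float:
        return self.n_steps * self.dt_ms / 1000.0

    def path_length_cm(self) -> float:
        d = np.diff(self.positions_cm, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class SpikeRecord:
    """Spike events of the excitatory population plus the trajectory."""

    cell_ids: np.ndarray       # int, one per spike
    times_ms: np.ndarray       # float, one per spike
    trajectory: Trajectory
    n_cells: int

    def spikes_of(self, cell: int) -> np.ndarray:
        return self.times_ms[self.cell_ids == cell]


@dataclass
class RecurrentWeights:
    """Weight tables W[target, source] for the four pathways."""

    w_ee: np.ndarray   # (n_e, n_e), Gaussian kernel, zero diagonal
    w_ei: np.ndarray   # (n_e, n_i), I -> E
    w_ie: np.ndarray   # (n_i, n_e), E -> I
    w_ii: np.ndarray   # (n_i, n_i)


def assign_place_centers(
    n_e: int, env: Environment = DEFAULT_ENV, seed: int | None = None
) -> np.ndarray:
    """Uniformly random place-field centers for the excitatory cells."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, env.width_cm, n_e)
    y = rng.uniform(0, env.height_cm, n_e)
    return np.column_stack([x, y])


def build_recurrent_weights(
    params: RecurrentNetParams,
    centers: np.ndarray,
    seed: int | None = None,
) -> RecurrentWeights:
    """Gaussian E->E kernel plus all-to-all uniform inhibitory pathways.

    Self-connections are excluded.  sigma_W = 0 yields zero recurrent
    excitation (the feedforward regime).
    """
    rng = np.random.default_rng(seed)
    n_e, n_i = params.n_e, params.n_i
    if params.sigma_w_cm > 0:
        d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        peak = params.e_weight_scale / (2.0 * np.pi * params.sigma_w_cm)
        w_ee = peak * np.exp(-d2 / (2.0 * params.sigma_w_cm**2))
        np.fill_diagonal(w_ee, 0.0)
    else:
        w_ee = np.zeros((n_e, n_e))
    w_ei = rng.uniform(0, params.w_max_i_to_e, (n_e, n_i)) * params.i_weight_scale
    w_ie = rng.uniform(0, params.w_max_e_to_i, (n_i, n_e)) * params.e_weight_scale
    w_ii = rng.uniform(0, params.w_max_i_to_i, (n_i, n_i)) * params.i_weight_scale
    return RecurrentWeights(w_ee, w_ei, w_ie, w_ii)


def external_current(
    centers: np.ndarray,
    position: np.ndarray,
    sigma_ext_cm: float,
    gain: float = 1.0,
) -> np.ndarray:
    """Spatially tuned input current to each E cell at one position."""
    d2 = ((centers - np.asarray(position)) ** 2).sum(-1)
    return gain / (2.0 * np.pi * sigma_ext_cm) * np.exp(-d2 / (2.0 * sigma_ext_cm**2))


def generate_trajectory(
    env: Environment = DEFAULT_ENV,
    duration_s: float = 160.0,
    speed_cm_s: float = 7.0,
    dt_ms: float = 1.0,
    heading_noise_rad_per_sqrt_s: float = 0.3,
    seed: int | None = None,
) -> Trajectory:
    """Constant-speed random walk with wall reflection.

    The heading diffuses with the given noise density; at a wall the
    corresponding velocity component is reflected, so positions stay inside
    the arena at all times.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * 1000.0 / dt_ms))
    dt_s = dt_ms / 1000.0
    pos = np.empty((n, 2))
    p = np.array([env.width_cm, env.height_cm]) * rng.random(2)
    theta = rng.uniform(0, 2 * np.pi)
    sigma_step = heading_noise_rad_per_sqrt_s * np.sqrt(dt_s)
    dtheta = rng.normal(0.0, sigma_step, n)
    step = speed_cm_s * dt_s
    for t in range(n):
        theta += dtheta[t]
        v = np.array([np.cos(theta), np.sin(theta)])
        p = p + step * v
        # reflect at the walls
        if p[0] < 0:
            p[0] = -p[0]
            theta = np.pi - theta
        elif p[0] > env.width_cm:
            p[0] = 2 * env.width_cm - p[0]
            theta = np.pi - theta
        if p[1] < 0:
            p[1] = -p[1]
            theta = -theta
        elif p[1] > env.height_cm:
            p[1] = 2 * env.height_cm - p[1]
            theta = -theta
        pos[t] = p
    return Trajectory(pos, dt_ms, speed_cm_s)


def simulate(
    params: RecurrentNetParams,
    weights: RecurrentWeights,
    centers: np.ndarray,
    trajectory: Trajectory,
    lesion_set: np.ndarray | None = None,
    seed: int | None = None,
    ext_off_after_s: float | None = None,
) -> SpikeRecord:
    """Integrate the network along the trajectory and record E spikes.

    ``lesion_set`` lists E cells whose external spatial input is removed
    (the cells stay in the network).  ``ext_off_after_s`` switches the
    external input off entirely after that time, which is used to probe
    whether the network sustains an activity bump on its own.  Initial
    membrane potentials are drawn uniformly below threshold from ``seed``;
    the dynamics themselves are deterministic.
    """
    rng = np.random.default_rng(seed)
    n_e, n_i = params.n_e, params.n_i
    dt = params.dt_ms
    v_e = rng.uniform(0, 0.5 * params.v_th, n_e)
    v_i = rng.uniform(0, 0.5 * params.v_th, n_i)
    i_ee = np.zeros(n_e)
    i_ei = np.zeros(n_e)
    i_ie = np.zeros(n_i)
    i_ii = np.zeros(n_i)
    dec_e = 1.0 - dt / params.tau_e_ms
    dec_i = 1.0 - dt / params.tau_i_ms
    leak = dt / params.tau_cell_ms
    ext_mask = np.ones(n_e)
    if lesion_set is not None:
        ext_mask[np.asarray(lesion_set, dtype=int)] = 0.0
    pref = params.input_gain / (2.0 * np.pi * params.sigma_ext_cm) * ext_mask
    inv2s2 = 1.0 / (2.0 * params.sigma_ext_cm**2)
    off_step = (
        int(ext_off_after_s * 1000.0 / dt) if ext_off_after_s is not None else None
    )
    spk_e = np.zeros(n_e, bool)
    spk_i = np.zeros(n_i, bool)
    out_cells: list[np.ndarray] = []
    out_times: list[np.ndarray] = []
    spike_budget = 0
    window = max(1, int(1000.0 / dt))  # 1 s blow-up check window
    pos = trajectory.positions_cm
    for t in range(trajectory.n_steps):
        # synaptic decay, then increments from last step's spikes
        i_ee *= dec_e
        i_ie *= dec_e
        i_ei *= dec_i
        i_ii *= dec_i
        if spk_e.any():
            i_ee += weights.w_ee[:, spk_e].sum(axis=1)
            i_ie += weights.w_ie[:, spk_e].sum(axis=1)
        if spk_i.any():
            i_ei += weights.w_ei[:, spk_i].sum(axis=1)
            i_ii += weights.w_ii[:, spk_i].sum(axis=1)
        if off_step is not None and t >= off_step:
            i_ext = 0.0
        else:
            d2 = ((centers[:, 0] - pos[t, 0]) ** 2 + (centers[:, 1] - pos[t, 1]) ** 2)
            i_ext = pref * np.exp(-d2 * inv2s2)
        v_e += -leak * v_e + dt * (params.i_bias_e + i_ee - i_ei) + dt * i_ext
        v_i += -leak * v_i + dt * (params.i_bias_i + i_ie - i_ii)
        spk_e = v_e >= params.v_th
        spk_i = v_i >= params.v_th
        if spk_e.any():
            ids = np.flatnonzero(spk_e)
            out_cells.append(ids)
            out_times.append(np.full(len(ids), t * dt))
            v_e[spk_e] = params.v_reset
            spike_budget += len(ids)
        if spk_i.any():
            v_i[spk_i] = params.v_reset
        if (t + 1) % window == 0:
            mean_rate = spike_budget / n_e / (window * dt / 1000.0)
            if mean_rate > params.max_rate_hz:
                raise SimulationUnstable(
                    f"mean E rate {mean_rate:.0f} Hz exceeded ceiling "
                    f"{params.max_rate_hz:.0f} Hz at t={t * dt:.0f} ms"
                )
            spike_budget = 0
    cells = np.concatenate(out_cells) if out_cells else np.empty(0, int)
    times = np.concatenate(out_times) if out_times else np.empty(0)
    return SpikeRecord(cells, times, trajectory, n_e)


def rate_maps_from_record(
    record: SpikeRecord,
    env: Environment = DEFAULT_ENV,
    smooth_cm: float = 5.0,
) -> np.ndarray:
    """Per-cell firing-rate maps (n_cells, ny, nx); unvisited bins are NaN."""
    dt_s = record.trajectory.dt_ms / 1000.0
    order = np.argsort(record.cell_ids, kind="stable")
    cells = record.cell_ids[order]
    times = record.times_ms[order] / 1000.0
    bounds = np.searchsorted(cells, np.arange(record.n_cells + 1))
    maps = np.empty((record.n_cells, env.ny, env.nx))
    for c in range(record.n_cells):
        maps[c] = rate_map_from_spikes(
            times[bounds[c] : bounds[c + 1]],
            record.trajectory.positions_cm,
            dt_s,
            env,
            smooth_cm,
        )
    return maps


def bump_dispersion(
    record: SpikeRecord,
    centers: np.ndarray,
    t_start_ms: float,
    t_end_ms: float,
) -> float:
    """Spread (cm) of spiking activity in place-preference space.

    Spike-count-weighted standard distance of the active cells' centers in
    the window; a sustained localized bump gives a value far below that of
    uniformly scattered activity.
    """
    sel = (record.times_ms >= t_start_ms) & (record.times_ms < t_end_ms)
    if not sel.any():
        return float("nan")
    pts = centers[record.cell_ids[sel]]
    com = pts.mean(axis=0)
    return float(np.sqrt(((pts - com) ** 2).sum(axis=1).mean()))


def kernel_width_sweep(
    base_params: RecurrentNetParams,
    sigma_w_values: np.ndarray,
    trajectory: Trajectory,
    env: Environment = DEFAULT_ENV,
    seed: int | None = None,
) -> pd.DataFrame:
    """Field statistics as a function of the recurrent kernel width."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for sw, child in zip(np.atleast_1d(sigma_w_values), ss.spawn(len(np.atleast_1d(sigma_w_values)))):
        rng = np.random.default_rng(child)
        params = replace(base_params, sigma_w_cm=float(sw))
        centers = assign_place_centers(params.n_e, env, int(rng.integers(2**31 - 1)))
        weights = build_recurrent_weights(params, centers, int(rng.integers(2**31 - 1)))
        record = simulate(params, weights, centers, trajectory,
                          seed=int(rng.integers(2**31 - 1)))
        maps = rate_maps_from_record(record, env)
        fsets = [detect_fields(m, env) for m in maps]
        areas = np.concatenate([fs.areas_cm2 for fs in fsets]) if fsets else np.array([])
        n_place = sum(fs.is_place_cell for fs in fsets)
        fields_per_place = (
            float(np.mean([fs.n_fields for fs in fsets if fs.is_place_cell]))
            if n_place else 0.0
        )
        rows.append(
            {
                "sigma_w_cm": float(sw),
                "median_field_size_cm2": float(np.median(areas)) if len(areas) else 0.0,
                "mean_field_size_cm2": float(areas.mean()) if len(areas) else 0.0,
                "mean_fields_per_place_cell": fields_per_place,
                "n_place_cells": int(n_place),
                "n_spikes": int(len(record.times_ms)),
            }
        )
    return pd.DataFrame(rows)


def input_lesion_curve(
    params: RecurrentNetParams,
    weights: RecurrentWeights,
    centers: np.ndarray,
    trajectory: Trajectory,
    n_lesioned_levels: np.ndarray,
    n_rep: int = 2,
    seed: int | None = None,
    env: Environment = DEFAULT_ENV,
) -> pd.DataFrame:
    """Error rate vs number of E cells deprived of their spatial input.

    The baseline (no-lesion) simulation defines each place cell's reference
    field map; lesioned runs are scored with the binary error rate of each
    cell's suprathreshold activity against its own reference fields,
    averaged over place cells.  The error is nonzero even without lesions
    because suprathreshold firing outside accepted fields (regions
    < 200 cm^2) counts as erroneous.
    """
    ss = np.random.SeedSequence(seed)
    base_rng = np.random.default_rng(ss.spawn(1)[0])
    baseline = simulate(params, weights, centers, trajectory,
                        seed=int(base_rng.integers(2**31 - 1)))
    base_maps = rate_maps_from_record(baseline, env)
    reference = [detect_fields(m, env) for m in base_maps]
    place = [i for i, fs in enumerate(reference) if fs.is_place_cell]
    rng = np.random.default_rng(ss.spawn(2)[1])
    rows = []
    for n_les in np.atleast_1d(n_lesioned_levels):
        for rep in range(n_rep):
            lesion = rng.choice(params.n_e, int(n_les), replace=False)
            record = simulate(params, weights, centers, trajectory,
                              lesion_set=lesion,
                              seed=int(rng.integers(2**31 - 1)))
            maps = rate_maps_from_record(record, env)
            eps = []
            for i in place:
                m = maps[i]
                peak = np.nanmax(m)
                observed = (
                    np.isfinite(m) & (m >= 0.2 * peak) if peak > 0
                    else np.zeros(m.shape, bool)
                )
                eps.append(error_rate(observed, reference[i].field_mask).eps)
            rows.append(
                {
                    "n_lesioned": int(n_les),
                    "rep": rep,
                    "eps": float(np.mean(eps)) if eps else np.nan,
                    "n_place_cells": len(place),
                }
            )
    return pd.DataFrame(rows)
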