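"""Hebbian feedforward EC -> DG -> CA3 model of place-field formation.

During learning, fixed random EC->DG and DG->CA3 pathways drive CA3 through
the dentate gyrus, which acts as a pattern separator; in each region a
k-winner-take-all (k-WTA) rule keeps the k = round(sparsity * N) most
activated cells and silences the rest.  The plastic EC->CA3 synapses are
then set by Hebbian hetero-association over all location bins:

    w_ij = sum_r [p_j(r) - mean_j(p_j)] * q_i(r)

with p_j the presynaptic EC rate map and q_i the CA3 teaching activity.
After learning, CA3 is driven by EC alone (the DG plays no role in
retrieval): h_i(r) = sum_j w_ij p_j(r), followed by CA3 k-WTA.

The EC input is a mixture of grid cells and weakly spatially modulated
(WSM) cells; by default 1/6 of the 1100 EC cells are grid cells.  For
lesion and stability experiments the EC can be partitioned into an MEC half
(one third grid cells, two thirds stable WSM cells) and an LEC half (WSM
cells whose maps may change between visits).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, sparse

from .environment import DEFAULT_ENV, Environment
from . import spatial_inputs as si
from .fieldstats import FieldSet, detect_fields, error_rate, summarize_population

__all__ = [
    "FFParams",
    "InputMix",
    "HippocampalNet",
    "kwta",
    "kwta_rows",
    "build_network",
    "learn_ec_ca3",
    "retrieve_ca3",
    "fieldsets_for_maps",
    "lesion_mask_for",
    "lesion_experiment",
    "stability_experiment",
    "effective_grid_fraction",
]


@dataclass(frozen=True)
class FFParams:
    """Region sizes, fan-ins and sparsities of the hippocampal circuit."""

    n_ec: int = 1100
    n_dg: int = 12000
    n_ca3: int = 2500
    fanin_ec_dg: int = 352
    fanin_dg_ca3: int = 7
    fanin_ec_ca3: int = 352
    sparsity_dg: float = 0.0078
    sparsity_ca3: float = 0.032

    @property
    def k_dg(self) -> int:
        return int(round(self.sparsity_dg * self.n_dg))

    @property
    def k_ca3(self) -> int:
        return int(round(self.sparsity_ca3 * self.n_ca3))

    @classmethod
    def reduced(cls, factor: int = 4) -> "FFParams":
        """Proportionally smaller circuit for fast experimentation.

        Cell counts and the EC fan-ins shrink by ``factor``; sparsities (and
        hence the active fractions) are unchanged.  The DG->CA3 fan-in of 7
        is already tiny and is kept as is.
        """
        return cls(
            n_ec=1104 // factor if factor == 4 else max(8, round(1100 / factor)),
            n_dg=round(12000 / factor),
            n_ca3=round(2500 / factor),
            fanin_ec_dg=round(352 / factor),
            fanin_dg_ca3=7,
            fanin_ec_ca3=round(352 / factor),
        )


@dataclass(frozen=True)
class InputMix:
    """Composition of the EC input layer."""

    grid_fraction: float = 1.0 / 6.0
    sigma_n_cm: float = 6.0
    partition: bool = False  # split EC into MEC (1/3 grid) and LEC halves

    def __post_init__(self) -> None:
        if not 0.0 <= self.grid_fraction <= 1.0:
            raise ValueError("grid_fraction must be in [0, 1]")


@dataclass
class HippocampalNet:
    """Built network: input maps, fixed wiring, and (after learning) weights."""

    params: FFParams
    mix: InputMix
    env: Environment
    ec_rates: np.ndarray            # (n_ec, ny, nx)
    cell_class: np.ndarray          # 'grid' | 'wsm' per EC cell
    region: np.ndarray              # 'MEC' | 'LEC' | 'EC' per EC cell
    grid_pop: si.GridCellPopulation | None
    ec_dg: sparse.csr_matrix        # (n_ec, n_dg) fixed weights
    dg_ca3: sparse.csr_matrix       # (n_dg, n_ca3) fixed weights
    ec_ca3_idx: np.ndarray          # (n_ca3, fanin_ec_ca3) afferent ids
    lec_m2: np.ndarray | None = None  # second-visit LEC maps (partition only)
    w_ec_ca3: np.ndarray | None = None  # learned (n_ca3, n_ec), masked

    @property
    def n_grid(self) -> int:
        return int((self.cell_class == "grid").sum())

    def population_matrix(self, rates: np.ndarray | None = None) -> np.ndarray:
        r = self.ec_rates if rates is None else rates
        return r.reshape(r.shape[0], -1).T


def kwta(activations: np.ndarray, k: int) -> np.ndarray:
    """k-winner-take-all: the k most active cells keep their activation.

    Ties at the cutoff are broken by index order (lower index wins).
    """
    act = np.asarray(activations, dtype=float)
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > act.size:
        raise ValueError("k exceeds population size")
    out = np.zeros_like(act)
    if k:
        winners = np.argsort(-act, kind="stable")[:k]
        out[winners] = act[winners]
    return out


def kwta_rows(act: np.ndarray, k: int) -> np.ndarray:
    """Row-wise k-WTA for an (n_locations, n_cells) activation matrix."""
    if k < 0 or k > act.shape[1]:
        raise ValueError("k out of range")
    out = np.zeros_like(act)
    if k:
        order = np.argsort(-act, axis=1, kind="stable")[:, :k]
        rows = np.arange(act.shape[0])[:, None]
        out[rows, order] = act[rows, order]
    return out


def _random_bipartite(
    n_src: int, n_tgt: int, fanin: int, rng: np.random.Generator
) -> sparse.csr_matrix:
    """Fixed pathway: each target draws `fanin` distinct sources, U(0,1) weights."""
    if fanin > n_src:
        raise ValueError("fan-in exceeds source population size")
    rows = np.empty(n_tgt * fanin, dtype=np.int64)
    for t in range(n_tgt):
        rows[t * fanin : (t + 1) * fanin] = rng.choice(n_src, fanin, replace=False)
    cols = np.repeat(np.arange(n_tgt), fanin)
    w = rng.random(n_tgt * fanin)
    return sparse.csr_matrix((w, (rows, cols)), shape=(n_src, n_tgt))


def build_network(
    mix: InputMix = InputMix(),
    params: FFParams = FFParams(),
    env: Environment = DEFAULT_ENV,
    seed: int | None = None,
) -> HippocampalNet:
    """Wire the fixed pathways and generate all EC input rate maps."""
    ss = np.random.SeedSequence(seed)
    s_grid, s_wsm, s_wire, s_m2 = [np.random.default_rng(c) for c in ss.spawn(4)]

    n_ec = params.n_ec
    n_grid = int(round(mix.grid_fraction * n_ec))
    cell_class = np.array(["grid"] * n_grid + ["wsm"] * (n_ec - n_grid))
    if mix.partition:
        n_mec = n_ec // 2
        if n_grid > n_mec:
            raise ValueError("grid cells must fit inside the MEC half")
        region = np.array(["MEC"] * n_mec + ["LEC"] * (n_ec - n_mec))
    else:
        region = np.array(["EC"] * n_ec)

    grid_pop = None
    maps = np.zeros((n_ec, env.ny, env.nx))
    if n_grid:
        grid_pop = si.sample_grid_population(
            n_grid, env, seed=int(s_grid.integers(2**31 - 1))
        )
        maps[:n_grid] = si.grid_population_maps(grid_pop, env)
    for i in range(n_grid, n_ec):
        maps[i] = si.wsm_rate_map(mix.sigma_n_cm, env, rng=s_wsm)

    lec_m2 = None
    if mix.partition:
        n_lec = n_ec - n_ec // 2
        lec_m2 = np.stack(
            [si.wsm_rate_map(mix.sigma_n_cm, env, rng=s_m2) for _ in range(n_lec)]
        )

    ec_dg = _random_bipartite(n_ec, params.n_dg, params.fanin_ec_dg, s_wire)
    dg_ca3 = _random_bipartite(params.n_dg, params.n_ca3, params.fanin_dg_ca3, s_wire)
    if params.fanin_ec_ca3 > n_ec:
        raise ValueError("fan-in exceeds source population size")
    ec_ca3_idx = np.stack(
        [s_wire.choice(n_ec, params.fanin_ec_ca3, replace=False) for _ in range(params.n_ca3)]
    )
    return HippocampalNet(
        params, mix, env, maps, cell_class, region, grid_pop,
        ec_dg, dg_ca3, ec_ca3_idx, lec_m2,
    )


def _teaching_activity(net: HippocampalNet) -> np.ndarray:
    """CA3 teaching activity q_i(r) via the fixed EC->DG->CA3 pathway."""
    P = net.population_matrix()                       # (n_bins, n_ec)
    dg_act = kwta_rows(P @ net.ec_dg, net.params.k_dg)
    return kwta_rows(dg_act @ net.dg_ca3, net.params.k_ca3)


def hetero_association(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Hebbian hetero-association weights w_ij = sum_r [p_j - mean(p_j)] q_i.

    ``P`` is (n_locations, n_pre) presynaptic activity, ``Q`` is
    (n_locations, n_post) postsynaptic teaching activity; returns the
    (n_post, n_pre) weight table.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    return Q.T @ (P - P.mean(axis=0))


def learn_ec_ca3(net: HippocampalNet) -> np.ndarray:
    """Hebbian hetero-association of the EC->CA3 weights over all locations.

    Only the 352 (``fanin_ec_ca3``) anatomical afferents of each CA3 cell
    carry a (signed) learned weight; all other entries are zero.  The weight
    table is stored on the network and returned.
    """
    P = net.population_matrix()
    Q = _teaching_activity(net)
    W = hetero_association(P, Q)                      # (n_ca3, n_ec)
    mask = np.zeros_like(W, dtype=bool)
    rows = np.repeat(np.arange(net.params.n_ca3), net.params.fanin_ec_ca3)
    mask[rows, net.ec_ca3_idx.ravel()] = True
    W[~mask] = 0.0
    net.w_ec_ca3 = W
    return W


def retrieve_ca3(
    net: HippocampalNet,
    lesion_mask: np.ndarray | None = None,
    ec_rates: np.ndarray | None = None,
    center: bool = True,
) -> np.ndarray:
    """CA3 rate maps driven by EC alone through the learned weights.

    ``lesion_mask`` silences the marked EC cells at every location;
    ``ec_rates`` substitutes alternative input maps (e.g. a second visit).

    Because the learned weights are covariances, driving them with raw
    rates adds a spatially uniform per-cell bias sum_j w_ij * mean(p_j)
    that the competition would amplify into cells firing across the whole
    arena.  By default the presynaptic maps are therefore mean-centered at
    retrieval (``center=True``), which is equivalent to giving each CA3
    cell a static threshold equal to that bias; the relative activation
    landscape is unchanged.  Centering is computed on the maps actually
    presented, so lesioned (all-zero) cells contribute nothing.

    Winning activations below zero are rectified to zero so the result is a
    valid nonnegative rate map stack of shape (n_ca3, ny, nx).
    """
    if net.w_ec_ca3 is None:
        raise RuntimeError("learn_ec_ca3 must be called before retrieval")
    P = net.population_matrix(ec_rates)
    if lesion_mask is not None:
        P = P.copy()
        P[:, np.asarray(lesion_mask, bool)] = 0.0
    if center:
        P = P - P.mean(axis=0)
    H = kwta_rows(P @ net.w_ec_ca3.T, net.params.k_ca3)
    H = np.clip(H, 0.0, None)
    return H.T.reshape(net.params.n_ca3, net.env.ny, net.env.nx)


def fieldsets_for_maps(maps: np.ndarray, env: Environment) -> list[FieldSet]:
    return [detect_fields(m, env) for m in maps]


def lesion_mask_for(
    net: HippocampalNet,
    target: str,
    fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random lesion mask over EC cells of the given class or region.

    target: 'grid', 'LEC', 'MEC', or 'random' (any EC cell); cells are
    sampled uniformly without replacement within the target pool.
    """
    if target == "grid":
        pool = np.flatnonzero(net.cell_class == "grid")
    elif target in ("LEC", "MEC"):
        pool = np.flatnonzero(net.region == target)
    elif target == "random":
        pool = np.arange(net.params.n_ec)
    else:
        raise ValueError(f"unknown lesion target {target!r}")
    if len(pool) == 0:
        raise ValueError(f"no cells in lesion target {target!r}")
    n = int(round(fraction * len(pool)))
    mask = np.zeros(net.params.n_ec, bool)
    mask[rng.choice(pool, n, replace=False)] = True
    return mask


def _mean_eps(
    lesioned_fsets: list[FieldSet], reference: list[FieldSet]
) -> float:
    """Binary-map error per place cell against its own intact field map.

    Both sides are accepted-field masks, so an unperturbed network scores
    exactly zero; averaged over the intact network's place cells.
    """
    eps = []
    for fs, ref in zip(lesioned_fsets, reference):
        if not ref.is_place_cell:
            continue
        eps.append(error_rate(fs.field_mask, ref.field_mask).eps)
    return float(np.mean(eps)) if eps else np.nan


def lesion_experiment(
    net: HippocampalNet,
    target: str,
    fractions: np.ndarray,
    n_rep: int = 3,
    seed: int | None = None,
    reference: list[FieldSet] | None = None,
) -> pd.DataFrame:
    """Field statistics and error rate under graded lesions of EC inputs.

    The error rate scores each place cell's lesioned suprathreshold map
    against its intact field map and averages over place cells.
    """
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = fieldsets_for_maps(retrieve_ca3(net), net.env)
    rows = []
    for frac in np.atleast_1d(fractions):
        for rep in range(n_rep):
            mask = lesion_mask_for(net, target, float(frac), rng)
            maps = retrieve_ca3(net, lesion_mask=mask)
            fsets = fieldsets_for_maps(maps, net.env)
            summ = summarize_population(fsets)
            rows.append(
                {
                    "target": target,
                    "fraction": float(frac),
                    "n_lesioned": int(mask.sum()),
                    "rep": rep,
                    "eps": _mean_eps(fsets, reference),
                    "mean_field_size_cm2": summ["mean_field_size_cm2"],
                    "mean_fields_per_active_cell": summ["mean_fields_per_active_cell"],
                    "n_active": summ["n_active"],
                    "n_place_cells": summ["n_place_cells"],
                }
            )
    return pd.DataFrame(rows)


def _minmax(maps: np.ndarray) -> np.ndarray:
    lo = maps.min(axis=(1, 2), keepdims=True)
    hi = maps.max(axis=(1, 2), keepdims=True)
    rng = np.where(hi > lo, hi - lo, 1.0)
    return (maps - lo) / rng


def _smooth_all(maps: np.ndarray, env: Environment, smooth_cm: float = 5.0) -> np.ndarray:
    sig = smooth_cm / env.bin_size_cm
    return np.stack([ndimage.gaussian_filter(m, sig, mode="reflect") for m in maps])


def stability_experiment(
    net: HippocampalNet,
    alphas: np.ndarray,
    lesion_target: str | None = None,
    lesion_fraction: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """CA3 map stability between two visits as LEC maps drift.

    The second-visit LEC map of each cell is the min-max-normalized mixture
    alpha * M1 + (1 - alpha) * M2 of its training map M1 and an independent
    map M2; MEC maps are unchanged.  Stability is the mean Pearson
    correlation between each cell's smoothed visit-1 and visit-2 CA3 maps,
    over cells active in both visits.  Optional lesions apply on visit 2.
    """
    if not net.mix.partition or net.lec_m2 is None:
        raise ValueError("stability requires an MEC/LEC-partitioned network")
    rng = np.random.default_rng(seed)
    lec = net.region == "LEC"
    m1 = net.ec_rates[lec]
    visit1 = retrieve_ca3(net)
    sm1 = _smooth_all(visit1, net.env)
    rows = []
    for alpha in np.atleast_1d(alphas):
        mixed = _minmax(alpha * m1 + (1.0 - alpha) * net.lec_m2)
        ec2 = net.ec_rates.copy()
        ec2[lec] = mixed
        mask = (
            lesion_mask_for(net, lesion_target, lesion_fraction, rng)
            if lesion_target
            else None
        )
        visit2 = retrieve_ca3(net, lesion_mask=mask, ec_rates=ec2)
        sm2 = _smooth_all(visit2, net.env)
        both = (visit1.max(axis=(1, 2)) > 0) & (visit2.max(axis=(1, 2)) > 0)
        corrs = []
        for a, b in zip(sm1[both], sm2[both]):
            sa, sb = a.std(), b.std()
            if sa > 0 and sb > 0:
                corrs.append(np.corrcoef(a.ravel(), b.ravel())[0, 1])
        fsets = fieldsets_for_maps(visit2, net.env)
        summ = summarize_population(fsets)
        rows.append(
            {
                "alpha": float(alpha),
                "lesion_target": lesion_target or "none",
                "stability": float(np.mean(corrs)) if corrs else np.nan,
                "n_cells_compared": int(len(corrs)),
                "mean_field_size_cm2": summ["mean_field_size_cm2"],
            }
        )
    return pd.DataFrame(rows)


def effective_grid_fraction(
    mix: InputMix = InputMix(partition=True),
    params: FFParams = FFParams(),
    lesion_target: str = "LEC",
    lesion_fraction: float = 0.0,
) -> float:
    """Grid-cell share of the surviving EC input after a partial lesion.

    E.g. lesioning 40% of the LEC raises the grid share from 1/6 to about
    0.21, mimicking a partial-lesion experiment.
    """
    n_ec = params.n_ec
    n_grid = round(mix.grid_fraction * n_ec)
    n_mec = n_ec // 2
    n_lec = n_ec - n_mec
    pool = {"LEC": n_lec, "MEC": n_mec, "random": n_ec, "grid": n_grid}[lesion_target]
    n_lesioned = round(lesion_fraction * pool)
    grid_lost = 0
    if lesion_target == "grid":
        grid_lost = n_lesioned
    elif lesion_target == "MEC":
        grid_lost = round(n_lesioned * n_grid / n_mec)
    elif lesion_target == "random":
        grid_lost = round(n_lesioned * n_grid / n_ec)
    return (n_grid - grid_lost) / (n_ec - n_lesioned)
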