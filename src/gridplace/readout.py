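"""Linear readout of input population vectors: can one place field exist?

A purported place cell computes h(r) = w^T p(r) and fires where h exceeds a
threshold c.  Producing a single circular field of radius R at r0 is then a
binary classification of the population vectors (PVs) over all location
bins: in-field PVs must satisfy w^T p >= c, out-field PVs w^T p < c.  A
maximum-margin linear classifier (LinearSVC) both decides separability and
returns the most robust solution in the margin sense.

Robustness is probed by lesioning input cells (setting their rate to zero
everywhere), recomputing the binary activation map at fixed (w, c), and
scoring it against the intended field with the binary error rate
(``fieldstats.error_rate``; 0.5 = chance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.svm import LinearSVC

from .environment import DEFAULT_ENV, Environment
from .fieldstats import error_rate
from .spatial_inputs import GridCellPopulation, single_spacing_population, grid_population_maps

__all__ = [
    "FieldSpec",
    "ReadoutSolution",
    "label_bins",
    "as_population_matrix",
    "solve_readout",
    "activation_map",
    "lesion_curve",
    "module_weight_profile",
    "competitive_field_ceiling",
    "RobustnessCriterion",
    "spacing_requirement_sweep",
    "SpacingSweepResult",
]


@dataclass(frozen=True)
class FieldSpec:
    """A circular target place field."""

    center_cm: tuple[float, float]
    radius_cm: float

    def validate(self, env: Environment) -> None:
        x, y = self.center_cm
        r = self.radius_cm
        if r < 0:
            raise ValueError("radius must be >= 0")
        if x - r < 0 or x + r > env.width_cm or y - r < 0 or y + r > env.height_cm:
            raise ValueError("field disc must lie fully inside the environment")


@dataclass
class ReadoutSolution:
    """Weights and threshold of a fitted linear readout.

    The activation is h(r) = weights . p(r); the cell is in-field where
    h >= threshold (ties count as in-field).  ``margin`` is the geometric
    margin 1/||w|| of the max-margin fit; ``separable`` is True when the
    training PVs are classified without error.
    """

    weights: np.ndarray
    threshold: float
    margin: float
    train_accuracy: float
    separable: bool


def label_bins(field: FieldSpec, env: Environment = DEFAULT_ENV) -> np.ndarray:
    """Boolean (ny, nx) map: bin center within radius of the field center."""
    field.validate(env)
    centers = env.bin_centers()
    d = np.hypot(centers[:, 0] - field.center_cm[0], centers[:, 1] - field.center_cm[1])
    return (d <= field.radius_cm).reshape(env.shape)


def as_population_matrix(rates: np.ndarray) -> np.ndarray:
    """Stack (n_cells, ny, nx) rate maps into a (n_bins, n_cells) PV matrix."""
    rates = np.asarray(rates, dtype=float)
    return rates.reshape(rates.shape[0], -1).T


def solve_readout(
    rates: np.ndarray,
    labels: np.ndarray,
    *,
    C: float = 2.0,
    max_iter: int = 50000,
    tol: float = 1e-6,
    seed: int = 0,
) -> ReadoutSolution:
    """Fit the max-margin linear separator between in- and out-field PVs.

    Moderate regularization (C=2) is large enough that every target field
    in the default environment is separated exactly, while keeping the
    max-margin solution distributed across inputs rather than concentrated
    on a few support dimensions; no class reweighting is applied.
    """
    P = as_population_matrix(rates)
    y = np.asarray(labels, dtype=bool).ravel()
    if y.all() or not y.any():
        raise ValueError("both classes must be non-empty")
    svc = LinearSVC(C=C, max_iter=max_iter, tol=tol, random_state=seed)
    svc.fit(P, y.astype(int))
    w = svc.coef_.ravel().copy()
    c = -float(svc.intercept_[0])
    pred = (P @ w >= c)
    acc = float((pred == y).mean())
    norm = float(np.linalg.norm(w))
    return ReadoutSolution(w, c, 1.0 / norm if norm > 0 else np.inf, acc, acc == 1.0)


def activation_map(
    sol: ReadoutSolution, rates: np.ndarray, lesion_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Activation h(r) and the thresholded binary map h >= c.

    ``lesion_mask`` marks input cells whose rate is forced to zero at all
    locations before the readout is applied (weights and threshold fixed).
    """
    rates = np.asarray(rates, dtype=float)
    w = sol.weights.copy()
    if lesion_mask is not None:
        w = np.where(np.asarray(lesion_mask, bool), 0.0, w)
    h = np.tensordot(w, rates, axes=(0, 0))
    return h, h >= sol.threshold


def lesion_curve(
    sol: ReadoutSolution,
    rates: np.ndarray,
    labels: np.ndarray,
    fractions: np.ndarray,
    n_rep: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Error rate vs fraction of randomly lesioned input cells.

    For each fraction, ``n_rep`` random lesion draws are scored with the
    binary error rate against the intended field labels; the weights and
    threshold stay fixed.
    """
    rng = np.random.default_rng(seed)
    n_cells = rates.shape[0]
    rows = []
    for frac in np.atleast_1d(fractions):
        n_les = int(round(frac * n_cells))
        eps = []
        for _ in range(n_rep):
            mask = np.zeros(n_cells, bool)
            mask[rng.choice(n_cells, n_les, replace=False)] = True
            _, binary = activation_map(sol, rates, mask)
            eps.append(error_rate(binary, labels).eps)
        rows.append(
            {
                "fraction": float(frac),
                "n_lesioned": n_les,
                "eps_mean": float(np.mean(eps)),
                "eps_sd": float(np.std(eps)),
            }
        )
    return pd.DataFrame(rows)


def module_weight_profile(
    sol: ReadoutSolution, pop: GridCellPopulation
) -> pd.DataFrame:
    """Mean absolute readout weight per grid module (absent modules omitted)."""
    rows = []
    for m in np.unique(pop.module):
        sel = pop.module == m
        rows.append(
            {
                "module": int(m),
                "n_cells": int(sel.sum()),
                "mean_abs_weight": float(np.abs(sol.weights[sel]).mean()),
            }
        )
    return pd.DataFrame(rows)


def competitive_field_ceiling(
    rates: np.ndarray,
    env: Environment = DEFAULT_ENV,
    center_cm: tuple[float, float] | None = None,
    n_thresholds: int = 400,
) -> float:
    """Largest single-field area (cm^2) achievable by competitive learning.

    Competitive learning sets the weight vector equal to an input PV,
    w = p(r0), so the activation map is the PV autocorrelation around r0.
    Lowering the threshold c grows the field around r0 until, because of the
    grid periodicity, a second disjoint active region appears.  Returns the
    area of the largest map that still has exactly one connected active
    region.
    """
    if center_cm is None:
        center_cm = (env.width_cm / 2, env.height_cm / 2)
    P = as_population_matrix(rates)
    centers = env.bin_centers()
    idx = int(np.argmin(np.hypot(centers[:, 0] - center_cm[0], centers[:, 1] - center_cm[1])))
    w = P[idx]
    h = (P @ w).reshape(env.shape)
    hmax = h.max()
    thresholds = np.quantile(h, np.linspace(1.0, 0.0, n_thresholds))
    best = 0.0
    struct = np.ones((3, 3), bool)
    for c in thresholds:
        if c >= hmax:
            continue
        binary = h >= c
        _, n = ndimage.label(binary, structure=struct)
        if n > 1:
            break
        if n == 1:
            best = binary.sum() * env.bin_area_cm2
    return float(best)


@dataclass(frozen=True)
class RobustnessCriterion:
    """When does a readout solution count as robust?

    Two requirements, both rooted in the periodic-autocorrelation argument:

    1. *Sub-linear lesion error*: the mean error rate after lesioning
       ``lesion_fraction`` of the inputs (``n_rep`` random draws) must stay
       below the linear reference 0.5 * lesion_fraction (a readout whose
       error grows linearly from (0, 0) to (all cells, 0.5) is the fragile
       baseline) and below the absolute cap ``eps_max``.
    2. *No periodic interference*: the grid spacing must exceed the largest
       distance from any in-field location to any location in the
       environment, so the secondary peak of the PV autocorrelation falls
       outside the arena and cannot re-activate the cell out of field.
       For a field of radius R centered at r0 this reach is
       max_corner |corner - r0| + R.  Set
       ``require_interference_free=False`` to use the lesion clause alone.
    """

    lesion_fraction: float = 0.10
    eps_max: float = 0.25
    n_rep: int = 20
    require_sublinear: bool = True
    require_interference_free: bool = True

    def eps_cap(self) -> float:
        cap = self.eps_max
        if self.require_sublinear:
            cap = min(cap, 0.5 * self.lesion_fraction)
        return cap

    def interference_free(
        self, spacing_cm: float, field: "FieldSpec", env: Environment
    ) -> bool:
        if not self.require_interference_free:
            return True
        corners = np.array(
            [[0, 0], [env.width_cm, 0], [0, env.height_cm], [env.width_cm, env.height_cm]]
        )
        reach = float(
            np.max(np.hypot(corners[:, 0] - field.center_cm[0],
                            corners[:, 1] - field.center_cm[1]))
        ) + field.radius_cm
        return spacing_cm > reach


@dataclass
class SpacingSweepResult:
    table: pd.DataFrame
    min_robust_spacing_cm: float | None


def spacing_requirement_sweep(
    radius_cm: float,
    spacings_cm: np.ndarray,
    n_cells: int = 183,
    env: Environment = DEFAULT_ENV,
    *,
    criterion: RobustnessCriterion = RobustnessCriterion(),
    seed: int | None = None,
) -> SpacingSweepResult:
    """Smallest common grid spacing supporting a robust field of given radius.

    For each spacing a population with identical spacing, random offsets and
    near-identical orientations (sd 3 deg) is generated, the max-margin
    readout for a centered circular field is fitted, and the lesion
    robustness criterion evaluated.
    """
    rng = np.random.default_rng(seed)
    field = FieldSpec((env.width_cm / 2, env.height_cm / 2), radius_cm)
    labels = label_bins(field, env)
    rows = []
    min_robust = None
    for s in np.sort(np.atleast_1d(spacings_cm)):
        pop_seed = int(rng.integers(0, 2**31 - 1))
        pop = single_spacing_population(n_cells, float(s), seed=pop_seed)
        rates = grid_population_maps(pop, env)
        sol = solve_readout(rates, labels)
        curve = lesion_curve(
            sol, rates, labels,
            np.array([criterion.lesion_fraction]),
            n_rep=criterion.n_rep,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        eps = float(curve["eps_mean"].iloc[0])
        robust = (
            sol.separable
            and eps < criterion.eps_cap()
            and criterion.interference_free(float(s), field, env)
        )
        rows.append(
            {
                "spacing_cm": float(s),
                "separable": sol.separable,
                "train_accuracy": sol.train_accuracy,
                "eps_at_criterion": eps,
                "robust": bool(robust),
            }
        )
        if robust and min_robust is None:
            min_robust = float(s)
    return SpacingSweepResult(pd.DataFrame(rows), min_robust)
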