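"""Entorhinal input populations: grid cells and weakly spatially modulated cells.

Grid cells fire in fields arranged on a hexagonal lattice.  A cell with
spacing s, orientation theta and a spatial offset has field centers at
``offset + i*a1 + j*a2`` where a1, a2 are lattice vectors of length s at
theta and theta + 60 deg.  The firing rate at location r is

    p(r) = A_j * exp(-ln(5) * (d(r) / sigma)**2)

where d is the distance to the nearest field center j, sigma = 0.32 * s is
the field radius, and A_j is that field's peak rate (drawn from
Normal(1, 0.1), clipped at zero).  The rate thus falls to A_j / 5 at the
field border, mirroring the conventional place-field boundary.

The population is split into four modules with spacing means
{38.8, 48.4, 65, 98.4} cm (sd 8 cm) and orientation means {15, 30, 45, 60}
deg (sd 3 deg); about 87% of cells fall into the two small-spacing modules.

Weakly spatially modulated (WSM) cells stand in for the many EC neurons with
low but nonzero spatial information (e.g. LEC cells in object-poor arenas):
per-bin uniform noise smoothed with an isotropic Gaussian kernel of width
sigma_N and min-max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .environment import DEFAULT_ENV, Environment

__all__ = [
    "GridCellPopulation",
    "sample_grid_population",
    "single_spacing_population",
    "hex_field_centers",
    "grid_rate_map",
    "grid_population_maps",
    "wsm_rate_map",
    "wsm_population_maps",
    "pv_distance_correlation",
    "PVCorrelation",
    "spatial_autocorrelogram",
]

# Module statistics of the dorsal-MEC grid population.
MODULE_SPACING_MEANS_CM = (38.8, 48.4, 65.0, 98.4)
MODULE_SPACING_SD_CM = 8.0
MODULE_ORIENTATION_MEANS_DEG = (15.0, 30.0, 45.0, 60.0)
MODULE_ORIENTATION_SD_DEG = 3.0
# Only the combined weight of modules 1+2 (87%) is constrained by the data;
# the split within and beyond is a modelling choice.
MODULE_PROBS = (0.52, 0.35, 0.08, 0.05)

FIELD_RADIUS_RATIO = 0.32  # sigma_i = 0.32 * spacing
_LN5 = np.log(5.0)


@dataclass
class GridCellPopulation:
    """Per-cell grid parameters.

    Attributes
    ----------
    spacing_cm, orientation_deg : arrays of shape (n_cells,)
    offset_cm : array (n_cells, 2), spatial phase of the lattice
    module : int array (n_cells,), module id in 1..4 (0 = unassigned, e.g.
        single-spacing populations)
    amp_seed : int array (n_cells,), per-cell seed for the per-field peak
        rates so that rate maps are pure functions of (population, env)
    """

    spacing_cm: np.ndarray
    orientation_deg: np.ndarray
    offset_cm: np.ndarray
    module: np.ndarray
    amp_seed: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.spacing_cm)

    @property
    def field_sigma_cm(self) -> np.ndarray:
        """Field radius sigma_i = 0.32 * spacing."""
        return FIELD_RADIUS_RATIO * self.spacing_cm


def _lattice_vectors(spacing_cm: float, orientation_deg: float) -> tuple[np.ndarray, np.ndarray]:
    th = np.deg2rad(orientation_deg)
    a1 = spacing_cm * np.array([np.cos(th), np.sin(th)])
    th2 = th + np.pi / 3.0
    a2 = spacing_cm * np.array([np.cos(th2), np.sin(th2)])
    return a1, a2


def sample_grid_population(
    n_cells: int,
    env: Environment = DEFAULT_ENV,
    *,
    module_probs: tuple[float, ...] = MODULE_PROBS,
    spacing_means_cm: tuple[float, ...] = MODULE_SPACING_MEANS_CM,
    spacing_sd_cm: float = MODULE_SPACING_SD_CM,
    orientation_means_deg: tuple[float, ...] = MODULE_ORIENTATION_MEANS_DEG,
    orientation_sd_deg: float = MODULE_ORIENTATION_SD_DEG,
    seed: int | None = None,
) -> GridCellPopulation:
    """Draw a grid-cell population from the four-module statistics."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    module = rng.choice(len(module_probs), size=n_cells, p=module_probs) + 1
    spacing = rng.normal(
        np.asarray(spacing_means_cm)[module - 1], spacing_sd_cm
    )
    spacing = np.clip(spacing, 1.0, None)
    orientation = rng.normal(
        np.asarray(orientation_means_deg)[module - 1], orientation_sd_deg
    )
    # Offsets uniform over one lattice unit cell.
    uv = rng.random((n_cells, 2))
    offset = np.empty((n_cells, 2))
    for i in range(n_cells):
        a1, a2 = _lattice_vectors(spacing[i], orientation[i])
        offset[i] = uv[i, 0] * a1 + uv[i, 1] * a2
    amp_seed = rng.integers(0, 2**31 - 1, size=n_cells)
    return GridCellPopulation(spacing, orientation, offset, module, amp_seed)


def single_spacing_population(
    n_cells: int,
    spacing_cm: float,
    *,
    orientation_mean_deg: float = 0.0,
    orientation_sd_deg: float = 3.0,
    seed: int | None = None,
) -> GridCellPopulation:
    """Population in which every cell shares one spacing but offsets differ.

    Used to ask how large the grid spacing must be for a linear readout to
    support a robust large place field.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if spacing_cm <= 0:
        raise ValueError("spacing_cm must be positive")
    rng = np.random.default_rng(seed)
    spacing = np.full(n_cells, float(spacing_cm))
    orientation = rng.normal(orientation_mean_deg, orientation_sd_deg, n_cells)
    uv = rng.random((n_cells, 2))
    offset = np.empty((n_cells, 2))
    for i in range(n_cells):
        a1, a2 = _lattice_vectors(spacing[i], orientation[i])
        offset[i] = uv[i, 0] * a1 + uv[i, 1] * a2
    amp_seed = rng.integers(0, 2**31 - 1, size=n_cells)
    return GridCellPopulation(spacing, orientation, offset, np.zeros(n_cells, int), amp_seed)


def hex_field_centers(
    spacing_cm: float,
    orientation_deg: float,
    offset_cm: np.ndarray,
    env: Environment,
    margin_spacings: float = 1.0,
) -> np.ndarray:
    """Hexagonal lattice of field centers covering env plus a margin.

    The lattice extends ``margin_spacings`` grid spacings beyond every wall
    so the nearest field center is defined for every bin.  Centers are
    returned in a deterministic enumeration order.
    """
    a1, a2 = _lattice_vectors(spacing_cm, orientation_deg)
    margin = margin_spacings * spacing_cm
    lo = np.array([-margin, -margin])
    hi = np.array([env.width_cm + margin, env.height_cm + margin])
    # Integer ranges from the bounding-box corners in lattice coordinates.
    B = np.column_stack([a1, a2])
    Binv = np.linalg.inv(B)
    corners = np.array([[lo[0], lo[1]], [lo[0], hi[1]], [hi[0], lo[1]], [hi[0], hi[1]]])
    ij = (corners - offset_cm) @ Binv.T
    i_min, j_min = np.floor(ij.min(axis=0)).astype(int) - 1
    i_max, j_max = np.ceil(ij.max(axis=0)).astype(int) + 1
    ii, jj = np.meshgrid(
        np.arange(i_min, i_max + 1), np.arange(j_min, j_max + 1), indexing="ij"
    )
    pts = offset_cm + ii.reshape(-1, 1) * a1 + jj.reshape(-1, 1) * a2
    keep = (
        (pts[:, 0] >= lo[0]) & (pts[:, 0] <= hi[0])
        & (pts[:, 1] >= lo[1]) & (pts[:, 1] <= hi[1])
    )
    return pts[keep]


def grid_rate_map(
    pop: GridCellPopulation,
    index: int,
    env: Environment = DEFAULT_ENV,
    *,
    margin_spacings: float = 1.0,
) -> np.ndarray:
    """Rate map of one grid cell, shape env.shape, peak ~1."""
    centers = hex_field_centers(
        pop.spacing_cm[index], pop.orientation_deg[index], pop.offset_cm[index],
        env, margin_spacings,
    )
    rng = np.random.default_rng(int(pop.amp_seed[index]))
    amps = np.clip(rng.normal(1.0, 0.1, len(centers)), 0.0, None)
    d, nearest = cKDTree(centers).query(env.bin_centers())
    sigma = pop.field_sigma_cm[index]
    rates = amps[nearest] * np.exp(-_LN5 * (d / sigma) ** 2)
    return rates.reshape(env.shape)


def grid_population_maps(
    pop: GridCellPopulation, env: Environment = DEFAULT_ENV
) -> np.ndarray:
    """Rate maps of all cells, shape (n_cells, ny, nx)."""
    return np.stack([grid_rate_map(pop, i, env) for i in range(pop.n_cells)])


def wsm_rate_map(
    sigma_n_cm: float,
    env: Environment = DEFAULT_ENV,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Weakly spatially modulated rate map in [0, 1] with max exactly 1.

    Per-bin uniform(0, 1) noise smoothed with a Gaussian kernel of sd
    sigma_n_cm (reflecting boundary) and min-max normalized.
    """
    if sigma_n_cm <= 0:
        raise ValueError("sigma_n_cm must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    noise = rng.random(env.shape)
    sm = ndimage.gaussian_filter(noise, sigma=sigma_n_cm / env.bin_size_cm, mode="reflect")
    lo, hi = sm.min(), sm.max()
    if hi == lo:  # pathological flat map
        return np.zeros(env.shape)
    return (sm - lo) / (hi - lo)


def wsm_population_maps(
    n_cells: int,
    sigma_n_cm: float = 6.0,
    env: Environment = DEFAULT_ENV,
    *,
    seed: int | None = None,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.stack([wsm_rate_map(sigma_n_cm, env, rng=rng) for _ in range(n_cells)])


@dataclass
class PVCorrelation:
    """Mean population-vector correlation versus spatial offset."""

    distance_cm: np.ndarray
    mean_corr: np.ndarray
    n_pairs: np.ndarray
    n_excluded_pvs: int = 0


def pv_distance_correlation(
    rates: np.ndarray,
    env: Environment = DEFAULT_ENV,
    max_dist_cm: float = 100.0,
    bin_width_cm: float | None = None,
) -> PVCorrelation:
    """Mean Pearson correlation of PVs at pairs of locations, by distance.

    ``rates`` has shape (n_cells, ny, nx).  The PV at a location is the
    vector of all cells' rates there.  Locations with a constant PV
    (undefined correlation) are excluded and counted.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 3 or rates.shape[0] < 2:
        raise ValueError("need a (n_cells, ny, nx) stack with >= 2 cells")
    n_cells = rates.shape[0]
    P = rates.reshape(n_cells, -1).T  # (n_bins, n_cells)
    mu = P.mean(axis=1, keepdims=True)
    sd = P.std(axis=1, keepdims=True)
    valid = sd[:, 0] > 0
    Z = (P[valid] - mu[valid]) / sd[valid]
    C = (Z @ Z.T) / n_cells
    centers = env.bin_centers()[valid]
    D = cdist(centers, centers)
    if bin_width_cm is None:
        bin_width_cm = env.bin_size_cm
    edges = np.arange(0.0, max_dist_cm + bin_width_cm, bin_width_cm)
    # first bin is the self/near-zero offset bin
    which = np.digitize(D.ravel(), edges[1:], right=False)
    in_range = which < len(edges) - 1
    sums = np.bincount(which[in_range], weights=C.ravel()[in_range], minlength=len(edges) - 1)
    counts = np.bincount(which[in_range], minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = 0.5 * (edges[:-1] + edges[1:])
    mids[0] = 0.0  # the first bin contains the zero-offset self pairs
    return PVCorrelation(mids, mean, counts, int((~valid).sum()))


def spatial_autocorrelogram(values: np.ndarray) -> np.ndarray:
    """Pearson correlation of a rate map with itself at every spatial offset.

    Returns an array of shape (2*ny - 1, 2*nx - 1) whose center is the
    zero-offset correlation (1).  For a grid cell the six innermost
    secondary peaks lie at one grid spacing from the center.
    """
    A = np.asarray(values, dtype=float)
    M = np.ones_like(A)
    flip = A[::-1, ::-1]
    mflip = M[::-1, ::-1]
    n = signal.fftconvolve(M, mflip, mode="full")
    s_xy = signal.fftconvolve(A, flip, mode="full")
    s_x = signal.fftconvolve(A, mflip, mode="full")
    s_y = signal.fftconvolve(M, flip, mode="full")
    s_xx = signal.fftconvolve(A**2, mflip, mode="full")
    s_yy = signal.fftconvolve(M, (A**2)[::-1, ::-1], mode="full")
    num = n * s_xy - s_x * s_y
    den = np.sqrt(np.clip(n * s_xx - s_x**2, 0, None) * np.clip(n * s_yy - s_y**2, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 1e-9 * np.maximum(n, 1), num / den, np.nan)
    return r
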