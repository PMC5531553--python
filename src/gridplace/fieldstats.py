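"""Place-field analysis shared by all models.

Conventions
-----------
* A bin is *active* for a cell if its rate is at least ``rate_frac`` (default
  20%) of the cell's peak rate.
* A *place field* is a maximal contiguous region (8-connected by default) of
  active bins with area strictly greater than ``min_area_cm2`` (200 cm^2,
  i.e. at least 33 bins of 6.25 cm^2).
* A cell is *active* if it has a nonzero peak; a *place cell* if it has at
  least one accepted field.
* Spatial information of a rate map lambda(r) with occupancy probability
  p(r):  I = sum_r p(r) * (lambda/mean) * log2(lambda/mean), with
  0*log(0) = 0.
* The error rate of an observed binary activity map against a reference
  field map is

      eps = 1/2 * (miss fraction in-field + false-alarm fraction out-field)

  which is 0 for perfect agreement and 0.5 in expectation for firing that is
  statistically independent of location (including total silence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .environment import DEFAULT_ENV, Environment

__all__ = [
    "Field",
    "FieldSet",
    "ErrorScore",
    "detect_fields",
    "spatial_information",
    "error_rate",
    "occupancy_map",
    "rate_map_from_spikes",
    "smooth_rate_map",
    "summarize_population",
]


@dataclass
class Field:
    """One detected place field."""

    mask: np.ndarray          # boolean (ny, nx)
    area_cm2: float
    centroid_cm: np.ndarray   # (2,) x, y
    peak_rate: float


@dataclass
class FieldSet:
    """All accepted fields of one cell plus activity flags."""

    fields: list[Field]
    active: bool
    active_mask: np.ndarray   # bins >= rate_frac * peak (suprathreshold)
    peak_rate: float

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    @property
    def is_place_cell(self) -> bool:
        return self.active and self.n_fields >= 1

    @property
    def field_mask(self) -> np.ndarray:
        """Union of all accepted-field bins."""
        out = np.zeros_like(self.active_mask)
        for f in self.fields:
            out |= f.mask
        return out

    @property
    def areas_cm2(self) -> np.ndarray:
        return np.array([f.area_cm2 for f in self.fields])


@dataclass
class ErrorScore:
    """Eq-style lesion error: mean of in-field miss and out-field false alarm."""

    eps: float
    miss_rate: float
    false_alarm_rate: float


_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def detect_fields(
    values: np.ndarray,
    env: Environment = DEFAULT_ENV,
    *,
    rate_frac: float = 0.2,
    min_area_cm2: float = 200.0,
    connectivity: int = 8,
) -> FieldSet:
    """Threshold a rate map at rate_frac * peak and extract place fields.

    NaN bins (e.g. unvisited space) are treated as inactive.
    """
    vals = np.asarray(values, dtype=float)
    finite = np.isfinite(vals)
    peak = np.nanmax(vals) if finite.any() else 0.0
    if not np.isfinite(peak) or peak <= 0:
        return FieldSet([], False, np.zeros(vals.shape, bool), 0.0)
    active_mask = finite & (vals >= rate_frac * peak)
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels, n = ndimage.label(active_mask, structure=struct)
    fields: list[Field] = []
    bin_area = env.bin_area_cm2
    for lab in range(1, n + 1):
        mask = labels == lab
        area = mask.sum() * bin_area
        if area > min_area_cm2:
            iy, ix = np.nonzero(mask)
            b = env.bin_size_cm
            centroid = np.array([(ix.mean() + 0.5) * b, (iy.mean() + 0.5) * b])
            fields.append(Field(mask, float(area), centroid, float(np.nanmax(vals[mask]))))
    return FieldSet(fields, True, active_mask, float(peak))


def spatial_information(
    values: np.ndarray, occupancy: np.ndarray | None = None
) -> float:
    """Spatial information (bits) of a rate map.

    ``occupancy`` may be an (unnormalized) occupancy weight per bin; by
    default occupancy is uniform over all finite bins.  Raises on an all-zero
    or empty map (mean rate must be positive).
    """
    lam = np.asarray(values, dtype=float).ravel()
    ok = np.isfinite(lam)
    if occupancy is None:
        p = ok.astype(float)
    else:
        p = np.asarray(occupancy, dtype=float).ravel() * ok
    if p.sum() <= 0:
        raise ValueError("no occupied bins")
    p = p / p.sum()
    lam = np.where(ok, lam, 0.0)
    mean = float((p * lam).sum())
    if mean <= 0:
        raise ValueError("mean rate must be positive for spatial information")
    ratio = lam / mean
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(ratio > 0, p * ratio * np.log2(ratio), 0.0)
    return float(terms.sum())


def error_rate(observed: np.ndarray, reference: np.ndarray) -> ErrorScore:
    """Binary-map error of observed activity against a reference field map."""
    obs = np.asarray(observed, dtype=bool).ravel()
    ref = np.asarray(reference, dtype=bool).ravel()
    if obs.shape != ref.shape:
        raise ValueError("observed and reference must have the same shape")
    n_in = int(ref.sum())
    n_out = int((~ref).sum())
    if n_in == 0 or n_out == 0:
        raise ValueError("reference must contain both in-field and out-field bins")
    miss = float((~obs & ref).sum()) / n_in
    fa = float((obs & ~ref).sum()) / n_out
    return ErrorScore(0.5 * (miss + fa), miss, fa)


def occupancy_map(
    positions: np.ndarray, dt_s: float, env: Environment = DEFAULT_ENV
) -> np.ndarray:
    """Time (s) spent in each bin for a trajectory sampled every dt_s."""
    ix, iy = env.position_to_bin(positions)
    occ = np.zeros(env.shape)
    np.add.at(occ, (iy, ix), dt_s)
    return occ


def smooth_rate_map(
    rates: np.ndarray,
    visited: np.ndarray,
    smooth_cm: float = 5.0,
    env: Environment = DEFAULT_ENV,
) -> np.ndarray:
    """Occupancy-masked Gaussian smoothing (sd smooth_cm, reflecting walls).

    The kernel is renormalized over visited bins, so the smoothed estimate is
    a weighted average of nearby visited bins; bins with no visited bin
    within the kernel support stay NaN.
    """
    vis = np.asarray(visited, dtype=float)
    r = np.where(vis > 0, np.nan_to_num(rates), 0.0)
    sig = smooth_cm / env.bin_size_cm
    num = ndimage.gaussian_filter(r, sig, mode="reflect")
    den = ndimage.gaussian_filter(vis, sig, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-12, num / np.maximum(den, 1e-300), np.nan)
    return out


def rate_map_from_spikes(
    spike_times_s: np.ndarray,
    positions: np.ndarray,
    dt_s: float,
    env: Environment = DEFAULT_ENV,
    smooth_cm: float = 5.0,
) -> np.ndarray:
    """Firing-rate map (Hz) from spike times and the concurrent trajectory.

    Spikes are binned by the animal's position at the spike time, divided by
    the occupancy time per bin, then smoothed with a Gaussian kernel of sd
    ``smooth_cm``.  Unvisited bins are excluded from the estimate and remain
    NaN where the smoothing kernel finds no visited neighbour.
    """
    positions = np.asarray(positions, dtype=float)
    occ = occupancy_map(positions, dt_s, env)
    visited = occ > 0
    counts = np.zeros(env.shape)
    if len(spike_times_s):
        idx = np.clip((np.asarray(spike_times_s) / dt_s).astype(int), 0, len(positions) - 1)
        ix, iy = env.position_to_bin(positions[idx])
        np.add.at(counts, (iy, ix), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(visited, counts / np.maximum(occ, 1e-300), np.nan)
    if smooth_cm and smooth_cm > 0:
        return smooth_rate_map(raw, visited, smooth_cm, env)
    return raw


def summarize_population(fieldsets: list[FieldSet]) -> dict:
    """Population summary of field sizes, counts and activity.

    Returns a dict with mean/median field size, mean fields per active cell,
    active- and place-cell counts, and the cumulative field-size
    distribution (sorted areas and cumulative fraction).
    """
    areas = np.concatenate([fs.areas_cm2 for fs in fieldsets]) if fieldsets else np.array([])
    n_active = sum(fs.active for fs in fieldsets)
    n_place = sum(fs.is_place_cell for fs in fieldsets)
    fields_per_active = (
        np.mean([fs.n_fields for fs in fieldsets if fs.active]) if n_active else 0.0
    )
    sorted_areas = np.sort(areas)
    cum = np.arange(1, len(areas) + 1) / len(areas) if len(areas) else np.array([])
    return {
        "n_cells": len(fieldsets),
        "n_active": int(n_active),
        "n_place_cells": int(n_place),
        "n_fields": int(len(areas)),
        "mean_field_size_cm2": float(areas.mean()) if len(areas) else 0.0,
        "median_field_size_cm2": float(np.median(areas)) if len(areas) else 0.0,
        "mean_fields_per_active_cell": float(fields_per_active),
        "field_sizes_cm2": sorted_areas,
        "cumulative_fraction": cum,
    }
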