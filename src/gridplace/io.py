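"""Lightweight persistence: rate-map stacks as .npz with a JSON sidecar,
per-cell parameter tables as CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spatial_inputs import GridCellPopulation

__all__ = [
    "save_rate_maps",
    "load_rate_maps",
    "grid_population_to_frame",
    "grid_population_from_frame",
]


def save_rate_maps(path: str | Path, maps: np.ndarray, metadata: dict | None = None) -> None:
    """Write an (n_cells, ny, nx) stack to ``path.npz`` plus ``path.json``."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), rates=np.asarray(maps))
    meta = {"n_cells": int(len(maps)), **(metadata or {})}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_rate_maps(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        maps = data["rates"]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return maps, meta


def grid_population_to_frame(pop: GridCellPopulation) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spacing_cm": pop.spacing_cm,
            "orientation_deg": pop.orientation_deg,
            "offset_x_cm": pop.offset_cm[:, 0],
            "offset_y_cm": pop.offset_cm[:, 1],
            "module": pop.module,
            "field_sigma_cm": pop.field_sigma_cm,
            "amp_seed": pop.amp_seed,
        }
    )


def grid_population_from_frame(df: pd.DataFrame) -> GridCellPopulation:
    return GridCellPopulation(
        spacing_cm=df["spacing_cm"].to_numpy(float),
        orientation_deg=df["orientation_deg"].to_numpy(float),
        offset_cm=df[["offset_x_cm", "offset_y_cm"]].to_numpy(float),
        module=df["module"].to_numpy(int),
        amp_seed=df["amp_seed"].to_numpy(np.int64),
    )
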