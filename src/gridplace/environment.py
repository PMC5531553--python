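"""Discretized 2-D environment shared by all models.

The default arena is a 2 x 1 m rectangle binned into 80 x 40 square bins of
2.5 cm, i.e. 3200 location bins.  Continuous coordinates are in centimetres
with the origin at the lower-left corner; bin (ix, iy) covers the half-open
square [ix*b, (ix+1)*b) x [iy*b, (iy+1)*b) where b is the bin side.

Rate maps are stored as arrays of shape (ny, nx): the first axis is y
(rows), the second x (columns).  Flattened (row-major) order is therefore
``index = iy * nx + ix``; population matrices of shape (n_bins, n_cells)
use this flattening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Environment:
    """Rectangular arena with a square-bin discretization."""

    width_cm: float = 200.0
    height_cm: float = 100.0
    nx: int = 80
    ny: int = 40

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("bin counts must be positive")
        bx = self.width_cm / self.nx
        by = self.height_cm / self.ny
        if not np.isclose(bx, by):
            raise ValueError(
                f"bins must be square: width/nx={bx:g} != height/ny={by:g}"
            )

    @property
    def bin_size_cm(self) -> float:
        return self.width_cm / self.nx

    @property
    def bin_area_cm2(self) -> float:
        return self.bin_size_cm ** 2

    @property
    def n_bins(self) -> int:
        return self.nx * self.ny

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape (ny, nx) of a rate map over this environment."""
        return (self.ny, self.nx)

    def bin_centers(self) -> np.ndarray:
        """Coordinates of all bin centers, shape (n_bins, 2), row-major."""
        b = self.bin_size_cm
        x = (np.arange(self.nx) + 0.5) * b
        y = (np.arange(self.ny) + 0.5) * b
        xx, yy = np.meshgrid(x, y)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (..., 2) lying inside the walls."""
        pts = np.asarray(points, dtype=float)
        x, y = pts[..., 0], pts[..., 1]
        return (x >= 0) & (x <= self.width_cm) & (y >= 0) & (y <= self.height_cm)

    def position_to_bin(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map continuous positions (..., 2) to integer bin indices (ix, iy).

        Positions exactly on the right/top wall are assigned to the last bin.
        """
        pts = np.asarray(points, dtype=float)
        b = self.bin_size_cm
        ix = np.clip((pts[..., 0] // b).astype(int), 0, self.nx - 1)
        iy = np.clip((pts[..., 1] // b).astype(int), 0, self.ny - 1)
        return ix, iy


DEFAULT_ENV = Environment()
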