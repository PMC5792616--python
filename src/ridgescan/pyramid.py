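"""Multiscale DEM pyramid: B-spline low-pass filtering plus dyadic decimation.

Each pyramid level halves the resolution: the grid is smoothed with a cubic
B-spline kernel (separable [1, 4, 6, 4, 1]/16, mirror boundary) and decimated
by averaging 2x2 blocks, so output cell centers coincide with the centroid of
each input block.  Constants and linear ramps are reproduced exactly in the
interior, and block averaging preserves the grid mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid_io import Grid

__all__ = ["ResolutionLadder", "downscale_once", "build_pyramid"]

# Discrete cubic B-spline smoothing kernel (binomial of order 4).
_BSPLINE3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class ResolutionLadder:
    """Dyadic ladder of target resolutions.

    ``factors`` are integer multiples of ``base_cell_size``; the default
    (1, 2, 4, 8, 16) on a 0.5 m base yields the 0.5 / 1 / 2 / 4 / 8 m stack.
    """

    base_cell_size: float = 0.5
    factors: tuple[int, ...] = (1, 2, 4, 8, 16)

    def __post_init__(self) -> None:
        f = tuple(self.factors)
        if f[0] != 1:
            raise ValueError("first ladder factor must be 1 (the base resolution)")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("ladder factors must be strictly increasing")
        for x in f:
            if x & (x - 1):
                raise ValueError("ladder factors must be powers of 2")
        self.factors = f

    @property
    def resolutions(self) -> tuple[float, ...]:
        return tuple(self.base_cell_size * f for f in self.factors)


def _smooth(values: np.ndarray) -> np.ndarray:
    mask = np.isnan(values)
    v = np.where(mask, 0.0, values)
    out = ndimage.convolve1d(v, _BSPLINE3, axis=0, mode="mirror")
    out = ndimage.convolve1d(out, _BSPLINE3, axis=1, mode="mirror")
    if mask.any():
        # conservative propagation: any nodata under the filter support poisons the cell
        touch = ndimage.convolve1d(mask.astype(float), np.ones(5), axis=0, mode="mirror")
        touch = ndimage.convolve1d(touch, np.ones(5), axis=1, mode="mirror")
        out[touch > 0] = np.nan
    return out


def downscale_once(g: Grid) -> Grid:
    """One pyramid step: cubic B-spline smoothing then 2x2 block decimation.

    The output georeference keeps the same top-left origin (block centroids
    are the new cell centers); a trailing odd row/column is trimmed.
    """
    if g.n_rows < 4 or g.n_cols < 4:
        raise ValueError("grid too small to downscale (need at least 4x4 cells)")
    sm = _smooth(g.values)
    nr, nc = (g.n_rows // 2) * 2, (g.n_cols // 2) * 2
    sm = sm[:nr, :nc]
    blocks = sm.reshape(nr // 2, 2, nc // 2, 2).mean(axis=(1, 3))
    return Grid(
        values=blocks,
        x_origin=g.x_origin,
        y_origin=g.y_origin,
        cell_size=g.cell_size * 2,
        nodata=g.nodata,
        crs_label=g.crs_label,
    )


def build_pyramid(g: Grid, ladder: ResolutionLadder | None = None) -> dict[float, Grid]:
    """Map resolution (meters) -> Grid for every ladder level.

    Level k is obtained by k successive :func:`downscale_once` calls; level 0
    is the input itself.
    """
    if ladder is None:
        ladder = ResolutionLadder(base_cell_size=g.cell_size)
    if abs(ladder.base_cell_size - g.cell_size) > 1e-9:
        raise ValueError(
            f"ladder base {ladder.base_cell_size} != grid cell size {g.cell_size}"
        )
    out: dict[float, Grid] = {}
    current = g
    factor = 1
    for target in ladder.factors:
        while factor < target:
            current = downscale_once(current)
            factor *= 2
        out[current.cell_size] = current
    return out
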