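"""One-dimensional finite-volume sediment grid.

Depth coordinate ``x`` is in cm, zero at the sediment-water interface and
positive downward, the standard early-diagenesis convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid1D:
    """Cell-centred finite-volume discretization of a sediment column.

    Attributes
    ----------
    cell_centers : ndarray
        Depth of each cell centre (cm), strictly increasing, first > 0.
    cell_widths : ndarray
        Width of each cell (cm); widths sum to ``depth_max``.
    porosity : ndarray
        Volume fraction of porewater per cell, each in (0, 1).
    depth_max : float
        Bottom of the modelled column (cm).
    """

    cell_centers: np.ndarray
    cell_widths: np.ndarray
    porosity: np.ndarray
    depth_max: float

    def __post_init__(self) -> None:
        c = np.asarray(self.cell_centers, dtype=float)
        w = np.asarray(self.cell_widths, dtype=float)
        phi = np.asarray(self.porosity, dtype=float)
        if c.ndim != 1 or len(c) != len(w) or len(c) != len(phi):
            raise ValueError("grid arrays must be 1-D and of equal length")
        if np.any(np.diff(c) <= 0) or c[0] <= 0 or c[-1] > self.depth_max:
            raise ValueError("cell_centers must be strictly increasing within (0, depth_max]")
        if np.any(w <= 0):
            raise ValueError("cell_widths must be positive")
        if abs(w.sum() - self.depth_max) > 1e-9 * self.depth_max:
            raise ValueError("cell widths must sum to depth_max")
        if np.any(phi <= 0) or np.any(phi >= 1):
            raise ValueError("porosity must lie strictly in (0, 1)")
        object.__setattr__(self, "cell_centers", c)
        object.__setattr__(self, "cell_widths", w)
        object.__setattr__(self, "porosity", phi)

    @property
    def n_cells(self) -> int:
        return len(self.cell_centers)

    @property
    def interfaces(self) -> np.ndarray:
        """Depths of the n+1 cell interfaces, from 0 to depth_max."""
        return np.concatenate([[0.0], np.cumsum(self.cell_widths)])


def build_grid(depth_max: float, n_cells: int, porosity) -> Grid1D:
    """Build a uniform-width grid over ``[0, depth_max]``.

    Parameters
    ----------
    depth_max : float
        Column depth in cm, > 0.
    n_cells : int
        Number of cells, at least 4.
    porosity : float or array-like
        Scalar porosity applied to every cell, or a per-cell profile.

    Returns
    -------
    Grid1D
    """
    if not depth_max > 0:
        raise ValueError("depth_max must be positive")
    if int(n_cells) != n_cells or n_cells < 4:
        raise ValueError("n_cells must be an integer >= 4")
    n_cells = int(n_cells)
    widths = np.full(n_cells, depth_max / n_cells)
    centers = (np.arange(n_cells) + 0.5) * (depth_max / n_cells)
    phi = np.broadcast_to(np.asarray(porosity, dtype=float), (n_cells,)).copy()
    if np.any(phi <= 0) or np.any(phi >= 1):
        raise ValueError("porosity must lie strictly in (0, 1)")
    return Grid1D(cell_centers=centers, cell_widths=widths, porosity=phi, depth_max=float(depth_max))
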