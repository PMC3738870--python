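"""Local cubic lattices of candidate C-alpha positions.

Each interpolated point gets its own small axis-aligned cubic grid of
candidate corrected positions, centred on the point itself.  The grid
spacing is 1/density (default density 6 points per linear Angstrom), and the
grid spans edge_length per axis, so an edge of 1.0 A at density 6 gives
7 points per axis and Q = 343 candidate vertices.

For the centre to be a grid point, edge_length x density must be an even
integer.  The standard retry schedule includes an edge of 1.5 A, for which
1.5 x 6 = 9 is odd; by default the grid is then minimally enlarged to the
next even step count (effective edge 5/3 A, 11 points per axis) so that
density and centre symmetry are preserved exactly.  Pass
``pad_to_even=False`` to get a hard error instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Lattice", "LatticeSymmetryError", "build_lattice"]


class LatticeSymmetryError(ValueError):
    """edge_length x density is not an even integer, so no centred grid exists."""


@dataclass
class Lattice:
    """Q candidate vertices around one interpolated point.

    ``vertices`` are ordered lexicographically by (x, y, z) grid offset, so
    downstream argmin tie-breaking is deterministic.  ``center_index`` locates
    the centre (zero offset) within that ordering.
    """

    center: np.ndarray        # (3,)
    vertices: np.ndarray      # (Q, 3)
    edge_length: float        # effective edge actually spanned, in A
    requested_edge: float     # edge that was asked for
    density: float            # grid points per linear A
    center_index: int

    @property
    def q(self) -> int:
        return len(self.vertices)

    @property
    def points_per_axis(self) -> int:
        return round(len(self.vertices) ** (1.0 / 3.0))


def build_lattice(center: np.ndarray, edge_length: float, density: float,
                  pad_to_even: bool = True) -> Lattice:
    """Build the cubic candidate lattice around ``center``.

    Parameters
    ----------
    center : (3,) array
        The interpolated point the lattice is local to (always a vertex).
    edge_length : float
        Requested per-axis span in Angstrom (standard schedule 1.0, 1.5, 2.0).
    density : float
        Grid points per linear Angstrom (default pipeline value: 6).
    pad_to_even : bool
        When edge_length x density is not an even integer, enlarge the grid
        to the next even step count instead of raising.
    """
    center = np.asarray(center, dtype=float)
    if center.shape != (3,):
        raise ValueError("center must be a 3-vector")
    if density < 1:
        raise ValueError("density must be at least 1 point per Angstrom")
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    product = edge_length * density
    steps = round(product)
    if abs(product - steps) > 1e-9 or steps % 2 != 0:
        if not pad_to_even:
            raise LatticeSymmetryError(
                f"edge_length x density = {product:g} must be an even integer so the "
                "grid is symmetric about its centre (centre must be a grid point)"
            )
        steps = math.ceil(product - 1e-9)
        steps += steps % 2
    half = steps // 2
    offsets = np.arange(-half, half + 1, dtype=float) / density
    count = len(offsets)  # odd, so the centre is a grid point
    gx, gy, gz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)  # lex order in (x, y, z)
    vertices = center[None, :] + grid
    center_index = half * (count * count + count + 1)
    return Lattice(
        center=center,
        vertices=vertices,
        edge_length=steps / density,
        requested_edge=float(edge_length),
        density=float(density),
        center_index=int(center_index),
    )
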