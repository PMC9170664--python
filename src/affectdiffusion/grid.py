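"""The affect grid and probability fields living on it.

The unit square is divided into ``n x n`` equal square cells of width
``delta = 1/n``; cell centers sit at ``((2m+1) delta/2, (2k+1) delta/2)``
so that no center touches the singular boundary.  A one-cell ghost layer
surrounds the interior (used by the propagator to impose no-flux
boundaries).  A :class:`ProbabilityField` stores nonnegative per-cell
masses summing to one; the corresponding density is mass / delta**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AffectGrid", "ProbabilityField", "build_grid", "delta_field", "density_at"]


@dataclass(frozen=True)
class AffectGrid:
    """Regular n-by-n discretization of the unit square (interior cells only)."""

    n: int

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 2:
            raise ValueError(f"grid size n must be an integer >= 2, got {self.n!r}")

    @property
    def delta(self) -> float:
        """Bin width; 1/30 ≈ 0.033 for the default grid."""
        return 1.0 / self.n

    def centers(self):
        """Cell-center coordinates along each axis, shape (n,) each."""
        c = (2 * np.arange(self.n) + 1) * (self.delta / 2.0)
        return c, c.copy()

    def cell_index(self, y) -> np.ndarray:
        """Map point(s) in the closed unit square to interior cell indices.

        Cells are half-open ``[m*delta, (m+1)*delta)``; points with a
        coordinate exactly 1 clamp to the last cell.
        """
        y = np.asarray(y, dtype=float)
        if np.any(y < 0.0) or np.any(y > 1.0):
            raise ValueError("point must lie in the closed unit square")
        idx = np.floor(y * self.n).astype(int)
        return np.clip(idx, 0, self.n - 1)

    def cell_center(self, idx) -> np.ndarray:
        idx = np.asarray(idx)
        return (2 * idx + 1) * (self.delta / 2.0)


def build_grid(n: int = 30) -> AffectGrid:
    """Build the affect grid with ``n`` interior cells per dimension."""
    return AffectGrid(n=int(n))


@dataclass
class ProbabilityField:
    """Per-cell probability masses on an affect grid.

    ``masses`` has shape (n, n), first axis = first affect dimension;
    entries are nonnegative and sum to one (to double precision).
    ``steps`` counts elapsed lattice updates since construction.
    """

    grid: AffectGrid
    masses: np.ndarray
    steps: int = 0

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (self.grid.n, self.grid.n):
            raise ValueError(
                f"masses shape {self.masses.shape} does not match grid n={self.grid.n}"
            )
        if np.any(self.masses < 0):
            raise ValueError("probability masses must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.masses.sum())

    def to_flat(self) -> np.ndarray:
        """Row-major flattening (first dimension index varies slowest)."""
        return self.masses.reshape(-1).copy()

    @classmethod
    def from_flat(cls, grid: AffectGrid, flat, steps: int = 0) -> "ProbabilityField":
        flat = np.asarray(flat, dtype=float)
        return cls(grid=grid, masses=flat.reshape(grid.n, grid.n), steps=steps)

    def save_txt(self, path) -> None:
        """Export as a plain-text matrix (row = first dimension index)."""
        np.savetxt(path, self.masses)

    @classmethod
    def load_txt(cls, path, steps: int = 0) -> "ProbabilityField":
        m = np.atleast_2d(np.loadtxt(path))
        return cls(grid=AffectGrid(n=m.shape[0]), masses=m, steps=steps)


def delta_field(grid: AffectGrid, y0) -> ProbabilityField:
    """Unit mass in the single cell containing ``y0`` (delta initial condition)."""
    i, j = grid.cell_index(y0)
    masses = np.zeros((grid.n, grid.n))
    masses[i, j] = 1.0
    return ProbabilityField(grid=grid, masses=masses)


def density_at(field: ProbabilityField, y) -> float:
    """Probability density at ``y``: mass of the containing cell / delta^2."""
    i, j = field.grid.cell_index(y)
    return float(field.masses[i, j]) / field.grid.delta ** 2
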