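"""Metropolis-Hastings lattice propagator for the Fokker-Planck equation.

The conditional density of the diffusion is advanced on the affect grid by a
discrete-space, discrete-time random-walk update.  In one time step the
state in cell (m, n) proposes one of five moves with probability 1/5 each:
stay, or move to one of the four edge-neighbors (no diagonals).  A proposed
move to a neighbor is accepted with probability

    k[(m,n) -> (m',n')] = min{1, exp(F_{m,n} - F_{m',n'})} ,

so downhill moves on the free-energy surface are always accepted and uphill
moves are exponentially suppressed.  Ghost cells surrounding the grid carry
infinite free energy, which forces zero acceptance toward them and thereby
implements the no-flux boundary condition: probability mass cannot leave the
unit square.

Mass bookkeeping per step is by fluxes:

    p'_{m,n} = p_{m,n} + j_in - j_out ,
    j_out = (1/5) p_{m,n} sum_N k[(m,n) -> .] ,
    j_in  = (1/5) sum_N p_{m',n'} k[(m',n') -> (m,n)] ,

which conserves total mass exactly (fluxes are antisymmetric between cell
pairs) and keeps every mass nonnegative (at most 4/5 of a cell's mass can
leave in one step).  The update satisfies detailed balance with respect to
the discrete Boltzmann field pi ∝ exp(-F), which is therefore stationary.

The step size is tied to the lattice spacing by matching the flat-surface
displacement variance 2 delta^2 / 5 per step to the diffusion law
<(Δy)^2> = 2 D Δt, giving

    Δt = delta^2 / (5 D) .

Grid resolution and time resolution cannot be chosen independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import sparse

from .grid import AffectGrid, ProbabilityField
from .potentials import PotentialSurface

__all__ = [
    "TransitionKernel",
    "build_kernel",
    "mh_step",
    "propagate",
    "stationary_field",
]

# neighbor directions: (di, dj) for accept[d]
_DIRECTIONS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class TransitionKernel:
    """Per-cell acceptance probabilities to the 4 neighbors, plus the step size.

    ``accept[d, i, j]`` is the acceptance probability for the move from cell
    (i, j) toward direction d in ((-1,0), (+1,0), (0,-1), (0,+1)); moves
    toward ghost cells are exactly zero.  ``dt = delta^2 / (5 D)``.
    """

    grid: AffectGrid
    accept: np.ndarray  # (4, n, n)
    dt: float
    D: float
    surface: PotentialSurface

    def stay_probability(self) -> np.ndarray:
        """Per-cell probability of remaining in place; always >= 1/5."""
        return 1.0 - (self.accept[0] / 5.0 + self.accept[1] / 5.0
                      + self.accept[2] / 5.0 + self.accept[3] / 5.0)

    @cached_property
    def operator(self) -> sparse.csr_matrix:
        """One lattice update as a column-stochastic sparse matrix.

        Acting on row-major flattened mass vectors: p' = operator @ p.
        """
        n = self.grid.n
        idx = np.arange(n * n).reshape(n, n)
        rows = [idx.reshape(-1)]
        cols = [idx.reshape(-1)]
        data = [self.stay_probability().reshape(-1)]
        for d, (di, dj) in enumerate(_DIRECTIONS):
            src_i = slice(max(0, -di), n - max(0, di))
            src_j = slice(max(0, -dj), n - max(0, dj))
            dst_i = slice(max(0, di), n - max(0, -di))
            dst_j = slice(max(0, dj), n - max(0, -dj))
            cols.append(idx[src_i, src_j].reshape(-1))
            rows.append(idx[dst_i, dst_j].reshape(-1))
            data.append(self.accept[d, src_i, src_j].reshape(-1) / 5.0)
        mat = sparse.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n * n, n * n),
        )
        return mat.tocsr()

    @cached_property
    def operator_csc(self) -> sparse.csc_matrix:
        """CSC copy of :attr:`operator`; faster for batched dense right-hand sides."""
        return self.operator.tocsc()


def build_kernel(surface: PotentialSurface, D: float) -> TransitionKernel:
    """Build the transition kernel for a tabulated surface and diffusion constant.

    The acceptance is computed as ``exp(-max(0, F_neighbor - F_current))``
    (overflow-safe for large downhill differences); directions pointing into
    the ghost layer are masked to exactly zero rather than fed infinities.
    """
    if not D > 0:
        raise ValueError(f"D must be positive, got {D!r}")
    grid = surface.grid
    n = grid.n
    F = surface.interior
    accept = np.zeros((4, n, n))
    padded = surface.values  # (n+2, n+2), inf on ghosts
    for d, (di, dj) in enumerate(_DIRECTIONS):
        nb = padded[1 + di : n + 1 + di, 1 + dj : n + 1 + dj]
        ghost = ~np.isfinite(nb)
        diff = np.where(ghost, 0.0, nb - F)
        acc = np.exp(-np.maximum(0.0, diff))
        accept[d] = np.where(ghost, 0.0, acc)
    accept.setflags(write=False)
    dt = grid.delta ** 2 / (5.0 * D)
    return TransitionKernel(grid=grid, accept=accept, dt=dt, D=float(D), surface=surface)


def _check_same_grid(field: ProbabilityField, kernel: TransitionKernel) -> None:
    if field.grid.n != kernel.grid.n:
        raise ValueError(
            f"field grid (n={field.grid.n}) does not match kernel grid (n={kernel.grid.n})"
        )


def mh_step(field: ProbabilityField, kernel: TransitionKernel) -> ProbabilityField:
    """Apply one Metropolis-Hastings lattice update (time advance of dt)."""
    _check_same_grid(field, kernel)
    flat = kernel.operator @ field.masses.reshape(-1)
    return ProbabilityField(
        grid=field.grid, masses=flat.reshape(field.grid.n, field.grid.n),
        steps=field.steps + 1,
    )


def propagate(field: ProbabilityField, kernel: TransitionKernel, duration: float):
    """Propagate a field for ``duration`` time units.

    The number of lattice updates is ``k = max(1, round(duration / dt))``
    for positive duration (so distinct observation times are never treated
    as simultaneous) and 0 for duration 0.  Returns ``(field, k)``.
    """
    _check_same_grid(field, kernel)
    if duration < 0:
        raise ValueError(f"duration must be nonnegative, got {duration!r}")
    if duration == 0:
        return field, 0
    k = max(1, int(round(duration / kernel.dt)))
    op = kernel.operator
    flat = field.masses.reshape(-1)
    for _ in range(k):
        flat = op @ flat
    out = ProbabilityField(
        grid=field.grid, masses=flat.reshape(field.grid.n, field.grid.n),
        steps=field.steps + k,
    )
    return out, k


def stationary_field(surface: PotentialSurface) -> ProbabilityField:
    """The discrete Boltzmann distribution p_{m,n} ∝ exp(-F_{m,n}).

    This is the invariant distribution of the lattice update and the
    long-time limit of any propagated field.
    """
    F = surface.interior
    finite = np.isfinite(F)
    if not finite.any():
        raise ValueError("degenerate surface: no finite free-energy values")
    w = np.zeros_like(F)
    w[finite] = np.exp(-(F[finite] - F[finite].min()))
    z = w.sum()
    if not z > 0:
        raise ValueError("degenerate surface: Boltzmann weights sum to zero")
    return ProbabilityField(grid=surface.grid, masses=w / z)
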