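"""Euler-Maruyama trajectory simulation.

Independent Monte-Carlo oracle for the conditional densities computed by the
lattice propagator.  Each trajectory iterates

    y <- y - D * grad F(y) * dt + sqrt(2 D dt) * xi ,   xi ~ N(0, I_2),

then clamps each coordinate into [eps, 1 - eps].  Clamping (rather than
reflection) controls overshooting near the singular free-energy wall at the
boundary; with the small reference step it is a negligible perturbation of
the interior dynamics.  The distribution of endpoints after evolving for
the requested duration approximates the conditional probability density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import AffectGrid, ProbabilityField
from .potentials import ModelParameters, free_energy_gradient

__all__ = ["EMConfig", "reference_dt", "simulate_endpoints", "endpoints_to_field"]


def reference_dt(D: float, n: int = 240) -> float:
    """The lattice step size at bin width 1/n: (1/n)^2 / (5 D).

    The default n=240 is the finest resolution used when benchmarking the
    lattice propagator; tying the simulation step to it keeps the two
    solvers on a common time discretization.
    """
    return (1.0 / n) ** 2 / (5.0 * D)


@dataclass(frozen=True)
class EMConfig:
    """Simulation settings: time step, trajectory count, boundary margin, seed."""

    dt: float
    n_traj: int = 100_000
    boundary_margin: float = 1e-6
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt!r}")
        if not 0 < self.boundary_margin < 0.5:
            raise ValueError("boundary_margin must lie in (0, 0.5)")
        if self.n_traj < 1:
            raise ValueError("n_traj must be positive")


def simulate_endpoints(
    params: ModelParameters,
    y0,
    duration: float,
    config: EMConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate ``config.n_traj`` trajectories from ``y0``; return endpoints.

    The number of steps is ceil(duration / dt) with the final step truncated
    so every trajectory lands exactly at ``duration``.  ``D = 0`` is allowed
    as a degenerate input (both drift and noise vanish).  Returns an array
    of shape (n_traj, 2) with every endpoint in [eps, 1 - eps]^2.
    """
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 <= 0.0) or np.any(y0 >= 1.0):
        raise ValueError("y0 must lie strictly inside the unit square")
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    D = params.D
    eps = config.boundary_margin
    y = np.tile(y0, (config.n_traj, 1))
    if duration == 0 or D == 0:
        return y
    n_steps = int(np.ceil(duration / config.dt))
    for step in range(n_steps):
        dt = min(config.dt, duration - step * config.dt)
        grad = free_energy_gradient(y, params)
        y += -D * grad * dt + np.sqrt(2.0 * D * dt) * rng.standard_normal(y.shape)
        np.clip(y, eps, 1.0 - eps, out=y)
    return y


def endpoints_to_field(endpoints, grid: AffectGrid) -> ProbabilityField:
    """Histogram endpoints over the grid cells, normalized to total mass 1.

    Uses the same half-open cell-assignment rule as the delta initial
    condition; no kernel smoothing is applied.
    """
    endpoints = np.asarray(endpoints, dtype=float)
    if endpoints.size == 0:
        raise ValueError("empty endpoint set")
    idx = grid.cell_index(endpoints)
    flat = idx[:, 0] * grid.n + idx[:, 1]
    counts = np.bincount(flat, minlength=grid.n * grid.n).astype(float)
    masses = (counts / counts.sum()).reshape(grid.n, grid.n)
    return ProbabilityField(grid=grid, masses=masses)
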