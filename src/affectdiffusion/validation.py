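"""Cross-validation of the lattice propagator against Euler-Maruyama.

Quantifies the agreement between the two solvers across grid resolutions
and time horizons: for a set of model parameter sets, the conditional
density from a random initial condition is computed with the lattice
propagator at several grid sizes and with an endpoint histogram from the
trajectory simulator, everything is rebinned to a common 30x30 grid, and
L2 / L-infinity differences of the cell masses are reported as medians per
(grid size, time multiplier).  Time horizons are multiples of the 30x30
lattice step, t * (1/30)^2 / (5 D), so the multiplier t equals the number
of lattice updates on the default grid.

Also houses the closed-form Ornstein-Uhlenbeck transition moments used as
an analytic oracle for the bounded-OU model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .em import EMConfig, endpoints_to_field
from .grid import ProbabilityField, build_grid, delta_field
from .potentials import BoundedOUParameters, free_energy_gradient, tabulate_potential
from .propagator import build_kernel, mh_step

__all__ = [
    "AccuracyReport",
    "rebin",
    "field_difference",
    "ou_transition_moments",
    "convergence_study",
]


def rebin(field: ProbabilityField, target_n: int) -> ProbabilityField:
    """Rebin a field to a ``target_n`` grid, conserving total mass exactly.

    Coarsening (source divisible by target) sums equal square blocks;
    refining (target divisible by source) splits each cell's mass equally
    among its sub-cells.
    """
    n = field.grid.n
    if target_n < 2:
        raise ValueError("target_n must be at least 2")
    if n == target_n:
        return ProbabilityField(grid=field.grid, masses=field.masses.copy(), steps=field.steps)
    if n % target_n == 0:
        f = n // target_n
        masses = field.masses.reshape(target_n, f, target_n, f).sum(axis=(1, 3))
    elif target_n % n == 0:
        f = target_n // n
        masses = np.repeat(np.repeat(field.masses, f, axis=0), f, axis=1) / (f * f)
    else:
        raise ValueError(f"incompatible grid sizes: {n} and {target_n}")
    return ProbabilityField(grid=build_grid(target_n), masses=masses, steps=field.steps)


def field_difference(p: ProbabilityField, q: ProbabilityField, metric: str = "L2") -> float:
    """L2 or L-infinity norm of the difference of two fields' cell masses."""
    if p.grid.n != q.grid.n:
        raise ValueError("fields live on different grids")
    diff = p.masses - q.masses
    if metric == "L2":
        return float(np.sqrt((diff ** 2).sum()))
    if metric == "Linf":
        return float(np.abs(diff).max())
    raise ValueError(f"unknown metric {metric!r}")


def ou_transition_moments(params: BoundedOUParameters, y0, T: float):
    """Analytic conditional mean and covariance of the (unbounded) OU process.

    For dy = -D A (y - mu) dt + sqrt(2 D) dW:
        mean(T) = mu + expm(-D A T) (y0 - mu)
        cov(T)  = A^{-1} (I - expm(-2 D A T))
    The stationary covariance A^{-1} matches the Boltzmann density of the
    quadratic potential F = (1/2)(y - mu)^T A (y - mu).
    """
    y0 = np.asarray(y0, dtype=float)
    A = params.A
    mean = params.mu + expm(-params.D * A * T) @ (y0 - params.mu)
    cov = np.linalg.inv(A) @ (np.eye(2) - expm(-2.0 * params.D * A * T))
    return mean, cov


@dataclass
class AccuracyReport:
    """Median solver differences per (grid size, time multiplier)."""

    table: pd.DataFrame  # index (n, t), columns median_l2, median_linf
    settings: dict

    def median_l2(self, n: int, t: int) -> float:
        return float(self.table.loc[(n, t), "median_l2"])


def _em_snapshots(params, y0, durations, dt, n_traj, margin, rng):
    """Endpoint histograms (on the 30-grid) at several elapsed times, one sweep."""
    grid30 = build_grid(30)
    D = params.D
    y = np.tile(np.asarray(y0, float), (n_traj, 1))
    fields = []
    t_now = 0.0
    for dur in durations:
        n_steps = int(np.ceil((dur - t_now) / dt - 1e-9))
        for s in range(n_steps):
            step_dt = min(dt, dur - t_now)
            grad = free_energy_gradient(y, params)
            y += -D * grad * step_dt + np.sqrt(2.0 * D * step_dt) * rng.standard_normal(y.shape)
            np.clip(y, margin, 1.0 - margin, out=y)
            t_now += step_dt
        fields.append(endpoints_to_field(y, grid30))
    return fields


def _mh_snapshots(params, y0, t_multipliers, n):
    """Lattice conditional fields at each multiplier, rebinned to the 30-grid."""
    grid = build_grid(n)
    surface = tabulate_potential(params, grid)
    kernel = build_kernel(surface, params.D)
    field = delta_field(grid, y0)
    # steps on grid n for multiplier t: round(t * n^2 / 900)
    step_targets = [max(1, int(round(t * n * n / 900.0))) for t in t_multipliers]
    fields = []
    done = 0
    for target in step_targets:
        for _ in range(target - done):
            field = mh_step(field, kernel)
        done = target
        fields.append(rebin(field, 30))
    return fields


def convergence_study(
    params_list,
    grid_sizes=(15, 30, 60, 120),
    t_multipliers=(5, 50, 100, 500),
    em_config: EMConfig | None = None,
    rng: np.random.Generator | None = None,
) -> AccuracyReport:
    """Compare the two solvers over grids and horizons; report medians.

    For each parameter set a random initial condition is drawn uniformly
    over the unit square (a continuous draw lands generically inside every
    grid's cells; lattice-aligned starts would artificially favor the grids
    they align with).  The trajectory simulator's step is tied
    to the finest lattice step in the study, dt = (1/max(n))^2 / (5 D);
    only ``n_traj`` and ``boundary_margin`` of ``em_config`` are used.
    """
    if not len(params_list) or not len(grid_sizes) or not len(t_multipliers):
        raise ValueError("params_list, grid_sizes and t_multipliers must be nonempty")
    if rng is None:
        rng = np.random.default_rng()
    n_traj = em_config.n_traj if em_config is not None else 100_000
    margin = em_config.boundary_margin if em_config is not None else 1e-6
    t_multipliers = sorted(t_multipliers)
    grid_sizes = sorted(grid_sizes)
    fine_n = max(grid_sizes)

    diffs = {(n, t): [] for n in grid_sizes for t in t_multipliers}
    diffs_inf = {(n, t): [] for n in grid_sizes for t in t_multipliers}
    for params in params_list:
        y0 = margin + (1.0 - 2.0 * margin) * rng.random(2)
        D = params.D
        durations = [t * (1.0 / 30) ** 2 / (5.0 * D) for t in t_multipliers]
        dt = (1.0 / fine_n) ** 2 / (5.0 * D)
        em_fields = _em_snapshots(params, y0, durations, dt, n_traj, margin, rng)
        for n in grid_sizes:
            mh_fields = _mh_snapshots(params, y0, t_multipliers, n)
            for t, mh_f, em_f in zip(t_multipliers, mh_fields, em_fields):
                diffs[(n, t)].append(field_difference(mh_f, em_f, "L2"))
                diffs_inf[(n, t)].append(field_difference(mh_f, em_f, "Linf"))

    index = pd.MultiIndex.from_product([grid_sizes, t_multipliers], names=["n", "t"])
    table = pd.DataFrame(
        {
            "median_l2": [float(np.median(diffs[k])) for k in index],
            "median_linf": [float(np.median(diffs_inf[k])) for k in index],
        },
        index=index,
    )
    settings = {
        "n_traj": n_traj,
        "boundary_margin": margin,
        "grid_sizes": list(grid_sizes),
        "t_multipliers": list(t_multipliers),
        "n_parameter_sets": len(params_list),
        "em_dt_rule": f"(1/{fine_n})^2 / (5 D)",
    }
    return AccuracyReport(table=table, settings=settings)
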