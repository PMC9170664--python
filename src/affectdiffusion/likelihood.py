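"""Min-log-likelihood of a parameter set given an affect time series.

The likelihood of a diffusion-model parameter set given an irregularly
sampled series is a product of conditional transition densities between
consecutive observations, each obtained by propagating a delta initial
condition on the lattice over the observed time gap and reading off the
density of the cell containing the next observation.  The first point of a
series can be evaluated under the stationary (Boltzmann) density or
skipped; pairs that straddle a night (a change of day label) can be skipped
entirely or have the later point evaluated under the stationary density.
Missing observations are bridged: the gap runs from the previous to the
next valid observation.

All work for one parameter set (tabulated surface, transition kernel,
stationary field) is computed once and shared across all pairs; pairs are
propagated as a batch of delta fields under the shared sparse update, which
is what makes the objective cheap enough for population-based optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import build_grid, delta_field, density_at
from .potentials import ModelParameters, tabulate_potential
from .propagator import build_kernel, propagate, stationary_field
from .series import AffectTimeSeries, rescale_series  # noqa: F401  (rescale re-exported)

__all__ = [
    "LikelihoodOptions",
    "ObservationPair",
    "pair_neg_loglik",
    "neg_log_likelihood",
    "neg_log_likelihood_pairs",
    "evaluated_pairs",
]


@dataclass(frozen=True)
class LikelihoodOptions:
    """Settings for likelihood evaluation.

    ``density_floor`` keeps the objective finite when an observation falls
    in a cell with zero propagated mass.  ``step_cap`` bounds the lattice
    steps of the longest pair; parameter sets exceeding it (very large D on
    long gaps, i.e. near-stationary dynamics) receive an infinite objective
    instead of an unbounded amount of work.
    """

    grid_n: int = 30
    initial_mode: str = "skip"  # {"stationary", "skip"}
    night_mode: str = "skip_pairs"  # {"skip_pairs", "stationary_restart"}
    density_floor: float = 1e-300
    step_cap: int = 20_000
    cache: bool = True

    def __post_init__(self) -> None:
        if not self.density_floor > 0:
            raise ValueError("density_floor must be positive")
        if self.initial_mode not in ("stationary", "skip"):
            raise ValueError(f"unknown initial_mode {self.initial_mode!r}")
        if self.night_mode not in ("skip_pairs", "stationary_restart"):
            raise ValueError(f"unknown night_mode {self.night_mode!r}")


@dataclass(frozen=True)
class ObservationPair:
    """A conditioning point, a target point, and the time gap between them (hours)."""

    x_from: tuple
    x_to: tuple
    interval: float


def pair_arrays(grid, pairs):
    """Vectorized (src_flat, dst_flat, intervals) for a pair dataset."""
    x_from = np.array([p.x_from for p in pairs])
    x_to = np.array([p.x_to for p in pairs])
    intervals = np.array([p.interval for p in pairs])
    src = grid.cell_index(x_from)
    dst = grid.cell_index(x_to)
    return src[:, 0] * grid.n + src[:, 1], dst[:, 0] * grid.n + dst[:, 1], intervals


class ModelContext:
    """Grid, tabulated surface, kernel and stationary field for one parameter set."""

    def __init__(self, params: ModelParameters, grid_n: int):
        self.params = params
        self.grid = build_grid(grid_n)
        self.surface = tabulate_potential(params, self.grid)
        self.kernel = build_kernel(self.surface, params.D)
        self.stationary = stationary_field(self.surface)

    def stationary_nll(self, x, floor: float) -> float:
        return -np.log(max(density_at(self.stationary, x), floor))

    def pairs_nll(self, pairs, options: LikelihoodOptions) -> float:
        """Sum of -ln conditional densities over a batch of pairs.

        Delta fields for all pairs are advanced jointly under the shared
        sparse update; each pair's density is harvested after its own step
        count k = max(1, round(interval / dt)).
        """
        if not len(pairs):
            return 0.0
        src_flat, dst_flat, intervals = pair_arrays(self.grid, pairs)
        return self.pairs_nll_arrays(src_flat, dst_flat, intervals, options)

    def pairs_nll_arrays(self, src_flat, dst_flat, intervals, options: LikelihoodOptions) -> float:
        """Batch evaluation from precomputed flat cell indices and gaps.

        Pairs sharing the same (source cell, step count) share one
        propagated column; only the density readout differs.
        """
        n = self.grid.n
        m = len(intervals)
        if m == 0:
            return 0.0
        inv_d2 = float(n * n)  # 1 / delta^2
        ks = np.maximum(1, np.rint(intervals / self.kernel.dt).astype(np.int64))
        if ks.max() > options.step_cap:
            return np.inf

        stride = int(ks.max()) + 1
        key = src_flat.astype(np.int64) * stride + ks
        uniq, inv = np.unique(key, return_inverse=True)
        u_src = uniq // stride
        u_k = uniq % stride
        nu = len(uniq)
        order = np.argsort(u_k, kind="stable")  # propagate shortest horizons first
        u_k_sorted = u_k[order]
        col_rank = np.empty(nu, dtype=np.int64)
        col_rank[order] = np.arange(nu)
        pair_col = col_rank[inv]  # k-sorted column of each pair

        active = np.zeros((n * n, nu))
        active[u_src[order], np.arange(nu)] = 1.0
        op = self.kernel.operator_csc
        densities = np.empty(m)
        ptr = 0  # columns harvested so far (in sorted order)
        base = 0  # columns sliced off the front of `active`
        step = 0
        while ptr < nu:
            step += 1
            active = op @ active
            done = int(np.searchsorted(u_k_sorted, step, side="right")) - ptr
            if done > 0:
                sel = (pair_col >= ptr) & (pair_col < ptr + done)
                densities[sel] = active[dst_flat[sel], pair_col[sel] - base] * inv_d2
                ptr += done
                # compact only when a decent fraction of columns is retired
                if ptr - base >= 0.25 * (nu - base):
                    active = np.ascontiguousarray(active[:, ptr - base:])
                    base = ptr
        return float(-np.log(np.maximum(densities, options.density_floor)).sum())

    def pairs_nll_uncached(self, pairs, options: LikelihoodOptions) -> float:
        """Reference path: each pair rebuilds its propagation independently."""
        total = 0.0
        for p in pairs:
            field = delta_field(self.grid, p.x_from)
            field, _ = propagate(field, self.kernel, p.interval)
            total += -np.log(max(density_at(field, p.x_to), options.density_floor))
        return total


def pair_neg_loglik(
    params: ModelParameters, x_from, x_to, interval: float,
    options: LikelihoodOptions = LikelihoodOptions(),
) -> float:
    """-ln of the conditional transition density p(x_to | x_from, interval)."""
    if not interval > 0:
        raise ValueError(f"interval must be positive, got {interval!r}")
    ctx = ModelContext(params, options.grid_n)
    pair = ObservationPair(tuple(np.asarray(x_from, float)), tuple(np.asarray(x_to, float)), interval)
    return ctx.pairs_nll([pair], options)


def evaluated_pairs(series: AffectTimeSeries, options: LikelihoodOptions):
    """The pairs and stationary-evaluated points the likelihood will use.

    Returns ``(pairs, stationary_points)``.  Invalid observations are
    dropped (their gaps are bridged); under ``skip_pairs`` pairs crossing a
    day change are omitted and the later point only conditions the next
    pair; under ``stationary_restart`` that later point is evaluated under
    the stationary density.  The series' very first valid point is handled
    by ``initial_mode``.
    """
    mask = series.valid
    t = series.t[mask]
    x = series.x[mask]
    day = series.day[mask]
    if len(t) == 0:
        raise ValueError("series has no valid observations")

    pairs: list[ObservationPair] = []
    stationary_points: list[tuple] = []
    if options.initial_mode == "stationary":
        stationary_points.append(tuple(x[0]))
    for j in range(1, len(t)):
        if day[j] != day[j - 1]:
            if options.night_mode == "stationary_restart":
                stationary_points.append(tuple(x[j]))
            continue
        pairs.append(ObservationPair(tuple(x[j - 1]), tuple(x[j]), float(t[j] - t[j - 1])))
    return pairs, stationary_points


def neg_log_likelihood(
    params: ModelParameters,
    series: AffectTimeSeries,
    options: LikelihoodOptions = LikelihoodOptions(),
) -> float:
    """Min-log-likelihood of ``params`` given ``series``.

    A non-finite intermediate result propagates as ``+inf`` so the global
    optimizer can reject the parameter set.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    pairs, stat_points = evaluated_pairs(series, options)
    return neg_log_likelihood_pairs(params, pairs, options, stationary_points=stat_points)


def neg_log_likelihood_pairs(
    params: ModelParameters,
    pairs,
    options: LikelihoodOptions = LikelihoodOptions(),
    stationary_points=(),
) -> float:
    """Min-log-likelihood of an explicit pair dataset (plus stationary terms)."""
    try:
        ctx = ModelContext(params, options.grid_n)
    except (ValueError, FloatingPointError):
        return np.inf
    if options.cache:
        total = ctx.pairs_nll(list(pairs), options)
    else:
        total = ctx.pairs_nll_uncached(list(pairs), options)
    for pt in stationary_points:
        total += ctx.stationary_nll(pt, options.density_floor)
    return total if np.isfinite(total) else np.inf
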