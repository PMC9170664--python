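# Methods

## The models

The package estimates bounded gradient-drift diffusion models of bivariate
affect.  The state `y(t) = (y1, y2)` — positive and negative affect on a
common 0–1 scale — evolves on the unit square according to

    dy_i = -D ∂F/∂y_i dt + sqrt(2 D) dW_i ,   i = 1, 2,

with uncorrelated Wiener processes `W_i`, diffusion constant `D > 0`
(units 1/hour throughout the package; unit conversions happen only at I/O)
and a free-energy surface `F(y)`.  Two surfaces are implemented:

* **Affective Ising Model (AIM)**

      F(y) = Σ_i [ -Λ_i y_i² + Θ_i y_i + N_i (y_i ln y_i + (1-y_i) ln(1-y_i)) ]
             + Λ₁₂ y₁ y₂

  with self-excitation `Λ_i ≥ 0`, thresholds `Θ_i ≥ 0`, entropy weights
  `N_i ≥ 0` and a signed cross-interaction `Λ₁₂` (positive values make the
  two dimensions mutually inhibiting).  The cross term is implemented as
  the product `y₁·y₂`, which is the form consistent with that
  interpretation.  The entropy terms diverge on the boundary, so the drift
  pushes the state back into the square; the free energy can have up to
  four local minima, producing multimodal and skewed affect distributions.

* **Bounded Ornstein–Uhlenbeck**: `F(y) = ½ (y-μ)ᵀ A (y-μ)` with attractor
  `μ` in the open unit square and symmetric positive-definite curvature
  `A`.  No parameterization is canonical for the bounded variant; this
  quadratic form was chosen because the interior dynamics are then exactly
  OU with drift `-D A (y-μ)`, giving closed-form transition moments

      mean(T) = μ + e^{-DAT}(y0-μ),    cov(T) = A⁻¹ (I - e^{-2DAT}),

  and stationary covariance `A⁻¹` — an analytic oracle for the numerical
  solver.  (Note the ½ in F: with `F = ½ a (y-μ)²` the per-dimension
  stationary variance is `1/a`, not `1/(2a)`.)

## The lattice propagator

The conditional density obeys the Fokker–Planck equation with no-flux
boundary conditions.  It is advanced on an `n × n` grid of square cells
(width `δ = 1/n`, centers at `((2m+1)δ/2, (2k+1)δ/2)` so no center touches
the singular boundary) by a Metropolis–Hastings random-walk update: each
step proposes stay/up/down/left/right with probability 1/5 each and accepts
a move with probability `min{1, exp(F_current - F_neighbor)}`.  A ghost
layer of cells with infinite free energy surrounds the grid; acceptance
toward a ghost cell is exactly zero (implemented by masking those
directions, never by arithmetic on infinities), which enforces zero flux
through the boundary.  Flux bookkeeping conserves total mass exactly and
the update satisfies detailed balance with respect to the discrete
Boltzmann field `π ∝ exp(-F)`, its stationary distribution.

Matching the flat-surface displacement variance `2δ²/5` per step to the
diffusion law `<Δy²> = 2DΔt` ties the time step to the grid:

    Δt = δ² / (5D).

Space and time resolution therefore cannot be chosen independently; finer
grids cost quadratically more cells *and* quadratically more steps.  The
default is `n = 30` (δ ≈ 0.033), which resolves self-report instruments
comfortably; `n` is a user parameter.

Numerical choices: double precision throughout; the update is assembled
once per parameter set as a sparse column-stochastic matrix; propagation
over a duration runs `k = max(1, round(duration/Δt))` updates (nearest
integer keeps the effective elapsed time closest to the request; the floor
of one step avoids treating distinct observations as simultaneous); cell
assignment of observations uses half-open cells `[mδ, (m+1)δ)` with points
at 1 clamped into the last cell.

## Likelihood

The likelihood of a parameter set given an irregular series is the product
of conditional transition densities between consecutive observations; the
package minimizes its negative logarithm.  Each pair contributes
`-ln max(density, floor)` where the density is the propagated mass of the
cell containing the next observation divided by `δ²` (no interpolation —
this matches the delta-initial-condition convention) and the floor
(`1e-300`) keeps the objective finite on zero-mass cells.  The first point
of a series can be scored under the stationary density or skipped; pairs
straddling a night (day-label change) are skipped by default, matching the
protocol of ignoring overnight dynamics — the day's first observation then
only conditions the next pair.  Missing observations are bridged from the
previous to the next valid observation.  Per parameter set, the tabulated
surface, kernel and stationary field are computed once; all pairs are
propagated as one batch of delta fields, with pairs sharing a (source
cell, step count) sharing a single propagated column.  A configurable step
cap (default 20,000 lattice steps for the longest gap) rejects
pathologically expensive parameter sets (very large D) with an infinite
objective.

## Optimization

The min-log-likelihood is multimodal, so a global heuristic is used:
differential evolution (rand/1/bin) with population size NP = 50,
crossover rate CR = 0.6, 1000 generations and differential weight 0.7 by
default.  The weight and the non-D priors are not pinned by any external
reference; defaults are exponential priors (means: Λ 2, Θ 2, N 1) and a
symmetric two-sided exponential for Λ₁₂ (scale 2) — nonnegative support
matching the constraints, tails heavy enough for a global search.
Children with infeasible coordinates are clipped to the feasible region
(D floored at 1e-8 to keep Δt finite).  The initial D is drawn from an
exponential with mean `5δ²/τ̄` (τ̄ = mean evaluated gap), so the expected
lattice step count per pair starts at 25: the early search favors cheap,
dynamical solutions over near-stationary ones, which are strong local
attractors and are expensive to evaluate.  Selection is greedy, so the
summed and best objectives never increase; everything is reproducible from
one seed.

## Synthetic experience-sampling data

The generator emulates a smartphone-based sampling design: `beeps_per_day`
(default 10) prompts placed by stratified random sampling in a daily
10:00–22:00 window (one uniform draw per equal stratum; mean within-day
gap 72 minutes), compliance 0.87 (each beep independently answered),
nights separating days.  Series are drawn from the model's own dynamics:
the first valid observation of a day from the stationary field (daily
restart; no overnight dynamics are simulated, consistent with the
skip-nights likelihood), later observations from the lattice-propagated
conditional of the previous one, with uniform jitter inside the sampled
cell (sub-cell placement is unspecified at cell resolution).  Recovery
experiments fit a base series and an enlarged dataset that redraws
`multiplier` endpoints from every base conditional density.

What the generator does *not* emulate: Likert discretization, measurement
error, response-time jitter, day-to-day nonstationarity, or person-level
heterogeneity.  Passing recovery tests therefore show the estimator is
correct under its own assumptions, not that real affect data satisfy them.

## Solver cross-validation

The accuracy study propagates, for each parameter set, a random initial
condition (continuous-uniform over the square — lattice-aligned starts
would artificially favor the grids they align with) to horizons
`t·(1/30)²/(5D)` for `t ∈ {5, 50, 100, 500}` with both the lattice solver
(grids 15–120, and 240 in a dedicated noise-floor check) and an
Euler–Maruyama endpoint histogram, rebins everything to the common 30×30
grid, and reports median L² and L∞ differences of cell masses (masses, not
densities, so the norm is grid-size-independent after rebinning).  The
Euler–Maruyama step is tied to the finest lattice step in the study; each
trajectory update adds `-D∇F dt + sqrt(2D dt) ξ` and clamps coordinates
into `[ε, 1-ε]` (ε = 1e-6).  Clamping was chosen over reflection because
under the diverging inward drift near the wall, reflection perturbs the
process more than a clamp at the reference step size.  At 10⁵ trajectories
the Monte-Carlo noise floor of the reference histogram is L² ≈ 4e-3;
lattice errors at n ≥ 30 reach that floor at the longer horizons, so
differences between fine grids there measure shared sampling noise rather
than discretization error (the paired n=240 check makes this floor
explicit).

## Problem sizes used in the test suite

Desk-scale settings keep the full suite within minutes while preserving
each qualitative contrast: the cross-validation study uses 5 prior-drawn
AIM parameter sets and 10⁵ trajectories; the recovery study uses a single
realistic truth (D = 0.006/h, i.e. a few tens of lattice steps per typical
gap — the regime the D-prior calibration targets) with one 600-observation
fit at NP = 20, 200 generations, and ten replicates of a 5-day base versus
16-fold enlarged comparison at NP = 12, 120 generations (the smaller base
and larger multiplier give the error contrast enough statistical power at
ten replicates).

## Known limitations

* Likelihood densities are evaluated at cell resolution; observations less
  than δ apart are indistinguishable.
* The step cap makes the objective formally infinite for extremely fast
  (large-D) parameter sets; fits to data genuinely near stationarity
  should raise `step_cap` and expect long runtimes.
* No standard errors or confidence intervals are produced.
* Single-person series only; no hierarchical pooling across persons.
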