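# affectdiffusion

Maximum-likelihood estimation for bounded gradient-drift diffusion models
of bivariate affect dynamics.

Experience-sampling studies prompt people several times a day to rate their
momentary positive and negative affect, yielding short, irregularly spaced
bivariate time series on a bounded scale.  The **Affective Ising Model
(AIM)** describes such data as a continuous-time diffusion on the unit
square,

    dy_i = -D ∂F(y)/∂y_i dt + √(2D) dW_i ,      i = 1, 2,

where the free energy

    F(y) = Σ_i [ -Λ_i y_i² + Θ_i y_i + N_i (y_i ln y_i + (1-y_i) ln(1-y_i)) ] + Λ₁₂ y₁ y₂

combines self-excitation (Λ_i), thresholds (Θ_i), entropy (N_i) and a
cross-interaction (Λ₁₂); `D` sets the time scale.  The model produces the
multimodal, skewed and V-shaped affect distributions seen in real data,
but its likelihood has no closed form: every pair of consecutive
observations requires solving the model's Fokker–Planck equation.

This package provides, for the AIM and a bounded Ornstein–Uhlenbeck
variant:

* a **Metropolis–Hastings lattice solver** for the Fokker–Planck equation
  with ghost-cell no-flux boundaries (step size law `Δt = δ²/(5D)`),
  including the stationary Boltzmann field `π ∝ e^{-F}`;
* a **min-log-likelihood** assembled from lattice-propagated conditional
  densities, with night handling and gap bridging for missed prompts;
* a **differential-evolution** (rand/1/bin) global optimizer with a
  schedule-calibrated prior for `D`, exposed both functionally and as the
  scikit-learn style estimator `GradientDiffusionMLE`;
* an **Euler–Maruyama trajectory simulator** as an independent Monte-Carlo
  oracle, and a **solver cross-validation** study across grid sizes;
* a **synthetic experience-sampling generator** (stratified 10-beep days,
  10:00–22:00 window, 87% compliance) and **parameter-recovery**
  experiments.

It is intended for affect researchers fitting nonlinear diffusion models
to single-person ESM series, and for methodologists studying such
estimators.  See `docs/methods.md` for the numerical details.

## Worked example

Simulate two weeks of experience sampling from a known AIM and re-estimate
its parameters:

```python
import numpy as np
from affectdiffusion import (AIMParameters, GradientDiffusionMLE,
                             build_grid, neg_log_likelihood)
from affectdiffusion.esm import ScheduleConfig, esm_schedule, simulate_series

truth = AIMParameters(lambda1=3.0, lambda2=2.0, lambda12=4.0,
                      theta1=1.0, theta2=2.0, n1=1.2, n2=0.8, D=0.006)
rng = np.random.default_rng(0)
schedule = esm_schedule(ScheduleConfig(days=14), rng)
series = simulate_series(truth, schedule, build_grid(30), rng)
print(f"{series.n_valid} valid observations over 14 days")
print(f"NLL at the true parameters: {neg_log_likelihood(truth, series):.2f}")

est = GradientDiffusionMLE(pop_size=20, generations=150, random_state=1)
est.fit(series)
print(f"fitted NLL: {est.nll_:.2f} after {est.n_evaluations_} evaluations")
print(f"D-hat = {est.params_.D:.5f} (truth 0.006)")
```

prints

```
110 valid observations over 14 days
NLL at the true parameters: -187.85
fitted NLL: -190.88 after 3020 evaluations
D-hat = 0.00600 (truth 0.006)
```

The fitted min-log-likelihood lies slightly below the value at the truth —
the maximum-likelihood optimum always dominates the generating parameters
— and the time-scale parameter `D` is recovered accurately even from a
two-week series.  Fourteen days of ten prompts at 87% compliance give ~110
usable observations; the negative NLL simply means densities above 1 on
the unit square.

A command-line interface covers the same pipeline:
`affectdiffusion simulate | fit | loglik | stationary | compare-solvers |
recover` (all commands take `--seed` and `--grid-n`; see `--help`).

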