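"""Free-energy surfaces for bounded gradient-drift diffusion models.

Two models are provided:

* the Affective Ising Model (AIM), a nonlinear model of bivariate affect
  (positive/negative) on the open unit square with self-excitation,
  threshold, entropy and cross-interaction terms;
* a bounded Ornstein-Uhlenbeck (OU) variant with a quadratic potential,
  whose interior dynamics admit a Gaussian transition density and therefore
  serve as a closed-form oracle.

The state ``y = (y1, y2)`` lives in the open unit square; the free energy
``F(y)`` is the potential whose negative gradient (scaled by the diffusion
constant ``D``) drives the drift of the stochastic dynamics

    dy_i = -D * dF/dy_i dt + sqrt(2 D) dW_i .

The AIM free energy is

    F(y) = sum_i [ -Lam_i y_i^2 + Th_i y_i
                   + N_i (y_i ln y_i + (1 - y_i) ln(1 - y_i)) ]
           + Lam_12 * y_1 * y_2 ,

where the cross-interaction term is the product of the two coordinates:
positive ``Lam_12`` makes the two dimensions mutually inhibiting.  The
entropy terms make the gradient diverge on the boundary, which keeps the
state inside the square.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Union

import numpy as np

__all__ = [
    "AIMParameters",
    "BoundedOUParameters",
    "ModelParameters",
    "PotentialSurface",
    "free_energy",
    "free_energy_gradient",
    "tabulate_potential",
    "params_from_dict",
    "params_from_json",
    "params_to_json",
]

#: fixed flat-vector order of the AIM parameters used by the optimizer
AIM_VECTOR_ORDER = ("lambda1", "lambda2", "lambda12", "theta1", "theta2", "n1", "n2", "D")

#: flat-vector order of the bounded-OU parameters
OU_VECTOR_ORDER = ("mu1", "mu2", "a11", "a22", "a12", "D")


@dataclass(frozen=True)
class AIMParameters:
    """The eight parameters of the Affective Ising Model.

    ``lambda1``/``lambda2`` are nonnegative self-excitation strengths,
    ``lambda12`` the (signed) cross-interaction, ``theta1``/``theta2``
    nonnegative thresholds, ``n1``/``n2`` nonnegative entropy weights and
    ``D`` the positive diffusion constant (units 1/time; hours throughout
    this package).
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    lambda12: float = 0.0
    theta1: float = 0.0
    theta2: float = 0.0
    n1: float = 0.0
    n2: float = 0.0
    D: float = 1.0

    model_id = "AIM"

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "theta1", "theta2", "n1", "n2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)!r}")
        if not self.D > 0:
            raise ValueError(f"D must be positive, got {self.D!r}")

    def to_vector(self) -> np.ndarray:
        """Serialize to the fixed flat order (Λ1, Λ2, Λ12, Θ1, Θ2, N1, N2, D)."""
        return np.array([getattr(self, f) for f in AIM_VECTOR_ORDER], dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "AIMParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (8,):
            raise ValueError(f"AIM parameter vector must have 8 entries, got shape {vec.shape}")
        return cls(**dict(zip(AIM_VECTOR_ORDER, vec)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model_id"] = self.model_id
        return d

    def replace(self, **kwargs) -> "AIMParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BoundedOUParameters:
    """Bounded Ornstein-Uhlenbeck model: quadratic potential on the unit square.

    ``F(y) = 0.5 (y - mu)^T A (y - mu)`` with attractor ``mu`` in the open
    unit square and symmetric positive-definite curvature
    ``A = [[a11, a12], [a12, a22]]``.  The interior dynamics are exactly OU
    with drift ``-D A (y - mu)`` and stationary covariance ``A^{-1}``.
    """

    mu1: float = 0.5
    mu2: float = 0.5
    a11: float = 1.0
    a22: float = 1.0
    a12: float = 0.0
    D: float = 1.0

    model_id = "boundedOU"

    def __post_init__(self) -> None:
        if not (0.0 < self.mu1 < 1.0 and 0.0 < self.mu2 < 1.0):
            raise ValueError("attractor mu must lie in the open unit square")
        if not (self.a11 > 0 and self.a22 > 0 and self.a11 * self.a22 - self.a12 ** 2 > 0):
            raise ValueError("curvature matrix must be positive definite")
        if not self.D > 0:
            raise ValueError(f"D must be positive, got {self.D!r}")

    @property
    def mu(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2])

    @property
    def A(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a12, self.a22]])

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in OU_VECTOR_ORDER], dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "BoundedOUParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (6,):
            raise ValueError(f"OU parameter vector must have 6 entries, got shape {vec.shape}")
        return cls(**dict(zip(OU_VECTOR_ORDER, vec)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model_id"] = self.model_id
        return d

    def replace(self, **kwargs) -> "BoundedOUParameters":
        return replace(self, **kwargs)


ModelParameters = Union[AIMParameters, BoundedOUParameters]


def params_from_dict(d: dict) -> ModelParameters:
    """Reconstruct a parameter record from a dict with a ``model_id`` field."""
    d = dict(d)
    model_id = d.pop("model_id", "AIM")
    if model_id == "AIM":
        return AIMParameters(**d)
    if model_id == "boundedOU":
        return BoundedOUParameters(**d)
    raise ValueError(f"unknown model_id {model_id!r}")


def params_to_json(params: ModelParameters) -> str:
    return json.dumps(params.to_dict(), indent=1)


def params_from_json(text: str) -> ModelParameters:
    return params_from_dict(json.loads(text))


def _check_interior(y: np.ndarray) -> None:
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("point must lie strictly inside the unit square")


def free_energy(y, params: ModelParameters):
    """Evaluate the free energy F(y) at interior point(s) ``y``.

    ``y`` may be a single 2-vector or an array of shape (..., 2); every
    coordinate must lie strictly inside (0, 1) because the AIM entropy
    terms are undefined on the boundary.
    """
    y = np.asarray(y, dtype=float)
    _check_interior(y)
    y1, y2 = y[..., 0], y[..., 1]
    if params.model_id == "AIM":
        f = (
            -params.lambda1 * y1 ** 2 + params.theta1 * y1
            + params.n1 * (y1 * np.log(y1) + (1 - y1) * np.log(1 - y1))
            - params.lambda2 * y2 ** 2 + params.theta2 * y2
            + params.n2 * (y2 * np.log(y2) + (1 - y2) * np.log(1 - y2))
            + params.lambda12 * y1 * y2
        )
    else:
        d1, d2 = y1 - params.mu1, y2 - params.mu2
        f = 0.5 * (params.a11 * d1 ** 2 + 2 * params.a12 * d1 * d2 + params.a22 * d2 ** 2)
    return f if f.ndim else float(f)


def free_energy_gradient(y, params: ModelParameters):
    """Analytic gradient of the free energy at interior point(s) ``y``."""
    y = np.asarray(y, dtype=float)
    _check_interior(y)
    y1, y2 = y[..., 0], y[..., 1]
    if params.model_id == "AIM":
        g1 = (-2 * params.lambda1 * y1 + params.theta1
              + params.n1 * np.log(y1 / (1 - y1)) + params.lambda12 * y2)
        g2 = (-2 * params.lambda2 * y2 + params.theta2
              + params.n2 * np.log(y2 / (1 - y2)) + params.lambda12 * y1)
    else:
        d1, d2 = y1 - params.mu1, y2 - params.mu2
        g1 = params.a11 * d1 + params.a12 * d2
        g2 = params.a12 * d1 + params.a22 * d2
    return np.stack([g1, g2], axis=-1)


@dataclass(frozen=True)
class PotentialSurface:
    """The free energy tabulated at the cell centers of an affect grid.

    ``values`` has shape (n+2, n+2): the interior block ``values[1:-1, 1:-1]``
    holds F at the interior cell centers; the surrounding ghost layer carries
    ``+inf`` as the infinity sentinel (no acceptance arithmetic is ever done
    on the sentinel itself; the transition kernel masks ghost directions).
    """

    grid: "AffectGrid"  # noqa: F821 - forward ref, see affectdiffusion.grid
    values: np.ndarray
    params: ModelParameters

    @property
    def interior(self) -> np.ndarray:
        return self.values[1:-1, 1:-1]


def tabulate_potential(params: ModelParameters, grid) -> PotentialSurface:
    """Tabulate F at every interior cell center; ghost cells get ``+inf``."""
    c1, c2 = grid.centers()
    pts = np.stack(np.meshgrid(c1, c2, indexing="ij"), axis=-1)
    values = np.full((grid.n + 2, grid.n + 2), np.inf)
    values[1:-1, 1:-1] = free_energy(pts, params)
    values.setflags(write=False)
    return PotentialSurface(grid=grid, values=values, params=params)
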