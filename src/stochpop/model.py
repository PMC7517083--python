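"""Domain types and closed-form results for the Verhulst/logistic population model.

The deterministic model is ``dX/dt = a X - eps X^2`` with growth rate ``a``
(birth minus death rate), nonlinear loss coefficient ``eps`` and carrying
capacity ``L = a / eps``.  Its stochastic counterpart adds multiplicative
environmental noise, ``dX = (a X - eps X^2) dt + lam X dW``, and optionally a
random growth rate ``a(omega) = a0 + a1 * psi1`` driven by a uniform random
variable.  This module holds the parameter containers, the exact deterministic
solutions (logistic and Richards), the stationary gamma-law moments of the
noisy model, and the exact geometric-Brownian-motion moments of the linear
(eps = 0) model that serve as analytic oracles for the spectral solvers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Regime",
    "ModelParams",
    "TimeGrid",
    "exact_logistic",
    "exact_richards",
    "stationary_gamma_moments",
    "linear_model_moments",
]


class Regime(enum.Enum):
    """Long-run behaviour of the noisy logistic model.

    The comparison is between the growth rate ``a0`` and ``lam^2 / 2``:
    above it the process is recurrent with a stationary gamma law, below it
    the population goes extinct almost surely, and equality is the
    noise-induced transition point.  The comparison is exact (tolerance 0);
    the transition case is measure-zero and informational only.
    """

    PERSISTENT = "persistent"
    EXTINCTION = "extinction"
    TRANSITION = "transition"


@dataclass(frozen=True)
class ModelParams:
    """Coefficients and initial condition of the population SDE.

    Parameters
    ----------
    a0 : float
        Mean growth rate (1/time).
    eps : float
        Nonlinear loss coefficient (1/(time*population)).  ``eps = 0`` is
        accepted and yields the linear (pure exponential / GBM) model; the
        closed-form logistic results then do not apply.
    lam : float
        Diffusion coefficient of the multiplicative noise (1/sqrt(time)).
    x0 : float
        Initial population (> 0).
    a1 : float
        Growth-rate randomness amplitude (1/time).  Zero means the growth
        rate is deterministic.  How ``a1`` maps onto the distribution of
        ``a`` is decided by the polynomial-chaos layer's basis convention
        (coefficient of the chaos polynomial vs. uniform half-width).
    """

    a0: float
    eps: float
    x0: float
    lam: float = 0.0
    a1: float = 0.0

    def __post_init__(self) -> None:
        if not self.eps >= 0.0:
            raise ValueError(f"eps must be >= 0, got {self.eps}")
        if not self.x0 > 0.0:
            raise ValueError(f"x0 must be > 0, got {self.x0}")
        if not self.lam >= 0.0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not self.a1 >= 0.0:
            raise ValueError(f"a1 must be >= 0, got {self.a1}")

    @property
    def carrying_capacity(self) -> float:
        """Carrying capacity ``L = a0 / eps`` (+inf for the linear model)."""
        if self.eps == 0.0:
            return math.inf
        return self.a0 / self.eps

    @property
    def regime(self) -> Regime:
        if self.a0 > 0.5 * self.lam**2:
            return Regime.PERSISTENT
        if self.a0 < 0.5 * self.lam**2:
            return Regime.EXTINCTION
        return Regime.TRANSITION


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid ``t_i = i * dt`` for ``i = 0..n_steps``.

    Kernel fields on this grid are causal: any kernel value whose noise-time
    argument exceeds the current time is identically zero.  The solver
    stability bound ``dt < 1/a0`` is checked at solver entry, not here.
    """

    dt: float
    n_steps: int

    def __post_init__(self) -> None:
        if not self.dt > 0.0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")

    @classmethod
    def from_horizon(cls, dt: float, t_end: float) -> "TimeGrid":
        """Grid covering ``[0, t_end]`` with step ``dt`` (rounded step count)."""
        return cls(dt=dt, n_steps=int(round(t_end / dt)))

    @property
    def t_end(self) -> float:
        return self.n_steps * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt


def exact_logistic(params: ModelParams, t) -> np.ndarray | float:
    """Exact solution of the deterministic logistic ODE ``dX/dt = aX - eps X^2``.

    ``X(t) = L / (1 + (L/x0 - 1) e^{-a t})`` with ``L = a0/eps``.  Monotone in
    ``t``; tends to ``L`` for ``a0 > 0`` and to 0 for ``a0 < 0``.  The noise
    and growth-rate-randomness parameters are ignored.
    """
    if params.a0 == 0.0:
        raise ValueError("exact_logistic is degenerate at a0 = 0")
    if params.eps == 0.0:
        raise ValueError("exact_logistic requires eps > 0 (use the linear model otherwise)")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    L = params.carrying_capacity
    out = L / (1.0 + (L / params.x0 - 1.0) * np.exp(-params.a0 * t))
    return out if out.ndim else float(out)


def exact_richards(params: ModelParams, beta: float, t) -> np.ndarray | float:
    """Exact solution of the Richards model ``dX/dt = aX - eps X^beta``.

    The allometric exponent ``beta`` reshapes the approach to equilibrium;
    ``beta = 2`` recovers the Verhulst/logistic model exactly.  The equation
    is of Bernoulli type: with ``u = X^{1-beta}`` it linearizes and

    ``X(t) = [eps/a + (x0^{1-beta} - eps/a) e^{-(beta-1) a t}]^{-1/(beta-1)}``.

    The equilibrium is ``(a/eps)^{1/(beta-1)}``; it is independent of ``beta``
    when the loss coefficient is tied to a fixed carrying capacity ``L``
    through ``eps = a / L^{beta-1}``.
    """
    if beta == 1.0:
        raise ValueError("beta = 1 collapses the loss term into the growth rate")
    if beta <= 0.0:
        raise ValueError(f"beta must be > 0, got {beta}")
    if params.a0 == 0.0:
        raise ValueError("exact_richards is degenerate at a0 = 0")
    if params.eps == 0.0:
        raise ValueError("exact_richards requires eps > 0")
    t = np.asarray(t, dtype=float)
    a, eps, x0 = params.a0, params.eps, params.x0
    u0 = x0 ** (1.0 - beta)
    u = eps / a + (u0 - eps / a) * np.exp(-(beta - 1.0) * a * t)
    out = u ** (-1.0 / (beta - 1.0))
    return out if out.ndim else float(out)


def stationary_gamma_moments(params: ModelParams) -> tuple[float, float]:
    """Mean and variance of the stationary gamma law of the noisy logistic SDE.

    In the persistent regime (``a0 > lam^2/2``) the process converges to a
    gamma distribution with shape ``2 a0/lam^2 - 1`` and scale
    ``lam^2/(2 eps)``, so the mean is ``a0/eps - lam^2/(2 eps)`` and the
    variance ``shape * scale^2``.  In the deterministic limit ``lam -> 0``
    the mean tends to the carrying capacity and the variance to zero.
    """
    if params.a1 != 0.0:
        raise ValueError("stationary gamma law holds for deterministic growth rate (a1 = 0)")
    if params.eps == 0.0:
        raise ValueError("stationary gamma law requires eps > 0")
    if params.lam == 0.0:
        return params.carrying_capacity, 0.0
    if params.regime is not Regime.PERSISTENT:
        raise ValueError("no stationary gamma distribution in this regime (a0 <= lam^2/2)")
    shape = 2.0 * params.a0 / params.lam**2 - 1.0
    scale = params.lam**2 / (2.0 * params.eps)
    return shape * scale, shape * scale**2


def linear_model_moments(a: float, lam: float, x0: float, t) -> tuple:
    """Exact moments of the linear model ``dX = aX dt + lam X dW`` (GBM).

    ``E[X] = x0 e^{a t}`` and ``Var[X] = x0^2 e^{2 a t} (e^{lam^2 t} - 1)``;
    the small-noise limit ``Var ~ lam^2 t x0^2 e^{2 a t}`` is the first-order
    Wiener-Hermite (Gaussian-kernel) variance and serves as the oracle for
    the spectral solver in the eps = 0 reduction.
    """
    t = np.asarray(t, dtype=float)
    mean = x0 * np.exp(a * t)
    var = x0**2 * np.exp(2.0 * a * t) * np.expm1(lam**2 * t)
    if t.ndim:
        return mean, var
    return float(mean), float(var)
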