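"""Second-order Wiener-Hermite expansion (WHE) solver for the stochastic
logistic SDE ``dX = (a X - eps X^2) dt + lam X dW`` with deterministic
parameters.

The solution is expanded in iterated Wiener integrals with deterministic
kernels: ``x^(0)(t)`` (the mean), ``x^(1)(t, t1)`` (the Gaussian part) and
``x^(2)(t, t1, t2)`` (the leading nonGaussian correction).  Projecting the
SDE on the Hermite functionals gives a closed deterministic system for the
kernels, advanced here by an explicit first-order finite-difference scheme:

* the mean kernel sees the nonlinear loss of its own square plus the
  variance integrals ``I1 = int (x^(1))^2 dt1`` and twice
  ``int int (x^(2))^2 dt1 dt2``;
* the first kernel is forced by ``lam * x^(0)`` on the diagonal ``t = t1``
  (the discrete image of the Dirac delta) and damped by ``2 eps x^(0)``;
* the second kernel is forced by ``-eps x^(1)(t1) x^(1)(t2)`` and by the
  diagonal jump ``lam * x^(1)`` at ``t = t2``, and is kept symmetric in
  ``(t1, t2)`` by explicit symmetrization after each step.

All kernel square-integrals use Delta t-weighted midpoint sums over the
causal support (kernels vanish for noise times beyond the current time).

Variance convention: the Wiener-Ito identity gives
``Var[X] = int (x^(1))^2 dt1 + 2 int int (x^(2))^2 dt1 dt2``, i.e. the
second-order kernel enters with the combinatorial weight 2! = 2.  The
reported ``var_nongaussian`` carries that weight so that
``var_total = var_gaussian + var_nongaussian`` holds identically; the
unweighted integral ``int int (x^(2))^2`` is kept alongside as
``nongauss_kernel_integral`` because published steady-state tables list the
second-order kernel integral without the weight.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams, TimeGrid

__all__ = [
    "max_stable_dt",
    "WHEKernels",
    "WHEMoments",
    "SteadyState",
    "whe_step",
    "whe_solve",
    "nongaussian_fraction",
]

#: relative tolerance of the steady-state convergence check
CONVERGENCE_RTOL = 1e-5
#: trailing fraction of the run over which convergence is measured
CONVERGENCE_WINDOW = 0.1


def max_stable_dt(params: ModelParams) -> float:
    """Sufficient stability bound ``dt < 1/a0`` of the explicit kernel scheme.

    The bound comes from the contraction condition of the mean-kernel update
    at the carrying capacity (where the effective damping is ``-a0``).  For
    ``a0 <= 0`` there is no growth-regime bound; ``+inf`` is returned with a
    warning so callers can still run decay scenarios.
    """
    if params.a0 > 0.0:
        return 1.0 / params.a0
    warnings.warn(
        "stability bound dt < 1/a0 is derived for the growth regime (a0 > 0); "
        "no finite bound returned",
        stacklevel=2,
    )
    return math.inf


@dataclass
class SteadyState:
    """Final-time moments of a run plus a convergence flag."""

    mean: float
    var_total: float
    var_gaussian: float
    var_nongaussian: float
    converged: bool


@dataclass
class WHEKernels:
    """Kernel state of the second-order WHE scheme on a :class:`TimeGrid`.

    ``x0`` holds the mean-kernel trajectory up to the current step ``i``;
    ``x1`` and ``x2`` hold the first/second kernels at the *current* time
    level only (their full histories are not needed for the moments).  The
    full ``(t, t1)`` history of the first kernel is recorded when
    ``keep_history`` is set.
    """

    grid: TimeGrid
    keep_history: bool = False
    i: int = 0
    x0: np.ndarray = field(init=False)
    x1: np.ndarray = field(init=False)
    x2: np.ndarray = field(init=False)
    x1_history: np.ndarray | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        m = self.grid.n_steps + 1
        self.x0 = np.zeros(m)
        self.x1 = np.zeros(m)
        self.x2 = np.zeros((m, m))
        if self.keep_history:
            self.x1_history = np.zeros((m, m))

    @classmethod
    def initial(cls, params: ModelParams, grid: TimeGrid, keep_history: bool = False) -> "WHEKernels":
        """Initial state: ``x^(0)(0) = x0``, higher kernels identically zero."""
        k = cls(grid=grid, keep_history=keep_history)
        k.x0[0] = params.x0
        return k

    def variance_integrals(self) -> tuple[float, float]:
        """``(I1, K2)`` = ``(int (x^(1))^2 dt1, int int (x^(2))^2 dt1 dt2)``
        at the current time level (midpoint sums over the causal support)."""
        dt = self.grid.dt
        s = slice(0, self.i + 1)
        u = self.x1[s]
        V = self.x2[s, s]
        with np.errstate(over="ignore", invalid="ignore"):
            return float(dt * (u @ u)), float(dt * dt * np.sum(V * V))


def whe_step(kernels: WHEKernels, params: ModelParams, grid: TimeGrid, i: int) -> WHEKernels:
    """Advance all three kernels one step, from time level ``i`` to ``i + 1``.

    The update is explicit: every right-hand-side term is evaluated at level
    ``i``.  The Dirac forcings are realized as Delta t-independent jumps on
    the diagonal (``lam x^(0)_i`` into ``x^(1)`` at ``t1 = t_i``;
    ``lam x^(1)_{i,j}`` into ``x^(2)`` at ``t2 = t_i``, symmetrized).  The
    state is modified in place and returned.
    """
    if i != kernels.i:
        raise ValueError(f"kernel state is at level {kernels.i}, cannot step level {i}")
    if i >= grid.n_steps:
        raise ValueError("grid exhausted")
    a, eps, lam = params.a0, params.eps, params.lam
    dt = grid.dt
    s = slice(0, i + 1)
    cur = kernels.x0[i]
    u = kernels.x1[s]
    V = kernels.x2[s, s]

    with np.errstate(over="ignore", invalid="ignore"):
        I1, K2 = kernels.variance_integrals()
        new0 = cur + dt * (a * cur - eps * (cur * cur + I1 + 2.0 * K2))

        damp = a - 2.0 * eps * cur
        I12 = dt * (V @ u)  # int x^(1)(t2) x^(2)(t1, t2) dt2, using symmetry of x^(2)
        new_u = u + dt * (damp * u - 4.0 * eps * I12)
        new_V = V + dt * (damp * V - eps * np.outer(u, u))

    # second kernel first: its delta forcing uses the level-i first kernel
    # (u is a view into x1, so x2 must be written before x1 is overwritten)
    kernels.x2[s, s] = new_V
    # delta forcing lam * x^(1) on the t2 = t_i line, then symmetrization
    kernels.x2[s, i] += 0.5 * lam * u
    kernels.x2[i, s] += 0.5 * lam * u
    kernels.x1[s] = new_u
    kernels.x1[i] += lam * cur

    kernels.x0[i + 1] = new0
    kernels.i = i + 1
    if kernels.x1_history is not None:
        kernels.x1_history[i + 1, : i + 2] = kernels.x1[: i + 2]
    if not (np.isfinite(new0) and np.all(np.isfinite(kernels.x1[s]))):
        raise FloatingPointError("FDM diverged; reduce dt")
    return kernels


@dataclass
class WHEMoments:
    """Moment time series of a WHE run.

    ``var_total = var_gaussian + var_nongaussian`` at every time;
    ``nongauss_kernel_integral`` is the unweighted ``int int (x^(2))^2``.
    """

    t: np.ndarray
    mean: np.ndarray
    var_total: np.ndarray
    var_gaussian: np.ndarray
    var_nongaussian: np.ndarray
    nongauss_kernel_integral: np.ndarray
    steady_state: SteadyState

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "mean": self.mean,
                "var_total": self.var_total,
                "var_gaussian": self.var_gaussian,
                "var_nongaussian": self.var_nongaussian,
                "nongauss_kernel_integral": self.nongauss_kernel_integral,
            }
        )


def _is_converged(series: np.ndarray, window: int, rtol: float = CONVERGENCE_RTOL) -> bool:
    tail = series[-window:]
    scale = max(abs(float(series[-1])), 1e-300)
    return float(tail.max() - tail.min()) / scale < rtol


def check_stability(params: ModelParams, grid: TimeGrid) -> None:
    bound = max_stable_dt(params) if params.a0 > 0.0 else math.inf
    if grid.dt >= bound:
        raise ValueError(
            f"dt = {grid.dt} violates the stability bound dt < 1/a0 = {bound}"
        )


def whe_solve(
    params: ModelParams,
    grid: TimeGrid,
    keep_kernels: bool = False,
) -> tuple[WHEKernels, WHEMoments]:
    """Run the second-order WHE scheme over the whole grid.

    Requires a deterministic growth rate (``a1 = 0``; random parameters are
    handled by the polynomial-chaos layer) and ``dt`` below the stability
    bound.  Returns the final kernel state and the moment time series; the
    steady-state record flags convergence when the relative change of both
    the mean and the total variance over the trailing 10% of the run is
    below 1e-5.
    """
    if params.a1 != 0.0:
        raise ValueError("whe_solve requires a1 = 0 (use gpc_whe_solve for a random growth rate)")
    check_stability(params, grid)

    n = grid.n_steps
    kernels = WHEKernels.initial(params, grid, keep_history=keep_kernels)
    I1 = np.zeros(n + 1)
    K2 = np.zeros(n + 1)
    for i in range(n):
        I1[i], K2[i] = kernels.variance_integrals()
        whe_step(kernels, params, grid, i)
    I1[n], K2[n] = kernels.variance_integrals()

    var_gauss = I1
    var_nongauss = 2.0 * K2
    var_total = var_gauss + var_nongauss
    window = max(2, n // 10)
    converged = _is_converged(kernels.x0, window) and _is_converged(var_total, window)
    moments = WHEMoments(
        t=grid.times,
        mean=kernels.x0.copy(),
        var_total=var_total,
        var_gaussian=var_gauss,
        var_nongaussian=var_nongauss,
        nongauss_kernel_integral=K2,
        steady_state=SteadyState(
            mean=float(kernels.x0[-1]),
            var_total=float(var_total[-1]),
            var_gaussian=float(var_gauss[-1]),
            var_nongaussian=float(var_nongauss[-1]),
            converged=converged,
        ),
    )
    return kernels, moments


def nongaussian_fraction(moments: WHEMoments) -> np.ndarray:
    """Share ``var_nongaussian / var_total`` per time point, in ``[0, 1]``.

    Times with zero total variance (e.g. ``t = 0`` or a noise-free run) get
    a fraction of 0.
    """
    out = np.zeros_like(moments.var_total)
    nz = moments.var_total > 0.0
    out[nz] = moments.var_nongaussian[nz] / moments.var_total[nz]
    return out
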