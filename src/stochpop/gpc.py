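"""Generalized polynomial chaos (gPC) layer and the coupled gPC-WHE system.

A uniformly distributed random growth rate ``a(omega)`` is expanded in
orthonormal Legendre chaos, ``a = a0 + a1 * psi1``, and every Wiener-Hermite
kernel is expanded in the same basis, ``x^(j) = sum_k x_k^(j) psi_k``.
Galerkin projection on the chaos basis (using ``<psi_i psi_j> = delta_ij``
and the triple products ``c_ijk = <psi_i psi_j psi_k>``) turns the
stochastic kernel system into a closed deterministic system for the doubly
indexed kernels ``x_k^(j)``, advanced with the same explicit
finite-difference, Dirac-jump and midpoint-integration conventions as the
pure-noise solver.  The implemented case is one random variable and chaos
order P = 1 (the equations are hard-coded from the projected system; higher
orders raise ``NotImplementedError``).

Basis convention.  Two interpretations of ``a1`` are supported:

* ``"coefficient"`` (default): ``a1`` is the coefficient multiplying the
  *orthonormal* first chaos polynomial, exactly as the coupled equations
  are written.  This is the convention under which the published
  steady-state variances and sensitivity tables for this model are
  reproduced; the implied distribution of ``a`` is uniform with half-width
  ``sqrt(3) * a1``.
* ``"half_width"``: ``a1`` is the half-width ``d`` of
  ``a ~ U[a0 - d, a0 + d]``; internally the orthonormal coefficient is
  ``d / sqrt(3)`` so that ``Var[a] = d^2 / 3``.  This is the
  probabilistically faithful choice and the one cross-validated against
  nested Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelParams, TimeGrid
from .whe import _is_converged, check_stability

__all__ = [
    "legendre_orthonormal",
    "triple_product_table",
    "GPCBasis",
    "GPCWHEKernels",
    "gpc_whe_solve",
    "CONVENTIONS",
]

SQRT3 = np.sqrt(3.0)
CONVENTIONS = ("coefficient", "half_width")


def legendre_orthonormal(k: int, z) -> np.ndarray | float:
    """Degree-``k`` Legendre polynomial, orthonormal under ``U[-1, 1]``.

    ``psi_k(z) = sqrt(2k + 1) P_k(z)`` so that ``E[psi_j psi_k] = delta_jk``
    with expectation over the uniform density ``1/2`` on ``[-1, 1]``.
    """
    if k < 0:
        raise ValueError("polynomial degree must be >= 0")
    z = np.asarray(z, dtype=float)
    if np.any(np.abs(z) > 1.0):
        raise ValueError("the chaos variable lives on [-1, 1]")
    coeffs = np.zeros(k + 1)
    coeffs[k] = 1.0
    out = np.sqrt(2.0 * k + 1.0) * np.polynomial.legendre.legval(z, coeffs)
    return out if out.ndim else float(out)


def triple_product_table(P: int) -> np.ndarray:
    """Triple products ``c_ijk = E[psi_i psi_j psi_k]`` for ``i,j,k <= P``.

    Computed by Gauss-Legendre quadrature, which is exact for the polynomial
    integrands involved.  The table is symmetric under any index permutation
    and satisfies ``c_0jk = delta_jk``.
    """
    if not 0 <= P <= 4:
        raise ValueError("triple products precomputed for chaos order P <= 4")
    nodes, weights = np.polynomial.legendre.leggauss(3 * P // 2 + 2)
    weights = weights / 2.0  # uniform density on [-1, 1]
    psi = np.stack([legendre_orthonormal(k, nodes) for k in range(P + 1)])
    return np.einsum("q,iq,jq,kq->ijk", weights, psi, psi, psi)


@dataclass(frozen=True)
class GPCBasis:
    """Orthonormal Legendre chaos basis of order ``P`` for one uniform variable."""

    P: int
    distribution: str = "uniform"

    @property
    def triple_products(self) -> np.ndarray:
        return triple_product_table(self.P)


@dataclass
class GPCWHEKernels:
    """Final-level kernels ``x_k^(j)`` (chaos index k, WHE order j) plus the
    per-time kernel square-integral series needed for variance decomposition.

    Naming: ``y`` = order-0 (mean) kernels, ``u`` = order-1 vectors over t1,
    ``v`` = order-2 matrices over (t1, t2); trailing 0/1 is the chaos index.
    ``j__`` series are ``int (u_)^2 dt1`` and ``q__`` series the unweighted
    ``int int (v_)^2 dt1 dt2``.  In a Gaussian-only run the second-order
    kernels are never allocated (``v0``/``v1`` stay ``None``; ``q`` = 0).
    """

    grid: TimeGrid
    gaussian_only: bool
    y0_series: np.ndarray
    y1_series: np.ndarray
    u0: np.ndarray
    u1: np.ndarray
    v0: np.ndarray | None
    v1: np.ndarray | None
    j00: np.ndarray
    j11: np.ndarray
    q00: np.ndarray
    q11: np.ndarray


def gpc_whe_solve(
    params: ModelParams,
    grid: TimeGrid,
    P: int = 1,
    gaussian_only: bool = False,
    convention: str = "coefficient",
) -> tuple[GPCWHEKernels, pd.DataFrame]:
    """Advance the coupled gPC-WHE deterministic system over the grid.

    With ``a1 = 0`` the chaos modes stay identically zero and the chaos-0
    kernels coincide with :func:`stochpop.whe.whe_solve` to round-off.  The
    returned table carries per-time mean (``x0^(0)``), the first chaos mode
    of the mean (``x1^(0)``), and all variance ingredients; feed it (or the
    kernel object) to :func:`stochpop.sensitivity.decompose_variance`.
    """
    if P != 1:
        raise NotImplementedError("chaos order P = 1 is the implemented case")
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    check_stability(params, grid)

    a0, eps, lam = params.a0, params.eps, params.lam
    a1 = params.a1 if convention == "coefficient" else params.a1 / SQRT3
    dt = grid.dt
    n = grid.n_steps
    m = n + 1

    y0, y1 = params.x0, 0.0
    u0 = np.zeros(m)
    u1 = np.zeros(m)
    v0 = v1 = None
    if not gaussian_only:
        v0 = np.zeros((m, m))
        v1 = np.zeros((m, m))
    y0_s = np.zeros(m)
    y1_s = np.zeros(m)
    j00 = np.zeros(m)
    j11 = np.zeros(m)
    q00 = np.zeros(m)
    q11 = np.zeros(m)

    def record(i: int) -> None:
        s = slice(0, i + 1)
        y0_s[i], y1_s[i] = y0, y1
        j00[i] = dt * (u0[s] @ u0[s])
        j11[i] = dt * (u1[s] @ u1[s])
        if not gaussian_only:
            V0, V1 = v0[s, s], v1[s, s]
            q00[i] = dt * dt * float(np.sum(V0 * V0))
            q11[i] = dt * dt * float(np.sum(V1 * V1))

    for i in range(n):
        record(i)
        s = slice(0, i + 1)
        a_ = u0[s].copy()
        b_ = u1[s].copy()
        J01 = dt * (a_ @ b_)
        if gaussian_only:
            Q01 = 0.0
        else:
            Q01 = dt * dt * float(np.sum(v0[s, s] * v1[s, s]))

        # mean kernels (chaos modes of x^(0))
        ny0 = y0 + dt * (
            a0 * y0 + a1 * y1
            - eps * (y0 * y0 + y1 * y1 + j00[i] + j11[i] + 2.0 * (q00[i] + q11[i]))
        )
        ny1 = y1 + dt * (
            a0 * y1 + a1 * y0 - 2.0 * eps * (y0 * y1 + J01 + 2.0 * Q01)
        )

        # effective damping coefficients of the first/second-order kernels:
        # diag couples through a0 - 2 eps x0^(0), off-diag through a1 - 2 eps x1^(0)
        d_same = a0 - 2.0 * eps * y0
        d_cross = a1 - 2.0 * eps * y1

        # first-order (Gaussian) kernels
        if gaussian_only:
            nu0 = a_ + dt * (d_same * a_ + d_cross * b_)
            nu1 = b_ + dt * (d_same * b_ + d_cross * a_)
        else:
            V0, V1 = v0[s, s], v1[s, s]
            R0 = dt * (V0 @ a_ + V1 @ b_)
            R1 = dt * (V1 @ a_ + V0 @ b_)
            nu0 = a_ + dt * (d_same * a_ + d_cross * b_ - 4.0 * eps * R0)
            nu1 = b_ + dt * (d_same * b_ + d_cross * a_ - 4.0 * eps * R1)
            nV0 = V0 + dt * (
                d_same * V0 + d_cross * V1
                - eps * (np.outer(a_, a_) + np.outer(b_, b_))
            )
            nV1 = V1 + dt * (
                d_same * V1 + d_cross * V0
                - eps * (np.outer(a_, b_) + np.outer(b_, a_))
            )
            v0[s, s] = nV0
            v1[s, s] = nV1
            v0[s, i] += 0.5 * lam * a_
            v0[i, s] += 0.5 * lam * a_
            v1[s, i] += 0.5 * lam * b_
            v1[i, s] += 0.5 * lam * b_
        u0[s] = nu0
        u1[s] = nu1
        u0[i] += lam * y0
        u1[i] += lam * y1
        y0, y1 = ny0, ny1
        if not np.isfinite(y0):
            raise FloatingPointError("FDM diverged; reduce dt")
    record(n)

    kernels = GPCWHEKernels(
        grid=grid,
        gaussian_only=gaussian_only,
        y0_series=y0_s,
        y1_series=y1_s,
        u0=u0,
        u1=u1,
        v0=v0,
        v1=v1,
        j00=j00,
        j11=j11,
        q00=q00,
        q11=q11,
    )
    table = pd.DataFrame(
        {
            "t": grid.times,
            "mean": y0_s,
            "x1_0": y1_s,
            "j00": j00,
            "j11": j11,
            "q00": q00,
            "q11": q11,
        }
    )
    return kernels, table
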