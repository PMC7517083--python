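"""Sampling-based reference solvers for the stochastic logistic SDE.

Three routes, all returning per-time sample moment tables:

* Euler-Maruyama time stepping (weak order 1, strong order 0.5),
* the exact pathwise solution
  ``X(t) = e^{(a - lam^2/2) t + lam B(t)} / (1/x0 + eps * int_0^t e^{...})``
  evaluated on simulated Brownian paths (positive by construction; the
  denominator integral uses the trapezoidal rule along each path),
* a nested parameter-plus-noise Monte Carlo for a uniformly random growth
  rate, with the law-of-total-variance split into a between-draw
  (parameter) and a within-draw (noise-like) component.

These are validation oracles for the spectral solvers, not production
solvers; moments come with standard errors so agreement can be judged in
standard-error units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, TimeGrid

__all__ = ["MCConfig", "em_paths", "exact_path_samples", "nested_mc"]


@dataclass(frozen=True)
class MCConfig:
    """Sampling configuration.

    ``seed`` is required explicitly: identical (seed, config) inputs give
    bit-identical sample moments.  ``dt_mc`` is the simulation step of the
    sampling solvers and need not equal the spectral grid step.
    """

    n_paths: int = 10_000
    seed: int = 0
    dt_mc: float = 0.01
    scheme: str = "euler_maruyama"
    n_param_draws: int = 200

    def __post_init__(self) -> None:
        if self.n_paths < 1:
            raise ValueError("n_paths must be >= 1")
        if self.dt_mc <= 0:
            raise ValueError("dt_mc must be > 0")
        if self.scheme not in ("euler_maruyama", "exact_path"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.n_param_draws < 1:
            raise ValueError("n_param_draws must be >= 1")


def _moment_frame(times: np.ndarray, X: np.ndarray) -> pd.DataFrame:
    """Sample mean/variance table with standard errors from paths ``X``
    of shape (n_paths, n_times)."""
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n > 1 else np.zeros(X.shape[1])
    se_mean = np.sqrt(var / n)
    if n > 1:
        m4 = ((X - mean) ** 4).mean(axis=0)
        se_var = np.sqrt(np.maximum(m4 - (n - 3) / (n - 1) * var**2, 0.0) / n)
    else:
        se_var = np.zeros_like(var)
    return pd.DataFrame(
        {"t": times, "mean": mean, "variance": var, "se_mean": se_mean, "se_var": se_var}
    )


def _mc_times(grid: TimeGrid, cfg: MCConfig) -> np.ndarray:
    n = int(round(grid.t_end / cfg.dt_mc))
    return np.arange(n + 1) * cfg.dt_mc


def em_paths(
    params: ModelParams,
    grid: TimeGrid,
    cfg: MCConfig,
    rng: np.random.Generator | None = None,
    a_value: float | None = None,
) -> pd.DataFrame:
    """Euler-Maruyama sample moments of ``dX = (aX - eps X^2) dt + lam X dW``.

    ``X_{i+1} = X_i + (a X_i - eps X_i^2) dt + lam X_i dW_i`` with Gaussian
    increments of variance ``dt_mc``.  Negative excursions are floored at 0
    (absorbing; drift and diffusion both vanish there), never resampled.
    ``a_value`` overrides the growth rate (used by the nested sampler);
    otherwise ``a1 = 0`` is required.
    """
    if a_value is None:
        if params.a1 != 0.0:
            raise ValueError("em_paths requires a1 = 0 (use nested_mc for a random growth rate)")
        a_value = params.a0
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    times = _mc_times(grid, cfg)
    dt = cfg.dt_mc
    sdt = np.sqrt(dt)
    X = np.empty((cfg.n_paths, times.size))
    x = np.full(cfg.n_paths, params.x0)
    X[:, 0] = x
    for i in range(times.size - 1):
        dW = sdt * rng.standard_normal(cfg.n_paths)
        x = x + (a_value * x - params.eps * x * x) * dt + params.lam * x * dW
        np.maximum(x, 0.0, out=x)
        X[:, i + 1] = x
    return _moment_frame(times, X)


def exact_path_samples(
    params: ModelParams,
    grid: TimeGrid,
    cfg: MCConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample moments from the exact pathwise solution of the SDE.

    Each path simulates Brownian motion on the grid, evaluates
    ``Y = exp((a - lam^2/2) t + lam B)`` and forms
    ``X = Y / (1/x0 + eps * cumtrapz(Y))``.  With ``lam = 0`` this reduces
    to the deterministic logistic solution up to the trapezoidal quadrature
    of the denominator.
    """
    if params.a1 != 0.0:
        raise ValueError("exact_path_samples requires a1 = 0")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    times = _mc_times(grid, cfg)
    dt = cfg.dt_mc
    dB = np.sqrt(dt) * rng.standard_normal((cfg.n_paths, times.size - 1))
    B = np.concatenate([np.zeros((cfg.n_paths, 1)), np.cumsum(dB, axis=1)], axis=1)
    drift = (params.a0 - 0.5 * params.lam**2) * times
    # guard against overflow for long horizons: work with Y normalized is not
    # needed at the parameter scales of this model (a*t <= O(20))
    Y = np.exp(drift + params.lam * B)
    integ = np.concatenate(
        [np.zeros((cfg.n_paths, 1)), np.cumsum(0.5 * dt * (Y[:, 1:] + Y[:, :-1]), axis=1)],
        axis=1,
    )
    X = Y / (1.0 / params.x0 + params.eps * integ)
    return _moment_frame(times, X)


def nested_mc(
    params: ModelParams,
    grid: TimeGrid,
    cfg: MCConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nested Monte Carlo for a uniformly random growth rate.

    The outer loop draws ``a ~ U[a0 - a1, a0 + a1]`` (``a1`` interpreted as
    the uniform half-width); the inner loop runs Euler-Maruyama with that
    draw.  The law of total variance splits the overall variance into a
    between-draw component (variance of inner means: the parameter part)
    and a within-draw component (mean of inner variances: the noise-like
    part, which at second order lumps noise and interaction together).

    Returns ``(moments, split)`` where ``split`` has columns
    ``t, var_between, var_within, var_total``.
    """
    if params.a1 < 0.0:
        raise ValueError("a1 must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    draws = rng.uniform(params.a0 - params.a1, params.a0 + params.a1, size=cfg.n_param_draws)
    times = _mc_times(grid, cfg)
    means = np.empty((cfg.n_param_draws, times.size))
    varis = np.empty((cfg.n_param_draws, times.size))
    for r, a in enumerate(draws):
        tab = em_paths(params, grid, cfg, rng=rng, a_value=float(a))
        means[r] = tab["mean"].to_numpy()
        varis[r] = tab["variance"].to_numpy()
    grand_mean = means.mean(axis=0)
    between = means.var(axis=0, ddof=1) if cfg.n_param_draws > 1 else np.zeros(times.size)
    within = varis.mean(axis=0)
    total = between + within
    n_eff = cfg.n_param_draws * cfg.n_paths
    moments = pd.DataFrame(
        {
            "t": times,
            "mean": grand_mean,
            "variance": total,
            "se_mean": np.sqrt(between / cfg.n_param_draws + within / n_eff),
            "se_var": np.sqrt(2.0 / max(cfg.n_param_draws - 1, 1)) * between
            + np.sqrt(2.0 / max(n_eff - 1, 1)) * within,
        }
    )
    split = pd.DataFrame(
        {"t": times, "var_between": between, "var_within": within, "var_total": total}
    )
    return moments, split
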