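"""Variance decomposition and variance-based sensitivity indices.

With one random parameter (chaos order P = 1) and WHE order M <= 2, the
total variance of the population splits additively into

* ``var_par  = (x1^(0))^2`` - spread carried by the random growth rate,
* ``var_noise = int (x0^(1))^2 + 2 int int (x0^(2))^2`` - spread injected by
  the driving noise,
* ``var_mix  = int (x1^(1))^2 + 2 int int (x1^(2))^2`` - interaction of the
  two sources,

and the first-order sensitivity index of each source is its variance share,
e.g. ``S_noise = var_noise / var_total``.  Indices sum to 1 wherever the
total variance is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpc import GPCWHEKernels
from .model import TimeGrid
from .whe import _is_converged

__all__ = ["VarianceReport", "decompose_variance", "sensitivity_indices"]


@dataclass
class VarianceReport:
    """Time series of the variance split and the sensitivity indices.

    Indices are stored as fractions in ``[0, 1]``; command-line output
    formats them as percentages.  ``degenerate`` marks times with zero total
    variance, where all indices are reported as 0.
    """

    t: np.ndarray
    var_total: np.ndarray
    var_par: np.ndarray
    var_noise: np.ndarray
    var_mix: np.ndarray
    s_noise: np.ndarray
    s_par: np.ndarray
    s_mix: np.ndarray
    degenerate: np.ndarray
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "var_total": self.var_total,
                "var_par": self.var_par,
                "var_noise": self.var_noise,
                "var_mix": self.var_mix,
                "s_noise": self.s_noise,
                "s_par": self.s_par,
                "s_mix": self.s_mix,
            }
        )


def decompose_variance(kernels: GPCWHEKernels, grid: TimeGrid) -> VarianceReport:
    """Split the total variance of a completed gPC-WHE run per time point.

    The second-order kernel integrals enter with their combinatorial weight
    2 (they are zero for a Gaussian-only run).  Additivity
    ``var_total = var_par + var_noise + var_mix`` holds by construction.
    """
    var_par = kernels.y1_series**2
    var_noise = kernels.j00 + 2.0 * kernels.q00
    var_mix = kernels.j11 + 2.0 * kernels.q11
    var_total = var_par + var_noise + var_mix

    degenerate = var_total == 0.0
    s = np.zeros((3, var_total.size))
    nz = ~degenerate
    s[0, nz] = var_noise[nz] / var_total[nz]
    s[1, nz] = var_par[nz] / var_total[nz]
    s[2, nz] = var_mix[nz] / var_total[nz]

    window = max(2, grid.n_steps // 10)
    converged = _is_converged(kernels.y0_series, window) and _is_converged(var_total, window)
    return VarianceReport(
        t=grid.times,
        var_total=var_total,
        var_par=var_par,
        var_noise=var_noise,
        var_mix=var_mix,
        s_noise=s[0],
        s_par=s[1],
        s_mix=s[2],
        degenerate=degenerate,
        converged=converged,
    )


def sensitivity_indices(report: VarianceReport, t="steady_state") -> tuple[float, float, float]:
    """``(S_noise, S_par, S_mix)`` at a given time or at steady state.

    ``t = "steady_state"`` uses the final time point of the run (the same
    convergence rule as the solvers applies; check ``report.converged``).
    A numeric ``t`` is matched to the nearest grid point.  At a degenerate
    time (zero total variance) all indices are 0.
    """
    if isinstance(t, str):
        if t != "steady_state":
            raise ValueError(f"unknown time specifier {t!r}")
        idx = len(report.t) - 1
    else:
        idx = int(np.argmin(np.abs(report.t - float(t))))
    return float(report.s_noise[idx]), float(report.s_par[idx]), float(report.s_mix[idx])
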